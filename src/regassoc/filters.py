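"""Variant prioritization by predicted function and eQTL evidence.

A variant is retained when any one of three criteria holds: it belongs to an
always-keep functional class (splice or stop by default), it is nonsynonymous
with a deleteriousness score strictly above the threshold (default 0.5, the
usual PolyPhen-2 "possibly damaging" boundary), or it carries eQTL evidence
with -log10 p at or above the cutoff (default 3.4).  Unannotated variants
fail.  The filter is a union of routes, order-invariant and idempotent.

Monomorphic variants (MAF = 0) pass the filter — functional evidence is
genotype-free — but every test statistic drops them downstream because a
monomorphic marker carries no association information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotationRecord, GenotypeMatrix

__all__ = ["FilterConfig", "functional_filter", "maf_summary"]


@dataclass(frozen=True)
class FilterConfig:
    del_score_min: float = 0.5          # strict > ("scores above 0.5")
    eqtl_neglogp_min: float = 3.4       # inclusive >= (a cutoff that is "used")
    always_keep_classes: frozenset[str] = frozenset({"splice", "stop"})
    maf_bins: tuple[float, ...] = (0.01, 0.05)

    def __post_init__(self) -> None:
        if self.del_score_min < 0 or self.eqtl_neglogp_min < 0:
            raise ValueError("thresholds must be nonnegative")
        bins = self.maf_bins
        if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])) or any(
            not 0 < b <= 0.5 for b in bins
        ):
            raise ValueError("maf_bins must be strictly increasing in (0, 0.5]")


def _keeps(rec: AnnotationRecord, cfg: FilterConfig) -> bool:
    if rec.func_class in cfg.always_keep_classes:
        return True
    if (
        rec.func_class == "nonsynonymous"
        and rec.del_score is not None
        and rec.del_score > cfg.del_score_min
    ):
        return True
    if rec.eqtl_neglogp is not None and rec.eqtl_neglogp >= cfg.eqtl_neglogp_min:
        return True
    return False


def functional_filter(
    variant_ids,
    annotations: list[AnnotationRecord],
    config: FilterConfig = FilterConfig(),
) -> list[str]:
    """Return the variant ids that pass any prioritization route, in input order."""
    by_vid = {a.vid: a for a in annotations}
    kept = []
    for vid in variant_ids:
        rec = by_vid.get(vid)
        if rec is not None and _keeps(rec, config):
            kept.append(vid)
    return kept


def maf_summary(mafs, maf_bins=(0.01, 0.05)) -> pd.DataFrame:
    """Count variants with MAF strictly below each bound.

    Mirrors the usual rare-variant stratification table: one row per bound
    plus a total row; percentages are count/total rounded to one decimal.
    An empty input yields a summary with total 0 and empty strata.
    """
    mafs = np.asarray(list(mafs), dtype=float)
    if mafs.size and (mafs.min() < 0 or mafs.max() > 0.5):
        raise ValueError("MAF values must lie in [0, 0.5]")
    total = mafs.size
    rows = [("total", total, 100.0 if total else np.nan)]
    for bound in maf_bins:
        cnt = int((mafs < bound).sum())
        pct = round(100.0 * cnt / total, 1) if total else np.nan
        rows.append((f"maf<{bound:g}", cnt, pct))
    return pd.DataFrame(rows, columns=["stratum", "count", "percent"])


def filter_genotypes(
    gm: GenotypeMatrix,
    annotations: list[AnnotationRecord],
    config: FilterConfig = FilterConfig(),
) -> GenotypeMatrix:
    """Convenience: apply :func:`functional_filter` to a genotype matrix."""
    kept = functional_filter(gm.variants["vid"], annotations, config)
    return gm.subset_variants(kept)
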