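"""Readers and writers for the file formats the toolkit touches.

Genotypes come from VCF (diploid, biallelic, GT field; gzip accepted via
htslib), pedigrees from 6-column PLINK-style PED files, phenotypes and variant
annotations from tab-delimited tables, gene intervals from BED3+name.  The
in-memory genotype container is :class:`GenotypeMatrix`: a persons x variants
minor-allele dosage matrix (NaN = missing) with per-variant metadata.

Conventions
-----------
* Variant ids default to ``chrom-pos`` when the VCF ID column is ``.``.
* VCF positions are 1-based; gene intervals are stored 0-based half-open
  (BED dialect), so a variant at 1-based position p lies in a gene iff
  ``start <= p-1 < end``.
* The counted (minor) allele is defined in the loaded cohort; at MAF = 0.5
  the ALT allele stays the counted allele.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import PedigreeSet, Person, UNKNOWN_SEX

__all__ = [
    "GenotypeMatrix",
    "AnnotationRecord",
    "read_vcf",
    "read_ped",
    "read_phenotypes",
    "read_annotation",
    "read_gene_table",
    "write_vcf",
    "write_ped",
    "write_phenotypes",
]

FUNC_CLASSES = {"nonsynonymous", "splice", "stop", "synonymous", "noncoding", "other"}


class MissingSampleError(KeyError):
    pass


@dataclass(frozen=True)
class AnnotationRecord:
    vid: str
    func_class: str
    del_score: float | None = None
    eqtl_neglogp: float | None = None

    def __post_init__(self) -> None:
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"unknown functional class {self.func_class!r}")
        if self.del_score is not None and not 0.0 <= self.del_score <= 1.0:
            raise ValueError(f"del_score {self.del_score} outside [0,1]")
        if self.eqtl_neglogp is not None and self.eqtl_neglogp < 0:
            raise ValueError(f"eqtl_neglogp {self.eqtl_neglogp} negative")


@dataclass
class GenotypeMatrix:
    """Minor-allele dosages for ``samples`` (rows) x ``variants`` (columns).

    ``variants`` is a DataFrame with columns chrom, pos, vid, ref, alt, maf,
    sorted by (chrom, pos); ``dosages`` is float with values {0,1,2} or NaN.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    _vindex: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape does not match samples x variants")
        if self.variants["vid"].duplicated().any():
            dup = self.variants.loc[self.variants["vid"].duplicated(), "vid"].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        self.variants = self.variants.reset_index(drop=True)
        self._vindex = {v: i for i, v in enumerate(self.variants["vid"])}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, vids) -> np.ndarray:
        return np.array([self._vindex[v] for v in vids], dtype=int)

    def subset_variants(self, vids) -> "GenotypeMatrix":
        idx = self.variant_index(vids)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx].copy(),
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise MissingSampleError(f"samples not in genotype matrix: {missing}")
        rows = [pos[s] for s in sample_ids]
        gm = GenotypeMatrix(
            samples=list(sample_ids),
            variants=self.variants.copy(),
            dosages=self.dosages[rows, :].copy(),
        )
        gm.recompute_maf()
        return gm

    def recompute_maf(self) -> None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        freq = np.where(np.isnan(freq), 0.0, freq)
        self.variants["maf"] = np.minimum(freq, 1.0 - freq)


def _compute_dosage_and_maf(alt_counts: np.ndarray) -> tuple[np.ndarray, float]:
    """Flip ALT counts to minor-allele counts; ALT kept at a 0.5 tie."""
    ok = np.isfinite(alt_counts)
    if not ok.any():
        return alt_counts, 0.0
    af = alt_counts[ok].mean() / 2.0
    if af > 0.5:
        d = np.where(ok, 2.0 - alt_counts, np.nan)
        return d, 1.0 - af
    return alt_counts, af


def read_vcf(path: str, sample_subset: list[str] | None = None) -> GenotypeMatrix:
    """Load a biallelic VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are skipped with a warning.  Dosage is the count of
    the minor allele computed in the loaded sample set; missing GT is NaN and
    MAF is computed on the nonmissing calls.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    if sample_subset is not None:
        absent = [s for s in sample_subset if s not in samples]
        if absent:
            raise MissingSampleError(f"samples not in VCF: {absent}")
        rows = np.array([samples.index(s) for s in sample_subset])
        samples = list(sample_subset)
    else:
        rows = np.arange(len(samples))

    recs, cols = [], []
    seen = set()
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multiallelic record at {var.CHROM}:{var.POS}")
            continue
        # gts012: 0/1/2 = ALT count, 3 = missing
        alt = var.gt_types.astype(float)[rows]
        alt[alt == 3] = np.nan
        d, maf = _compute_dosage_and_maf(alt)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}-{var.POS}"
        if vid in seen:
            raise ValueError(f"duplicate variant id {vid!r} in {path}")
        seen.add(vid)
        recs.append((var.CHROM, var.POS, vid, var.REF, var.ALT[0], maf))
        cols.append(d)
    variants = pd.DataFrame(recs, columns=["chrom", "pos", "vid", "ref", "alt", "maf"])
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    order = variants.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    return GenotypeMatrix(
        samples=samples,
        variants=variants.iloc[order].reset_index(drop=True),
        dosages=dosages[:, order],
    )


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_ped(path: str) -> PedigreeSet:
    """Read a whitespace-delimited 6+ column PED file (fid iid father mother sex pheno)."""
    persons: list[Person] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected >=6 columns, got {len(parts)}")
            fid, iid, fa, mo, sex = parts[:5]
            try:
                sex_i = int(sex)
            except ValueError:
                sex_i = UNKNOWN_SEX
            persons.append(
                Person(
                    fid=fid,
                    iid=iid,
                    father=None if fa in ("0", ".", "") else fa,
                    mother=None if mo in ("0", ".", "") else mo,
                    sex=sex_i if sex_i in (1, 2) else UNKNOWN_SEX,
                )
            )
    return PedigreeSet(persons)


def read_phenotypes(path: str) -> pd.DataFrame:
    """Tab-delimited phenotype table with header; requires fid, iid, exam columns.

    Returns a DataFrame indexed by (fid, iid, exam) with phenotype/covariate
    columns as floats where possible.
    """
    df = pd.read_csv(path, sep="\t", dtype={"fid": str, "iid": str})
    for col in ("fid", "iid", "exam"):
        if col not in df.columns:
            raise ValueError(f"phenotype table {path} lacks required column {col!r}")
    return df.set_index(["fid", "iid", "exam"])


def read_annotation(path: str) -> list[AnnotationRecord]:
    """Tab-delimited annotation table: vid, func_class, del_score, eqtl_neglogp.

    NA/empty numeric fields become missing; duplicate vids: last wins with a
    warning; malformed numbers raise with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("vid", "func_class"):
        if col not in df.columns:
            raise ValueError(f"annotation table {path} lacks required column {col!r}")
    out: dict[str, AnnotationRecord] = {}
    for row_i, row in enumerate(df.itertuples(index=False), 2):  # header is line 1
        def _num(val, name):
            if val is None or (isinstance(val, float) and np.isnan(val)) or val in ("", "NA", "."):
                return None
            try:
                return float(val)
            except ValueError:
                raise ValueError(f"{path}:{row_i}: malformed {name} field {val!r}") from None

        rec = AnnotationRecord(
            vid=row.vid,
            func_class=row.func_class,
            del_score=_num(getattr(row, "del_score", None), "del_score"),
            eqtl_neglogp=_num(getattr(row, "eqtl_neglogp", None), "eqtl_neglogp"),
        )
        if rec.vid in out:
            warnings.warn(f"duplicate annotation for {rec.vid}; keeping the last")
        out[rec.vid] = rec
    return list(out.values())


def read_gene_table(path: str) -> list[tuple[str, int, int, str]]:
    """BED3+name gene intervals: chrom, start, end, name (0-based half-open)."""
    genes = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected chrom start end name")
            chrom, start, end, name = parts[:4]
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{ln}: malformed interval bounds") from None
            if not 0 <= s < e:
                raise ValueError(f"{path}:{ln}: invalid interval [{s},{e})")
            genes.append((chrom, s, e, name))
    return genes


# -- writers (round-trips and the simulate CLI) ----------------------------

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write dosages as a minimal VCF 4.2 with the counted allele as ALT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for j, v in enumerate(gm.variants.itertuples(index=False)):
            gts = [_GT.get(d, "./.") for d in gm.dosages[:, j]]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_ped(pedset: PedigreeSet, path: str, phenotype: dict[str, float] | None = None) -> None:
    with open(path, "w") as fh:
        for fid in pedset.pedigrees:
            for iid in pedset.pedigrees[fid]:
                p = pedset.persons[iid]
                ph = (phenotype or {}).get(iid, -9)
                fh.write(
                    f"{p.fid} {p.iid} {p.father or 0} {p.mother or 0} {p.sex} {ph}\n"
                )


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    """Write a (fid,iid,exam)-indexed phenotype table as TSV."""
    df.reset_index().to_csv(path, sep="\t", index=False)
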