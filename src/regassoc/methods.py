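"""Named region-test entry points shared by the simulation harness, scan, and CLI.

A method name resolves to a callable that takes a prepared region and returns
a p-value.  Family-based names use the pedigree scores engine ("_e" suffix =
empirical variance); population names run on the unrelated subset.
"""

from __future__ import annotations

import numpy as np

from . import fbat, poptests
from .io import GenotypeMatrix
from .pedigree import PedigreeSet

FAMILY_METHODS = ("fbat_v", "fbat_v_e", "fbat_l", "fbat_l_e", "fbat_m", "fbat_m_e", "fbat_lmm")
POPULATION_METHODS = ("skat", "gcta")
ALL_METHODS = FAMILY_METHODS + POPULATION_METHODS


def run_method(
    name: str,
    *,
    genotypes: GenotypeMatrix,
    pedset: PedigreeSet,
    trait,
    markers: list[str] | None = None,
    design=None,
    scores=None,
    unrelated: list[str] | None = None,
    trait_map: dict[str, float] | None = None,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Run one named region test and return its p-value.

    ``scores`` (family tests) and ``unrelated`` + ``trait_map`` (population
    tests) can be passed to reuse work across several methods on the same
    region.
    """
    if name in FAMILY_METHODS:
        if scores is None:
            scores = fbat.build_region_scores(genotypes, pedset, trait, markers=markers, design=design)
        if name == "fbat_lmm":
            return fbat.fbat_lmm(scores, n_perm=n_perm, rng=rng).p_value
        base, mode = (name[:-2], "empirical") if name.endswith("_e") else (name, "model")
        func = {"fbat_v": fbat.fbat_v, "fbat_l": fbat.fbat_l, "fbat_m": fbat.fbat_m}[base]
        return func(scores, variance_mode=mode).p_value
    if name in POPULATION_METHODS:
        if unrelated is None:
            unrelated = poptests.select_unrelated(pedset, "founders_only")
        gm_u = genotypes.subset_samples(unrelated) if markers is None else (
            genotypes.subset_variants(markers).subset_samples(unrelated)
        )
        if trait_map is None:
            trait_map = fbat._as_trait_map(trait)
        keep = [s for s in gm_u.samples if s in trait_map]
        if len(keep) < len(gm_u.samples):
            gm_u = gm_u.subset_samples(keep)
        y = np.array([trait_map[s] for s in gm_u.samples])
        if name == "skat":
            return poptests.skat_test(gm_u, y).p_value
        return poptests.gcta_region_test(gm_u, y).p_value
    raise ValueError(f"unknown method {name!r}")
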