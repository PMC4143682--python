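"""Synthetic cohorts and the type-I-error / power evaluation harness.

Genotypes are produced by gene dropping: founder alleles are drawn
independently per locus at the requested minor-allele frequencies (no
linkage disequilibrium) and propagated by Mendelian inheritance.  Two
segregation modes exist:

* independent (default): every locus segregates independently in each
  meiosis, matching the no-LD approximation the family tests make;
* co-segregating region (``linked=True``): all loci in the call travel as a
  single non-recombining block through each meiosis, founder alleles still
  independent.  This is the faithful picture of a small gene region and is
  what lets a heritable trait be *linked* to the tested markers without
  being associated with them.

The quantitative trait is

    y = sum_c beta_c g_c + a_linked + a_unlinked + delta*covariates + e

where ``a_linked`` comes from hidden causal loci co-segregating with the
region (linkage without association; founder alleles independent of the
markers), ``a_unlinked`` is a pedigree-correlated polygenic deviate
MVN(0, sigma_a^2 * 2*Phi), and variances are scaled so the polygenic
heritability and causal variance come out as configured with unit total
genetic+environmental variance.  Age and sex covariates leak mildly into the
trait so the adjustment step has something to remove.

The harness regenerates a cohort per replicate, adjusts the phenotype,
runs the requested region tests, and reports per-method rejection rates at
the nominal level with exact (Clopper–Pearson) binomial intervals.  The
default evaluation size is 200 replicates at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import methods as _methods
from .fbat import build_family_design, build_region_scores
from .io import GenotypeMatrix
from .pedigree import KinshipMatrix, PedigreeSet, Person, kinship
from .pheno import TraitVector, residualize
from .poptests import select_unrelated

__all__ = [
    "MAP4_MAFS",
    "SimConfig",
    "SimulationReport",
    "make_pedigrees",
    "gene_drop",
    "simulate_trait",
    "simulate_dataset",
    "run_experiment",
    "preset_q1like",
    "preset_map4like",
]

# The 28 printed MAFs of the filtered MAP4-region variants (input table for
# the "MAP4-like" scenario; three loci are monomorphic).
MAP4_MAFS = (
    0.0085, 0.0085, 0.0128, 0.0128, 0.0043, 0.0, 0.0,
    0.0043, 0.0214, 0.0043, 0.3718, 0.3162, 0.0043, 0.0043,
    0.3590, 0.0, 0.0214, 0.3120, 0.0256, 0.0214, 0.3162,
    0.3162, 0.3205, 0.4017, 0.2521, 0.2564, 0.2222, 0.1795,
)


# ---------------------------------------------------------------------------
# pedigree templates

def _trio(fid: str) -> list[Person]:
    return [
        Person(fid, f"{fid}_f", sex=1),
        Person(fid, f"{fid}_m", sex=2),
        Person(fid, f"{fid}_c1", father=f"{fid}_f", mother=f"{fid}_m", sex=1),
    ]


def _sibship(fid: str, k: int) -> list[Person]:
    out = [Person(fid, f"{fid}_f", sex=1), Person(fid, f"{fid}_m", sex=2)]
    out += [
        Person(fid, f"{fid}_c{i}", father=f"{fid}_f", mother=f"{fid}_m", sex=1 + i % 2)
        for i in range(1, k + 1)
    ]
    return out


def _threegen(fid: str) -> list[Person]:
    """Grandparent couple, three middle-generation sibs with marry-in spouses,
    three grandchildren per middle couple: 17 persons, 4 nuclear families.

    Sized to resemble extended study pedigrees (many members, several nuclear
    families per pedigree), the regime where treating nuclear families as
    independent misstates the score variance."""
    gp = [Person(fid, f"{fid}_gf", sex=1), Person(fid, f"{fid}_gm", sex=2)]
    mid, kids = [], []
    for b in (1, 2, 3):
        mid.append(Person(fid, f"{fid}_p{b}", father=f"{fid}_gf", mother=f"{fid}_gm", sex=1))
        mid.append(Person(fid, f"{fid}_s{b}", sex=2))
        for c in (1, 2, 3):
            kids.append(
                Person(fid, f"{fid}_g{b}{c}", father=f"{fid}_p{b}", mother=f"{fid}_s{b}", sex=1 + c % 2)
            )
    return gp + mid + kids


def make_pedigrees(template: str, n_pedigrees: int) -> PedigreeSet:
    """Replicate a named pedigree template: 'trio', 'sibship-k', 'threegen'."""
    persons: list[Person] = []
    for i in range(n_pedigrees):
        fid = f"ped{i:04d}"
        if template == "trio":
            persons += _trio(fid)
        elif template.startswith("sibship-"):
            persons += _sibship(fid, int(template.split("-", 1)[1]))
        elif template == "threegen":
            persons += _threegen(fid)
        else:
            raise ValueError(f"unknown pedigree template {template!r}")
    return PedigreeSet(persons)


# ---------------------------------------------------------------------------
# gene dropping

def gene_drop(
    pedset: PedigreeSet,
    mafs,
    rng: np.random.Generator,
    linked: bool = False,
    chrom: str = "1",
    positions=None,
    vids=None,
) -> GenotypeMatrix:
    """Drop founder alleles through the pedigrees.

    Founder haplotype alleles are independent Bernoulli(maf) per locus (no
    LD).  Each meiosis picks the transmitted parental haplotype per locus
    independently, or — with ``linked=True`` — once for the whole locus block
    (complete co-segregation, no recombination).
    """
    mafs = np.asarray(list(mafs), dtype=float)
    if mafs.size and (mafs.min() < 0 or mafs.max() > 0.5):
        raise ValueError("mafs must lie in [0, 0.5]")
    L = mafs.size
    order = pedset.topological_order()
    idx = {iid: i for i, iid in enumerate(order)}
    hap = np.zeros((len(order), 2, L), dtype=np.int8)
    for iid in order:
        i = idx[iid]
        p = pedset.persons[iid]
        for slot, parent in enumerate((p.father, p.mother)):
            if parent is None:
                hap[i, slot] = rng.random(L) < mafs
            else:
                ph = hap[idx[parent]]
                if linked:
                    hap[i, slot] = ph[int(rng.integers(2))]
                else:
                    pick = rng.integers(2, size=L)
                    hap[i, slot] = ph[pick, np.arange(L)]
    dosages = hap.sum(axis=1).astype(float)
    if positions is None:
        positions = np.arange(1, L + 1) * 1000
    if vids is None:
        vids = [f"{chrom}-{p}" for p in positions]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=int),
            "vid": list(vids),
            "ref": "A",
            "alt": "C",
            "maf": mafs,
        }
    )
    gm = GenotypeMatrix(samples=order, variants=variants, dosages=dosages)
    gm.recompute_maf()
    return gm


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation scenario."""

    pedigree_template: str = "trio"
    n_pedigrees: int = 200
    mafs: tuple[float, ...] = MAP4_MAFS
    causal_index: tuple[int, ...] = ()      # marker columns with direct effects
    betas: tuple[float, ...] = ()           # per-allele effects, same order
    polygenic_h2: float = 0.0               # total polygenic heritability
    linked_h2: float = 0.0                  # share realized by loci co-segregating with the region
    n_linked_loci: int = 8
    linked_maf: float = 0.25
    n_exams: int = 1
    measurement_sd: float = 0.5
    n_replicates: int = 200
    alpha: float = 0.05
    n_perm: int = 1000                      # fbat_lmm permutations
    seed: int = 0
    chrom: str = "3"

    def __post_init__(self) -> None:
        if not 0.0 <= self.polygenic_h2 < 1.0:
            raise ValueError("polygenic_h2 must be in [0, 1)")
        if not 0.0 <= self.linked_h2 <= self.polygenic_h2:
            raise ValueError("linked_h2 must be in [0, polygenic_h2]")
        if len(self.causal_index) != len(self.betas):
            raise ValueError("causal_index and betas must align")
        if self.polygenic_h2 + self.causal_variance() >= 1.0:
            raise ValueError("polygenic plus causal variance must stay below 1")

    def causal_variance(self) -> float:
        v = 0.0
        for i, b in zip(self.causal_index, self.betas):
            p = self.mafs[i]
            v += 2.0 * p * (1.0 - p) * b * b
        return v


# ---------------------------------------------------------------------------
# trait model

def _polygenic_deviate(
    kin: KinshipMatrix, pedset: PedigreeSet, var: float, rng: np.random.Generator
) -> np.ndarray:
    """MVN(0, var * 2*Phi), drawn per pedigree block (cached Cholesky per shape)."""
    a = np.zeros(len(kin.ids))
    chol_cache: dict[bytes, np.ndarray] = {}
    for fid, members in pedset.pedigrees.items():
        rows = np.array([kin.index[m] for m in members])
        block = 2.0 * kin.phi[np.ix_(rows, rows)]
        key = block.tobytes()
        Lc = chol_cache.get(key)
        if Lc is None:
            w, Q = np.linalg.eigh(block)
            if w.min() < -1e-8:
                raise ValueError("2*Phi not positive semidefinite")
            Lc = Q * np.sqrt(np.clip(w, 0.0, None))
            chol_cache[key] = Lc
        a[rows] = Lc @ rng.standard_normal(rows.size)
    return np.sqrt(var) * a


def simulate_trait(
    genotypes: GenotypeMatrix,
    pedset: PedigreeSet,
    kin: KinshipMatrix,
    config: SimConfig,
    rng: np.random.Generator,
    linked_dosages: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw the raw trait and covariates for one replicate.

    ``linked_dosages`` are hidden causal loci co-segregating with the region
    (columns); their effect sizes are scaled to contribute ``linked_h2`` of
    variance.  Returns (per-exam trait array shaped (n, n_exams), covariates
    indexed like ``genotypes.samples``).
    """
    n = genotypes.n_samples
    y = np.zeros(n)
    for i, b in zip(config.causal_index, config.betas):
        g = genotypes.dosages[:, i]
        y += b * np.where(np.isfinite(g), g, 0.0)
    if config.linked_h2 > 0:
        if linked_dosages is None or linked_dosages.shape[1] != config.n_linked_loci:
            raise ValueError("linked_h2 > 0 requires linked_dosages columns")
        p = config.linked_maf
        beta_h = np.sqrt(config.linked_h2 / (config.n_linked_loci * 2 * p * (1 - p)))
        y += beta_h * (linked_dosages - 2 * p).sum(axis=1)
    unlinked = config.polygenic_h2 - config.linked_h2
    if unlinked > 0:
        rows = np.array([kin.index[s] for s in genotypes.samples])
        y += _polygenic_deviate(kin, pedset, unlinked, rng)[rows]
    env_var = 1.0 - config.polygenic_h2 - config.causal_variance()
    y += np.sqrt(env_var) * rng.standard_normal(n)

    age = rng.uniform(30.0, 70.0, n)
    sex = np.array([1.0 if pedset.persons[s].sex == 1 else 0.0 for s in genotypes.samples])
    y = y + 0.01 * (age - 50.0) + 0.1 * sex  # mild covariate leakage
    covars = pd.DataFrame({"age": age, "sex": sex}, index=pd.Index(genotypes.samples, name="iid"))
    if config.n_exams == 1:
        exams = y[:, None]
    else:
        exams = y[:, None] + config.measurement_sd * rng.standard_normal((n, config.n_exams))
    return exams, covars


def simulate_dataset(
    config: SimConfig, rng: np.random.Generator, pedset: PedigreeSet | None = None,
    kin: KinshipMatrix | None = None,
):
    """One replicate: genotypes (observed markers), raw per-exam trait, covariates."""
    if pedset is None:
        pedset = make_pedigrees(config.pedigree_template, config.n_pedigrees)
    if kin is None:
        kin = kinship(pedset)
    mafs = list(config.mafs)
    n_obs = len(mafs)
    linked_mode = config.linked_h2 > 0
    if linked_mode:
        mafs = mafs + [config.linked_maf] * config.n_linked_loci
    full = gene_drop(
        pedset,
        mafs,
        rng,
        linked=linked_mode,
        chrom=config.chrom,
        positions=np.arange(1, len(mafs) + 1) * 1000,
    )
    if linked_mode:
        linked_dosages = full.dosages[:, n_obs:]
        gm = GenotypeMatrix(
            samples=full.samples,
            variants=full.variants.iloc[:n_obs].copy(),
            dosages=full.dosages[:, :n_obs].copy(),
        )
    else:
        linked_dosages = None
        gm = full
    exams, covars = simulate_trait(gm, pedset, kin, config, rng, linked_dosages=linked_dosages)
    return gm, pedset, kin, exams, covars


# ---------------------------------------------------------------------------
# evaluation harness

@dataclass
class SimulationReport:
    table: pd.DataFrame
    config: SimConfig
    pvalues: pd.DataFrame | None = field(default=None, repr=False)

    def rate(self, method: str) -> float:
        return float(self.table.set_index("method").loc[method, "rate"])

    def count(self, method: str) -> int:
        return int(self.table.set_index("method").loc[method, "n_reject"])

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def _adjusted_trait(exams: np.ndarray, covars: pd.DataFrame) -> TraitVector:
    """Residualize each exam on age and sex, average across exams if several."""
    from .pheno import average_exams

    ids = list(covars.index)
    per_exam = {}
    for e in range(exams.shape[1]):
        raw = pd.Series(exams[:, e], index=covars.index)
        per_exam[str(e + 1)] = residualize(raw, covars[["age", "sex"]], exam=str(e + 1))
    if len(per_exam) == 1:
        return next(iter(per_exam.values()))
    return average_exams(per_exam)


def run_experiment(config: SimConfig, methods: list[str]) -> SimulationReport:
    """Rejection rates at the nominal level over ``config.n_replicates`` cohorts.

    Deterministic given ``config.seed``: replicate r uses the generator
    seeded with (seed, r).  A method failure in a replicate is recorded as NA
    and excluded from that method's denominator.
    """
    for m in methods:
        if m not in _methods.ALL_METHODS:
            raise ValueError(f"unknown method {m!r}")
    pedset = make_pedigrees(config.pedigree_template, config.n_pedigrees)
    kin = kinship(pedset)
    unrelated = select_unrelated(pedset, "founders_only")
    design = None
    rows = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, rep])
        gm, _, _, exams, covars = simulate_dataset(config, rng, pedset=pedset, kin=kin)
        trait = _adjusted_trait(exams, covars)
        tmap = dict(zip(trait.ids, trait.values))
        if design is None:
            design = build_family_design(pedset, gm.samples)
        scores = None
        if any(m in _methods.FAMILY_METHODS for m in methods):
            scores = build_region_scores(gm, pedset, trait, design=design)
        rec = {}
        for m in methods:
            try:
                rec[m] = _methods.run_method(
                    m,
                    genotypes=gm,
                    pedset=pedset,
                    trait=trait,
                    scores=scores,
                    unrelated=unrelated,
                    trait_map=tmap,
                    n_perm=config.n_perm,
                    rng=rng,
                )
            except Exception:
                rec[m] = np.nan
        rows.append(rec)
    pvals = pd.DataFrame(rows)
    out = []
    for m in methods:
        p = pvals[m]
        valid = p.notna()
        k = int((p[valid] < config.alpha).sum())
        n = int(valid.sum())
        lo, hi = _clopper_pearson(k, n) if n else (np.nan, np.nan)
        out.append(
            {
                "method": m,
                "n_reject": k,
                "n_valid": n,
                "n_failed": int((~valid).sum()),
                "rate": k / n if n else np.nan,
                "ci_low": lo,
                "ci_high": hi,
                "alpha": config.alpha,
                "n_replicates": config.n_replicates,
                "seed": config.seed,
            }
        )
    return SimulationReport(table=pd.DataFrame(out), config=config, pvalues=pvals)


# ---------------------------------------------------------------------------
# scenario presets

#: indices (into MAP4_MAFS) of the causal markers in the power scenarios:
#: the five rarest polymorphic loci plus three common ones — the region's
#: signal mixes rare and common causal variants.
CAUSAL_INDEX = (4, 7, 9, 12, 13, 23, 10, 14)

#: per-variant share of trait variance explained in the power presets
POWER_REGION_H2 = 0.12


def _power_betas(mixed_signs: bool) -> tuple[float, ...]:
    share = POWER_REGION_H2 / len(CAUSAL_INDEX)
    betas = []
    for j, i in enumerate(CAUSAL_INDEX):
        p = MAP4_MAFS[i]
        b = np.sqrt(share / (2 * p * (1 - p)))
        if mixed_signs and j % 2 == 1:
            b = -b
        betas.append(float(b))
    return tuple(betas)


def preset_q1like(
    seed: int = 0, template: str = "trio", n_pedigrees: int = 200, n_replicates: int = 200
) -> SimConfig:
    """Null trait with the Q1 heritability (62.8%), part of it linked to the region.

    No marker has a direct effect; 0.3 of the heritability comes from hidden
    loci co-segregating with the region (linkage without association) and the
    rest from an unlinked pedigree-correlated polygenic component.  On trio
    pedigrees every test is exactly valid; on the 'threegen' template the
    model-based family variance under-counts and inflates, which is what the
    empirical variance corrects.
    """
    return SimConfig(
        pedigree_template=template,
        n_pedigrees=n_pedigrees,
        mafs=MAP4_MAFS,
        polygenic_h2=0.628,
        linked_h2=0.3,
        n_replicates=n_replicates,
        n_perm=200,
        seed=seed,
    )


def preset_map4like(
    seed: int = 0,
    mixed_signs: bool = False,
    n_pedigrees: int = 200,
    n_replicates: int = 200,
) -> SimConfig:
    """Power scenario: 28 markers at the printed MAFs, 8 causal (5 rare + 3 common).

    ``mixed_signs`` flips every other causal effect to negative, the regime
    where direction-agnostic tests beat burden collapse.
    """
    return SimConfig(
        pedigree_template="trio",
        n_pedigrees=n_pedigrees,
        mafs=MAP4_MAFS,
        causal_index=CAUSAL_INDEX,
        betas=_power_betas(mixed_signs),
        polygenic_h2=0.3,
        linked_h2=0.0,
        n_replicates=n_replicates,
        n_perm=200,
        seed=seed,
    )
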