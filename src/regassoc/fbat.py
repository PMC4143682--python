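"""Family-based region association tests for quantitative traits.

The engine conditions on parental genotypes: under the null hypothesis of no
association, each offspring's marker genotype is a Mendelian draw given its
parents, so the score

    U_im = sum_j T_j (x_jm - e_jm)

(offspring j of nuclear family i, marker m, trait residual T, conditional
mean e = E[x | parents]) has expectation zero by construction, whatever the
trait values.  Four region tests are built on these scores:

* ``fbat_v``  — burden: markers collapsed by unweighted sum per offspring
  before scoring; normal Z test.
* ``fbat_m``  — multivariate: quadratic form U' V^- U, chi-square with df =
  rank(V).
* ``fbat_l``  — linear combination: marker weights estimated from
  between-family information (trait vs conditional-mean genotype, plus
  parent-only genotypes), which is independent of the transmissions that
  drive U under the null.
* ``fbat_lmm`` — variance-component style: sum over markers of squared total
  scores, direction-agnostic; p-value by Mendelian re-draw permutations.

Each of v/m/l supports a model-based variance (valid when nuclear families
are independent) and an empirical variance that aggregates scores within
pedigrees before taking outer products — the robust choice for extended
pedigrees with correlated phenotypes or linkage.

Missing data policy: a family is noninformative at a marker when either
parent is ungenotyped there; offspring with missing genotype (or a Mendelian
inconsistency) contribute nothing at that marker.  Genotypes are never
imputed here.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import GenotypeMatrix
from .pedigree import PedigreeSet, decompose_nuclear
from .pheno import TraitVector

__all__ = [
    "conditional_distribution",
    "build_region_scores",
    "empirical_variance",
    "fbat_v",
    "fbat_m",
    "fbat_l",
    "fbat_lmm",
    "RegionTestResult",
    "RegionSkipped",
]

PINV_RTOL = 1e-8


class RegionSkipped(RuntimeError):
    """No informative family (or marker) in the region: statistic undefined."""


@dataclass
class RegionTestResult:
    method: str
    statistic: float
    p_value: float
    df: float | None = None
    variance_mode: str = "model"
    n_informative_families: int = 0
    n_markers_used: int = 0
    extras: dict = field(default_factory=dict)


def conditional_distribution(father_dosage, mother_dosage):
    """Mendelian offspring-dosage distribution given parental dosages.

    Each parent transmits the minor allele with probability dosage/2; the
    offspring dosage is the sum of the two independent transmissions.
    Returns (probs over {0,1,2}, mean, variance).  A missing parent yields
    the noninformative sentinel (None, nan, nan).
    """
    f, m = father_dosage, mother_dosage
    if f is None or m is None or not (np.isfinite(f) and np.isfinite(m)):
        return None, np.nan, np.nan
    if f not in (0, 1, 2) or m not in (0, 1, 2):
        raise ValueError(f"parental dosages must be in {{0,1,2}}: ({f},{m})")
    pf, pm = f / 2.0, m / 2.0
    probs = np.array(
        [
            (1 - pf) * (1 - pm),
            pf * (1 - pm) + pm * (1 - pf),
            pf * pm,
        ]
    )
    mean = pf + pm
    var = pf * (1 - pf) + pm * (1 - pm)
    return probs, mean, var


# ---------------------------------------------------------------------------
# region scores

@dataclass
class FamilyDesign:
    """Index arrays tying a pedigree set to a genotype sample ordering.

    Precomputable once per (pedigree, sample-order) pair and reused across
    simulation replicates; row index -1 marks an ungenotyped person.
    """

    fam_ped: list[str]
    off_row: np.ndarray
    fat_row: np.ndarray
    mot_row: np.ndarray
    off_fam: np.ndarray
    off_iid: list[str]
    ped_code: np.ndarray          # per family, integer pedigree code
    parent_only_row: np.ndarray   # rows of persons acting only as parents
    n_families_total: int


def build_family_design(pedset: PedigreeSet, samples: list[str]) -> FamilyDesign:
    row_of = {s: i for i, s in enumerate(samples)}
    fams = decompose_nuclear(pedset)
    fam_ped, fat, mot, ped_codes = [], [], [], []
    off_row, off_fam, off_iid = [], [], []
    ped_code_of: dict[str, int] = {}
    offspring_ids = set()
    for k, fam in enumerate(fams):
        fam_ped.append(fam.pedigree_id)
        fat.append(row_of.get(fam.father, -1))
        mot.append(row_of.get(fam.mother, -1))
        ped_codes.append(ped_code_of.setdefault(fam.pedigree_id, len(ped_code_of)))
        for kid in fam.offspring:
            offspring_ids.add(kid)
            off_row.append(row_of.get(kid, -1))
            off_fam.append(k)
            off_iid.append(kid)
    parents = {f.father for f in fams} | {f.mother for f in fams}
    parent_only = sorted(p for p in parents - offspring_ids if p in row_of)
    return FamilyDesign(
        fam_ped=fam_ped,
        off_row=np.asarray(off_row, dtype=int),
        fat_row=np.asarray(fat, dtype=int),
        mot_row=np.asarray(mot, dtype=int),
        off_fam=np.asarray(off_fam, dtype=int),
        off_iid=off_iid,
        ped_code=np.asarray(ped_codes, dtype=int),
        parent_only_row=np.asarray([row_of[p] for p in parent_only], dtype=int),
        n_families_total=len(fams),
    )


@dataclass
class RegionScores:
    """Per-family score vectors and everything the four tests need."""

    markers: list[str]
    U: np.ndarray              # (n_fam, M) family score vectors
    Vdiag: np.ndarray          # (n_fam, M) model-based per-marker variances
    ped_code: np.ndarray       # (n_fam,)
    # offspring-level detail (permutations, weights)
    off_T: np.ndarray
    off_e: np.ndarray          # (n_off, M)
    off_probs: np.ndarray      # (n_off, M, 3) conditional genotype probabilities
    off_mask: np.ndarray       # (n_off, M) contribution usable
    off_x: np.ndarray
    # between-family weight-estimation data (NaN = unusable)
    est_T: np.ndarray
    est_pred: np.ndarray       # (n_est, M)
    n_informative_families: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def _as_trait_map(trait) -> dict[str, float]:
    if isinstance(trait, TraitVector):
        return dict(zip(trait.ids, trait.values))
    if hasattr(trait, "items"):
        return dict(trait.items())
    # pandas Series
    return {str(k): float(v) for k, v in trait.items()}


def build_region_scores(
    genotypes: GenotypeMatrix,
    pedset: PedigreeSet,
    trait,
    markers: list[str] | None = None,
    design: FamilyDesign | None = None,
    center_trait_warn: bool = True,
) -> RegionScores:
    """Assemble FBAT family scores for a marker set.

    ``trait`` is a :class:`~regassoc.pheno.TraitVector`, mapping, or Series of
    adjusted residuals keyed by individual id.  Monomorphic markers are
    dropped; Mendelian-inconsistent offspring are excluded at the offending
    marker with a warning.  Raises :class:`RegionSkipped` when no informative
    family remains.
    """
    if markers is not None:
        gm = genotypes.subset_variants(markers)
    else:
        gm = genotypes
    D = gm.dosages
    poly = np.nanstd(D, axis=0) > 0
    if not poly.all():
        D = D[:, poly]
    marker_ids = [v for v, keep in zip(gm.variants["vid"], poly) if keep]
    if not marker_ids:
        raise RegionSkipped("no polymorphic marker in region")

    tmap = _as_trait_map(trait)
    tvals = np.full(len(gm.samples), np.nan)
    for i, s in enumerate(gm.samples):
        if s in tmap:
            tvals[i] = tmap[s]
    finite_t = tvals[np.isfinite(tvals)]
    if center_trait_warn and finite_t.size and abs(finite_t.mean()) > 0.05 * (finite_t.std() + 1e-12):
        warnings.warn("trait residuals are not centered; centering before scoring")
        tvals = tvals - finite_t.mean()

    if design is None:
        design = build_family_design(pedset, gm.samples)
    return _scores_from_design(design, D, tvals, marker_ids)


def _scores_from_design(
    design: FamilyDesign, D: np.ndarray, tvals: np.ndarray, marker_ids: list[str]
) -> RegionScores:
    M = D.shape[1]
    n_fam = design.n_families_total
    nan_row = np.full(M, np.nan)

    def row(i):
        return D[i] if i >= 0 else nan_row

    F = np.vstack([row(i) for i in design.fat_row]) if n_fam else np.empty((0, M))
    Mo = np.vstack([row(i) for i in design.mot_row]) if n_fam else np.empty((0, M))
    X = np.vstack([row(i) for i in design.off_row]) if design.off_row.size else np.empty((0, M))
    T = np.array([tvals[i] if i >= 0 else np.nan for i in design.off_row])

    Ff, Mf = F[design.off_fam], Mo[design.off_fam]
    pf, pm = Ff / 2.0, Mf / 2.0
    e = pf + pm
    v = pf * (1 - pf) + pm * (1 - pm)
    mask = np.isfinite(Ff) & np.isfinite(Mf) & np.isfinite(X) & np.isfinite(T)[:, None]
    # Mendelian consistency: offspring count within attainable range
    with np.errstate(invalid="ignore"):
        lo = (Ff == 2).astype(float) + (Mf == 2)
        hi = (Ff > 0).astype(float) + (Mf > 0)
        viol = mask & ((X < lo) | (X > hi))
    if viol.any():
        warnings.warn(f"excluding {int(viol.sum())} Mendelian-inconsistent offspring-marker calls")
        mask &= ~viol

    diff = np.where(mask, X - e, 0.0)
    vm = np.where(mask, v, 0.0)
    Tz = np.where(np.isfinite(T), T, 0.0)
    U = np.zeros((n_fam, M))
    Vd = np.zeros((n_fam, M))
    np.add.at(U, design.off_fam, Tz[:, None] * diff)
    np.add.at(Vd, design.off_fam, (Tz**2)[:, None] * vm)

    informative = Vd.sum(axis=1) > 0
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise RegionSkipped("no informative family in region")

    # between-family weight-estimation data: offspring conditional means where
    # parents are observed, plus observed genotypes of parent-only persons
    pred_off = np.where(np.isfinite(Ff) & np.isfinite(Mf), e, np.nan)
    keep_off = np.isfinite(T)
    est_pred = [pred_off[keep_off]]
    est_T = [T[keep_off]]
    if design.parent_only_row.size:
        pt = tvals[design.parent_only_row]
        pg = D[design.parent_only_row]
        ok = np.isfinite(pt)
        est_pred.append(pg[ok])
        est_T.append(pt[ok])
    probs = np.stack(
        [(1 - pf) * (1 - pm), pf * (1 - pm) + pm * (1 - pf), pf * pm], axis=-1
    )
    probs = np.where(mask[..., None], probs, np.nan)

    return RegionScores(
        markers=marker_ids,
        U=U,
        Vdiag=Vd,
        ped_code=design.ped_code,
        off_T=Tz,
        off_e=np.where(mask, e, 0.0),
        off_probs=probs,
        off_mask=mask,
        off_x=np.where(mask, X, 0.0),
        est_T=np.concatenate(est_T) if est_T else np.empty(0),
        est_pred=np.vstack(est_pred) if est_pred else np.empty((0, M)),
        n_informative_families=n_inf,
        diagnostics={
            "n_families_total": n_fam,
            "n_families_skipped": n_fam - n_inf,
            "n_offspring": int(design.off_row.size),
        },
    )


# ---------------------------------------------------------------------------
# variances and tests

def empirical_variance(
    scores, aggregate_by_pedigree: bool = True, ped_codes=None
) -> np.ndarray:
    """Robust score variance: sum of per-unit outer products.

    With ``aggregate_by_pedigree`` the per-family score vectors are summed
    within each pedigree first, which is what protects the tests in extended
    pedigrees (correlated phenotypes, linkage).  Scores have null expectation
    zero by construction, so no centering is applied.  Requires at least two
    aggregation units.  Plain arrays may be passed with explicit
    ``ped_codes`` (default: every family its own pedigree).
    """
    if isinstance(scores, RegionScores):
        U, ped = scores.U, scores.ped_code
    else:
        U = np.asarray(scores, dtype=float)
        ped = np.asarray(ped_codes, dtype=int) if ped_codes is not None else np.arange(U.shape[0])
    if U.ndim == 1:
        U = U[:, None]
    if aggregate_by_pedigree:
        n_ped = int(ped.max()) + 1 if ped.size else 0
        agg = np.zeros((n_ped, U.shape[1]))
        np.add.at(agg, ped, U)
    else:
        agg = U
    if agg.shape[0] < 2:
        raise ValueError("empirical variance undefined with fewer than 2 aggregation units")
    return agg.T @ agg


def _two_sided_normal_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def fbat_v(scores: RegionScores, variance_mode: str = "model") -> RegionTestResult:
    """Unweighted burden test: markers collapsed per offspring before scoring."""
    Ub = scores.U.sum(axis=1)
    if variance_mode == "empirical":
        # aggregate family burden scores by pedigree before squaring
        n_ped = int(scores.ped_code.max()) + 1
        if n_ped < 2:
            raise ValueError("empirical variance needs >=2 pedigrees")
        agg = np.zeros(n_ped)
        np.add.at(agg, scores.ped_code, Ub)
        V = float((agg**2).sum())
    elif variance_mode == "model":
        V = float(scores.Vdiag.sum())
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    U = float(Ub.sum())
    if V <= 0:
        return RegionTestResult(
            method="fbat_v",
            statistic=np.nan,
            p_value=np.nan,
            variance_mode=variance_mode,
            n_informative_families=scores.n_informative_families,
            n_markers_used=scores.n_markers,
            extras={"diagnostic": "zero variance: statistic undefined"},
        )
    z = U / np.sqrt(V)
    return RegionTestResult(
        method="fbat_v",
        statistic=z,
        p_value=_two_sided_normal_p(z),
        variance_mode=variance_mode,
        n_informative_families=scores.n_informative_families,
        n_markers_used=scores.n_markers,
    )


def _variance_matrix(scores: RegionScores, variance_mode: str) -> np.ndarray:
    if variance_mode == "empirical":
        return empirical_variance(scores, aggregate_by_pedigree=True)
    if variance_mode == "model":
        # cross-marker conditional covariance assumed zero (independent
        # transmission across markers within a family; no-LD approximation)
        return np.diag(scores.Vdiag.sum(axis=0))
    raise ValueError(f"unknown variance_mode {variance_mode!r}")


def fbat_m(scores: RegionScores, variance_mode: str = "model") -> RegionTestResult:
    """Multivariate test: Q = U' V^- U, chi-square with df = rank(V)."""
    U = scores.U.sum(axis=0)
    V = _variance_matrix(scores, variance_mode)
    w, Q = np.linalg.eigh(V)
    lam_max = w.max() if w.size else 0.0
    keep = w > PINV_RTOL * max(lam_max, 1e-300)
    rank = int(keep.sum())
    if rank == 0:
        raise RegionSkipped("variance matrix has rank 0")
    Vinv = (Q[:, keep] / w[keep]) @ Q[:, keep].T
    stat = float(U @ Vinv @ U)
    p = float(stats.chi2.sf(stat, df=rank))
    return RegionTestResult(
        method="fbat_m",
        statistic=stat,
        df=rank,
        p_value=max(p, np.finfo(float).tiny),
        variance_mode=variance_mode,
        n_informative_families=scores.n_informative_families,
        n_markers_used=scores.n_markers,
    )


def estimate_weights(scores: RegionScores, min_n: int = 10) -> np.ndarray:
    """Between-family marker weights for the linear-combination test.

    For each marker, the sample covariance between the trait residual and the
    between-family genotype information (offspring conditional means plus
    parent-only genotypes).  Being a function of parental genotypes and
    traits only, the weights are independent of the within-family
    transmissions that randomize U under the null.  Markers whose estimation
    sample is smaller than ``min_n`` get weight 0.
    """
    M = scores.est_pred.shape[1]
    w = np.zeros(M)
    for m in range(M):
        ok = np.isfinite(scores.est_pred[:, m])
        n = int(ok.sum())
        if n < min_n:
            continue
        g = scores.est_pred[ok, m]
        t = scores.est_T[ok]
        if g.std() == 0:
            continue
        w[m] = float(np.cov(t, g, ddof=1)[0, 1])
    return w


def fbat_l(
    scores: RegionScores,
    variance_mode: str = "model",
    weights: np.ndarray | None = None,
) -> RegionTestResult:
    """Linear-combination test with between-family estimated weights."""
    fallback = False
    if weights is None:
        weights = estimate_weights(scores)
    weights = np.asarray(weights, dtype=float)
    if not np.any(weights):
        warnings.warn("all weights zero; falling back to unweighted burden")
        weights = np.ones(scores.n_markers)
        fallback = True
    U = float(weights @ scores.U.sum(axis=0))
    V = _variance_matrix(scores, variance_mode)
    denom = float(weights @ V @ weights)
    if denom <= 0:
        return RegionTestResult(
            method="fbat_l",
            statistic=np.nan,
            p_value=np.nan,
            variance_mode=variance_mode,
            n_informative_families=scores.n_informative_families,
            n_markers_used=scores.n_markers,
            extras={"diagnostic": "zero variance: statistic undefined"},
        )
    z = U / np.sqrt(denom)
    return RegionTestResult(
        method="fbat_l",
        statistic=z,
        p_value=_two_sided_normal_p(z),
        variance_mode=variance_mode,
        n_informative_families=scores.n_informative_families,
        n_markers_used=scores.n_markers,
        extras={"weights": weights, "unweighted_fallback": fallback},
    )


def _region_seed(markers: list[str]) -> int:
    return zlib.crc32("|".join(markers).encode()) & 0x7FFFFFFF


def fbat_lmm(
    scores: RegionScores,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RegionTestResult:
    """Variance-component style test with Mendelian re-draw permutations.

    Statistic Q = sum_m (sum_i U_im)^2: squaring per marker before summing
    makes the test direction-agnostic, so protective and deleterious effects
    within a region add instead of cancelling.  The null distribution is
    generated by redrawing every offspring's genotypes from the Mendelian
    conditional distribution given its parents (markers redrawn independently
    — the no-LD within-family approximation), and the p-value uses the
    add-one rule with ties counted as exceedances.

    Scores are taken per nuclear family without pedigree aggregation: like
    the original formulation, this test does not adjust for multiple nuclear
    families within an extended pedigree (flagged in the diagnostics).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else _region_seed(scores.markers))
    Utot = scores.U.sum(axis=0)
    q_obs = float((Utot**2).sum())
    T, e, mask = scores.off_T, scores.off_e, scores.off_mask
    probs = np.where(np.isfinite(scores.off_probs), scores.off_probs, 0.0)
    c0 = probs[..., 0]
    c01 = probs[..., 0] + probs[..., 1]
    n_off, M = e.shape
    exceed = 0
    chunk = max(1, int(4_000_000 / max(1, n_off * M)))
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        u = rng.random((c, n_off, M))
        x = (u >= c0).astype(float) + (u >= c01)
        diff = np.where(mask, x - e, 0.0)
        S = np.einsum("o,com->cm", T, diff)
        qs = (S**2).sum(axis=1)
        exceed += int((qs >= q_obs - 1e-12).sum())
        done += c
    p = (1.0 + exceed) / (1.0 + n_perm)
    return RegionTestResult(
        method="fbat_lmm",
        statistic=q_obs,
        p_value=p,
        variance_mode="permutation",
        n_informative_families=scores.n_informative_families,
        n_markers_used=scores.n_markers,
        extras={
            "n_perm": n_perm,
            "multi_family_pedigrees_not_adjusted": True,
        },
    )
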