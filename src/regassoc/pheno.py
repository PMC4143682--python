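"""Phenotype adjustment: covariate residualization, standardization, exam averaging.

Quantitative traits are adjusted before testing by regressing out covariates
(e.g. age, sex, age*sex, antihypertensive-medication use; or genotype
principal components) and standardizing the residuals to unit variance.  When
the phenotype was measured at several exams, residuals are computed per exam
and the per-person mean of the available exam residuals is re-standardized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["TraitVector", "residualize", "average_exams", "build_covariates"]


class DegenerateTraitError(ValueError):
    """Residual variance is (numerically) zero: the trait is fully explained."""


@dataclass
class TraitVector:
    """Standardized trait residuals for an ordered set of persons."""

    ids: list[str]
    values: np.ndarray
    exam: str = "1"
    n_exams_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("trait values must be finite")
        if len(self.ids) != self.values.size:
            raise ValueError("ids and values length mismatch")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.ids, name="iid"))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"iid": self.ids, "residual": self.values, "exam": self.exam})
        if self.n_exams_used is not None:
            df["n_exams_used"] = self.n_exams_used
        return df


def build_covariates(
    age: np.ndarray, sex: np.ndarray, meds: np.ndarray | None = None
) -> pd.DataFrame:
    """Standard adjustment design: age, sex (0/1), age*sex, optional meds (0/1)."""
    cols = {"age": np.asarray(age, float), "sex": np.asarray(sex, float)}
    cols["age_sex"] = cols["age"] * cols["sex"]
    if meds is not None:
        cols["meds"] = np.asarray(meds, float)
    return pd.DataFrame(cols)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # pivoted QR: columns whose pivot falls beyond the numerical rank
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[j] for j in piv[rank:]]


def residualize(
    raw_trait: pd.Series,
    covariates: pd.DataFrame | None,
    exam: str = "1",
) -> TraitVector:
    """Least-squares residuals of the trait on [1 | covariates], standardized.

    ``raw_trait`` is indexed by person id; ``covariates`` shares that index
    (persons with missing trait or covariates are dropped with a warning).
    Residuals are divided by their sample standard deviation, so the output
    has mean ~0 and sd 1.  A rank-deficient design raises an error naming the
    collinear columns; an exactly-explained trait raises
    :class:`DegenerateTraitError`.
    """
    y = raw_trait.dropna()
    if covariates is None or covariates.shape[1] == 0:
        ids = list(y.index)
        X = pd.DataFrame(index=y.index)
    else:
        joined = covariates.reindex(y.index)
        ok = joined.notna().all(axis=1)
        if not ok.all():
            warnings.warn(f"dropping {(~ok).sum()} persons with missing covariates")
        ids = list(y.index[ok])
        y = y.loc[ids]
        X = joined.loc[ids]
    design = sm.add_constant(X.to_numpy(dtype=float) if X.shape[1] else np.empty((len(ids), 0)))
    names = ["const"] + list(X.columns)
    if design.shape[0] <= design.shape[1]:
        raise ValueError("fewer observations than design columns")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    resid = sm.OLS(y.to_numpy(dtype=float), design).fit().resid
    sd = resid.std(ddof=1)
    if not np.isfinite(sd) or sd < 1e-12 * max(1.0, np.abs(y).max()):
        raise DegenerateTraitError("residual variance is zero after adjustment")
    return TraitVector(ids=ids, values=resid / sd, exam=exam)


def average_exams(trait_by_exam: dict[str, TraitVector]) -> TraitVector:
    """Per-person mean of available exam residuals, re-standardized.

    Persons present in at least one exam are retained (their mean uses the
    exams they have); the averaged values are standardized again so the
    output is a unit-variance trait tagged "average".
    """
    if not trait_by_exam:
        raise ValueError("no exams supplied")
    frames = [tv.as_series().rename(exam) for exam, tv in sorted(trait_by_exam.items())]
    wide = pd.concat(frames, axis=1)
    n_used = wide.notna().sum(axis=1).to_numpy()
    if (n_used == 0).any():
        warnings.warn("dropping persons with zero exams")
        wide = wide.loc[n_used > 0]
        n_used = n_used[n_used > 0]
    avg = wide.mean(axis=1)
    sd = avg.std(ddof=1)
    if sd < 1e-12:
        raise DegenerateTraitError("averaged residuals have zero variance")
    return TraitVector(
        ids=list(wide.index),
        values=((avg - avg.mean()) / sd).to_numpy(),
        exam="average",
        n_exams_used=n_used,
    )
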