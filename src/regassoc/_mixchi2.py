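"""Tail probabilities for positively weighted mixtures of 1-df chi-squares.

``P(sum_k lambda_k chi2_1 > q)`` is the null distribution of the kernel
score statistic.  The exact route is the Ruben–Farebrother expansion: with a
scale 0 < beta <= min(lambda) the mixture distribution equals an infinite
nonnegative mixture of central chi-square distributions,

    P(Q <= q) = sum_j a_j P(chi2_{k+2j} <= q / beta),

whose coefficients a_j sum to one, so the truncation error after J terms is
bounded by the untaken mass 1 - sum_{j<=J} a_j — the series is run until
that bound drops below tolerance.  Single or equal eigenvalues reduce to a
plain chi-square in closed form.  When the eigenvalue spread makes the
series converge too slowly, the kurtosis-matched noncentral chi-square
approximation of Liu, Tang & Zhang is used instead and flagged.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["mixture_chi2_sf", "ruben_sf", "liu_sf"]


def ruben_sf(
    q: float,
    lam: np.ndarray,
    tol: float = 1e-10,
    max_terms: int = 20000,
) -> tuple[float, float]:
    """Upper tail by the mixture-of-central-chi-squares series.

    Returns (p, error bound).  The error bound is rigorous: every term is a
    nonnegative mixture weight times a cdf value in [0, 1].
    """
    lam = np.asarray(lam, dtype=float)
    k = lam.size
    beta = 0.90625 * lam.min()  # conventional safe mixing scale
    t = 1.0 - beta / lam        # in [0, 1)
    x = q / beta

    # the mixture mass converges geometrically at rate max(t); bail out early
    # when the series cannot reach tolerance within the term budget
    t_max = float(t.max())
    if t_max > 0 and np.log(tol) / np.log(t_max) > max_terms:
        raise RuntimeError("mixture series converges too slowly for this eigenvalue spread")

    a0 = float(np.exp(0.5 * (k * np.log(beta) - np.log(lam).sum())))
    coeffs = np.zeros(max_terms + 1)
    b = np.zeros(max_terms + 1)
    coeffs[0] = a0
    t_pow = np.ones(k)
    cdf_sum = a0 * stats.chi2.cdf(x, df=k)
    mass = a0
    j = 0
    while mass < 1.0 - tol and j < max_terms:
        j += 1
        t_pow *= t
        b[j] = t_pow.sum()
        # a_j = (1/2j) * sum_{r<j} b_{j-r} a_r
        aj = 0.5 / j * float(b[1 : j + 1][::-1] @ coeffs[:j])
        coeffs[j] = aj
        mass += aj
        cdf_sum += aj * stats.chi2.cdf(x, df=k + 2 * j)
    bound = 1.0 - mass
    p = 1.0 - cdf_sum
    return float(p), float(bound)


def liu_sf(q: float, lam: np.ndarray) -> float:
    """Kurtosis-matched noncentral chi-square approximation to the mixture tail."""
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    mu_x = df + delta
    sigma_x = np.sqrt(2.0) * a
    return float(stats.ncx2.sf(t_star * sigma_x + mu_x, df, delta))


def mixture_chi2_sf(
    q: float, lam, min_lambda_ratio: float = 1e-10
) -> tuple[float, str]:
    """Tail probability of ``sum lambda_k chi2_1`` above ``q``.

    Eigenvalues at or below ``min_lambda_ratio`` times the largest are
    discarded (numerical zeros of a PSD matrix).  Returns ``(p, method)``
    with method "exact" (closed form), "ruben", or "liu" (fallback).
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0 or q <= 0:
        return (1.0, "exact")
    lam = lam[lam > min_lambda_ratio * lam.max()]
    if lam.size == 1:
        return (float(stats.chi2.sf(q / lam[0], df=1)), "exact")
    if np.allclose(lam, lam[0], rtol=1e-12):
        return (float(stats.chi2.sf(q / lam[0], df=lam.size)), "exact")
    try:
        p, bound = ruben_sf(q, lam)
    except Exception:
        return (liu_sf(q, lam), "liu")
    if not np.isfinite(p) or bound > 1e-7 or p < -1e-9:
        return (liu_sf(q, lam), "liu")
    return (float(min(max(p, np.finfo(float).tiny), 1.0)), "ruben")
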