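"""Spatial dependence diagnostics.

Global Moran's I with permutation inference and closed-form randomization
moments, the Moran scatter decomposition into HH/LH/LL/HL quadrants, and the
Lagrange-multiplier score tests for an omitted spatial lag (LM-Lag, null
ρ = 0) and spatially autocorrelated errors (LM-Error, null λ = 0) built from
OLS residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .weights import WeightMatrix

__all__ = ["MoranResult", "LMResult", "morans_i", "moran_permutation",
           "moran_scatter", "lm_lag", "lm_error"]


@dataclass
class MoranResult:
    i: float
    expected_i: float
    variance: float
    z: float
    p: float
    n_perm: int


@dataclass
class LMResult:
    statistic: float
    p: float
    test: str


def _deviations(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    z = y - y.mean()
    if np.all(z == 0):
        raise ValueError("y is constant; Moran's I is undefined")
    return z


def morans_i(y: np.ndarray, w: WeightMatrix) -> float:
    """Global Moran's I: (n/S₀)·ΣᵢΣⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ², z = y − ȳ."""
    z = _deviations(y)
    s0 = w.s0
    if s0 <= 0:
        raise ValueError("weight matrix has zero total weight")
    return float(len(z) / s0 * (z @ w.w @ z) / (z @ z))


def _randomization_moments(y: np.ndarray, w: WeightMatrix) -> tuple[float, float]:
    """Mean and variance of Moran's I under random permutation of y."""
    z = _deviations(y)
    n = z.size
    s0 = w.s0
    s1 = 0.5 * np.sum((w.w + w.w.T) ** 2)
    s2 = np.sum((w.w.sum(axis=1) + w.w.sum(axis=0)) ** 2)
    m2 = np.sum(z ** 2) / n
    m4 = np.sum(z ** 4) / n
    b2 = m4 / m2 ** 2
    e_i = -1.0 / (n - 1)
    num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
           - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0))
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i ** 2
    return e_i, var


def moran_permutation(y: np.ndarray, w: WeightMatrix, n_perm: int = 999,
                      seed: int = 0, alternative: str = "greater") -> MoranResult:
    """Moran's I with a seeded permutation test.

    The one-sided p-value (positive autocorrelation alternative, the default)
    is (1 + #{I_perm ≥ I_obs}) / (n_perm + 1); "two-sided" doubles the
    smaller tail.  The reported variance and z-score use the closed-form
    randomization moments.
    """
    z = _deviations(y)
    n = z.size
    obs = morans_i(y, w)
    rng = np.random.default_rng(seed)
    scale = n / w.s0 / (z @ z)
    perms = np.empty(n_perm)
    zp = z.copy()
    for b in range(n_perm):
        rng.shuffle(zp)
        perms[b] = scale * (zp @ w.w @ zp)
    ge = int(np.sum(perms >= obs))
    if alternative == "greater":
        p = (1 + ge) / (n_perm + 1)
    elif alternative == "two-sided":
        le = int(np.sum(perms <= obs))
        p = min(1.0, 2 * (1 + min(ge, le)) / (n_perm + 1))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    e_i, var = _randomization_moments(y, w)
    zscore = (obs - e_i) / np.sqrt(var)
    return MoranResult(i=obs, expected_i=e_i, variance=var, z=zscore, p=p,
                       n_perm=n_perm)


def moran_scatter(y: np.ndarray, w: WeightMatrix):
    """Per-unit deviations, spatial lags of deviations, and quadrant labels.

    Quadrants follow the signs of (yᵢ − ȳ, Σⱼwᵢⱼ(yⱼ − ȳ)): HH, LH, LL, HL;
    exact zeros count as "high" (HH-ward) by convention.  For row-standardized
    W the slope of lag on deviation equals Moran's I.
    """
    z = _deviations(y)
    lag = w.w @ z
    hi_z, hi_l = z >= 0, lag >= 0
    quad = np.where(hi_z & hi_l, "HH",
                    np.where(~hi_z & hi_l, "LH",
                             np.where(~hi_z & ~hi_l, "LL", "HL")))
    return z, lag, quad


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return beta, y - x @ beta


def _trace_t(w: np.ndarray) -> float:
    return float(np.trace(w @ w + w.T @ w))


def lm_lag(y: np.ndarray, x: np.ndarray, w: WeightMatrix) -> LMResult:
    """Score test for an omitted spatial lag (null ρ = 0), χ²₁ reference.

    LM = (eᵀWy/σ̃²)² / [ (WXβ̂)ᵀM(WXβ̂)/σ̃² + T ],  T = tr(W² + WᵀW),
    with e the OLS residuals, σ̃² = eᵀe/n, and M the annihilator of X.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    t_w = _trace_t(w.w)
    if t_w == 0:
        raise ValueError("weight matrix is zero; LM tests undefined")
    beta, e = _ols(y, x)
    s2 = (e @ e) / n
    wxb = w.w @ (x @ beta)
    _, m_wxb = _ols(wxb, x)
    denom = (wxb @ m_wxb) / s2 + t_w
    stat = (e @ (w.w @ y) / s2) ** 2 / denom
    return LMResult(statistic=float(stat), p=float(stats.chi2.sf(stat, 1)),
                    test="lag")


def lm_error(y: np.ndarray, x: np.ndarray, w: WeightMatrix) -> LMResult:
    """Score test for spatial error dependence (null λ = 0), χ²₁ reference.

    LM = (eᵀWe/σ̃²)² / tr(W² + WᵀW).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    t_w = _trace_t(w.w)
    if t_w == 0:
        raise ValueError("weight matrix is zero; LM tests undefined")
    _, e = _ols(y, x)
    s2 = (e @ e) / n
    stat = (e @ (w.w @ e) / s2) ** 2 / t_w
    return LMResult(statistic=float(stat), p=float(stats.chi2.sf(stat, 1)),
                    test="error")
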