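"""Truncated power spline basis for approximating the index function g.

The basis at a point t is (1, t, …, t^p, (t−k₁)₊^p, …, (t−k_l)₊^p) with
(x)₊ = max(x, 0) and the truncated term equal to zero when t ≤ k_j.  Knots are
placed at every ``step``-th order statistic of the observed index values, so
the knot set adapts to the distribution of t = uᵀα and is recomputed whenever
α changes.

The truncated power basis is notoriously ill-conditioned; every solver in this
package that touches it goes through an orthogonal-decomposition least-squares
path (LAPACK gelsd), never explicit normal equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TruncatedPowerBasis", "select_knots", "basis_row", "basis_matrix", "eval_g"]


@dataclass(frozen=True)
class TruncatedPowerBasis:
    """Knot set and polynomial order of a truncated power spline basis.

    dimension = order + 1 + n_knots (monomials 1..t^p plus one truncated
    term per knot).
    """

    knots: np.ndarray
    order: int = 3

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        object.__setattr__(self, "knots", knots)
        if self.order < 1:
            raise ValueError("spline order must be >= 1")
        if knots.size and np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")

    @property
    def dimension(self) -> int:
        return self.order + 1 + self.knots.size


def select_knots(t: np.ndarray, step: int = 10) -> np.ndarray:
    """Every ``step``-th order statistic of t, kept strictly inside (min, max).

    Order statistics at positions step, 2·step, … (1-based) are taken as
    knots; values coinciding with the sample minimum or maximum are dropped
    (a truncated term at the maximum is identically zero on the sample and
    one at the minimum duplicates the monomial span), and duplicates are
    collapsed so the result is strictly increasing.
    """
    t = np.sort(np.asarray(t, dtype=float))
    n = t.size
    if n <= step:
        raise ValueError("need more than `step` observations to place knots")
    cand = t[step - 1::step]
    cand = cand[(cand > t[0]) & (cand < t[-1])]
    knots = np.unique(cand)
    if knots.size == 0:
        raise ValueError("too few distinct values to place interior knots")
    return knots


def basis_matrix(t: np.ndarray, basis: TruncatedPowerBasis) -> np.ndarray:
    """Stack basis rows for a vector of index values: shape (n, dimension)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = basis.order
    mono = t[:, None] ** np.arange(p + 1)
    if basis.knots.size:
        trunc = np.maximum(t[:, None] - basis.knots[None, :], 0.0) ** p
        return np.hstack([mono, trunc])
    return mono


def basis_row(t: float, basis: TruncatedPowerBasis) -> np.ndarray:
    """Basis vector (1, t, …, t^p, (t−k₁)₊^p, …) at a single point."""
    return basis_matrix(np.array([t]), basis)[0]


def eval_g(t: np.ndarray, basis: TruncatedPowerBasis, delta: np.ndarray) -> np.ndarray:
    """Evaluate the spline approximation g(t) ≈ B(t)ᵀδ."""
    delta = np.asarray(delta, dtype=float)
    if delta.size != basis.dimension:
        raise ValueError(
            f"coefficient length {delta.size} != basis dimension {basis.dimension}")
    return basis_matrix(t, basis) @ delta
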