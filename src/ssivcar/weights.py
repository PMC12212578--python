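"""Spatial weight matrices.

Constructors for the connectivity structures used in spatial autoregressive
modelling: Rook and Bishop contiguity on a square grid, group-interaction
("Case") blocks, k-nearest-neighbour graphs on point sets, inverse-distance
kernels, and seeded random adjacency.  All constructors return a
:class:`WeightMatrix`, row-standardized by default so that the spatial lag
``W y`` is a neighbour average.

Serialization supports Matrix Market coordinate files (via scipy) and the
plain-text GAL neighbour-list format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import io as spio
from scipy import sparse
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "WeightMatrix",
    "rook_grid",
    "bishop_grid",
    "case_groups",
    "knn_points",
    "inverse_distance",
    "random_weights",
    "row_normalize",
    "read_weights",
    "write_weights",
]


@dataclass
class WeightMatrix:
    """An n×n nonnegative spatial connectivity matrix with zero diagonal.

    Attributes
    ----------
    w : ndarray
        Dense (n, n) array of nonnegative weights, zero diagonal.
    row_standardized : bool
        True if every row with at least one neighbour sums to 1.
    kind : str
        Free-text label (rook, bishop, case, knn, distance, random, custom).
    """

    w: np.ndarray
    row_standardized: bool = False
    kind: str = "custom"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diagonal(self.w) != 0):
            raise ValueError("diagonal must be zero (no self-neighbours)")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def s0(self) -> float:
        """Total sum of weights, the normalizer of global Moran's I."""
        return float(self.w.sum())

    def neighbours(self, i: int) -> np.ndarray:
        return np.nonzero(self.w[i])[0]

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, WeightMatrix):
            return NotImplemented
        return self.w.shape == other.w.shape and np.array_equal(self.w, other.w)


def _standardize(w: np.ndarray) -> tuple[np.ndarray, bool]:
    rs = w.sum(axis=1)
    nz = rs > 0
    out = w.copy()
    out[nz] = out[nz] / rs[nz, None]
    if not np.all(nz):
        logger.warning("%d row(s) have no neighbours; left with zero row sum",
                       int((~nz).sum()))
    return out, True


def row_normalize(wm: WeightMatrix) -> WeightMatrix:
    """Divide every nonzero row by its sum.  Idempotent."""
    w, _ = _standardize(wm.w)
    return WeightMatrix(w, row_standardized=True, kind=wm.kind)


def _grid_adjacency(h: int, offsets: list[tuple[int, int]]) -> np.ndarray:
    n = h * h
    w = np.zeros((n, n))
    for i in range(n):
        r, c = divmod(i, h)
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < h:
                w[i, rr * h + cc] = 1.0
    return w


def rook_grid(h: int, standardize: bool = True) -> WeightMatrix:
    """Rook (edge-sharing) contiguity on an h×h square grid, n = h²."""
    if h < 1:
        raise ValueError("h must be >= 1")
    w = _grid_adjacency(h, [(-1, 0), (1, 0), (0, -1), (0, 1)])
    if standardize:
        w, _ = _standardize(w)
    return WeightMatrix(w, row_standardized=standardize, kind="rook")


def bishop_grid(h: int, standardize: bool = True) -> WeightMatrix:
    """Bishop (corner-sharing) contiguity on an h×h square grid."""
    if h < 1:
        raise ValueError("h must be >= 1")
    w = _grid_adjacency(h, [(-1, -1), (-1, 1), (1, -1), (1, 1)])
    if standardize:
        w, _ = _standardize(w)
    return WeightMatrix(w, row_standardized=standardize, kind="bishop")


def case_groups(r: int = 3, m_members: int = 75) -> WeightMatrix:
    """Group-interaction ("Case") weights: r equal groups of m_members.

    Units interact equally within their group with weight 1/(m_members − 1),
    never across groups; the matrix is row-stochastic by construction.
    Defaults give n = 225.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if m_members < 2:
        raise ValueError("group size must be >= 2")
    block = np.full((m_members, m_members), 1.0 / (m_members - 1))
    np.fill_diagonal(block, 0.0)
    w = np.kron(np.eye(r), block)
    return WeightMatrix(w, row_standardized=True, kind="case")


def knn_points(points: np.ndarray, k: int, standardize: bool = True) -> WeightMatrix:
    """k-nearest-neighbour adjacency on a 2-D point set (Euclidean).

    Each row links to its k closest other points with weight 1 before
    standardization (1/k after).  Ties in distance are broken toward the
    smaller unit index; the matrix is generally asymmetric.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    if k < 1 or k >= n:
        raise ValueError("require 1 <= k < n")
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    # stable argsort breaks distance ties by smaller index
    order = np.argsort(d, axis=1, kind="stable")
    w = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    w[rows, order[:, :k].ravel()] = 1.0
    if standardize:
        w, _ = _standardize(w)
    return WeightMatrix(w, row_standardized=standardize, kind="knn")


def inverse_distance(points: np.ndarray, standardize: bool = True) -> WeightMatrix:
    """Dense inverse-Euclidean-distance weights w_ij = 1/d_ij, row-standardized."""
    pts = np.asarray(points, dtype=float)
    d = cdist(pts, pts)
    off = ~np.eye(len(pts), dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident points give infinite inverse distance")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    if standardize:
        w, _ = _standardize(w)
    return WeightMatrix(w, row_standardized=standardize, kind="distance")


def random_weights(n: int, density: float | None = None, seed: int = 0,
                   standardize: bool = True) -> WeightMatrix:
    """Seeded Bernoulli(density) off-diagonal adjacency.

    Default density 4/(n−1) targets an expected degree of 4, comparable to
    Rook contiguity.  Rows that draw no neighbour are kept with zero row sum.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if density is None:
        density = 4.0 / (n - 1)
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    w = (rng.random((n, n)) < density).astype(float)
    np.fill_diagonal(w, 0.0)
    if standardize:
        w, _ = _standardize(w)
    return WeightMatrix(w, row_standardized=standardize, kind="random")


# ---------------------------------------------------------------------------
# serialization


def write_weights(wm: WeightMatrix, path, fmt: str = "mtx") -> None:
    """Write a weight matrix as Matrix Market coordinate (.mtx) or GAL text."""
    if fmt == "mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(wm.w))
    elif fmt == "gal":
        lines = [str(wm.n)]
        for i in range(wm.n):
            nb = wm.neighbours(i)
            lines.append(f"{i + 1} {len(nb)}")
            lines.append(" ".join(str(j + 1) for j in nb))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_weights(path, fmt: str = "mtx") -> WeightMatrix:
    """Read a weight matrix from .mtx or GAL.

    GAL stores binary adjacency only; Matrix Market preserves the weights
    (explicit zeros are dropped).  Raises on negative weights or neighbour
    indices out of range.
    """
    if fmt == "mtx":
        m = spio.mmread(str(path))
        w = np.asarray(m.todense() if sparse.issparse(m) else m, dtype=float)
        if np.any(w < 0):
            raise ValueError("negative weight in file")
        rs = bool(np.all(np.isclose(w.sum(axis=1)[w.sum(axis=1) > 0], 1.0, atol=1e-12)))
        return WeightMatrix(w, row_standardized=rs, kind="custom")
    if fmt == "gal":
        with open(path) as fh:
            lines = fh.read().splitlines()
        header = lines[0].split()
        n = int(header[-1]) if len(header) > 1 else int(header[0])
        w = np.zeros((n, n))
        # each unit occupies two lines: "unit degree" then the neighbour list
        # (an empty line when the unit has no neighbours)
        for u in range(n):
            head = lines[1 + 2 * u].split()
            unit, deg = int(head[0]), int(head[1])
            if not 1 <= unit <= n:
                raise ValueError(f"unit index {unit} out of range 1..{n}")
            nbrs = [int(v) for v in lines[2 + 2 * u].split()]
            if len(nbrs) != deg:
                raise ValueError("neighbour count mismatch in GAL file")
            for j in nbrs:
                if not 1 <= j <= n:
                    raise ValueError(f"neighbour index {j} out of range 1..{n}")
                w[unit - 1, j - 1] = 1.0
        return WeightMatrix(w, row_standardized=False, kind="custom")
    raise ValueError(f"unknown format {fmt!r}")
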