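"""Spatial weight constructors, invariants, and serialization."""

import numpy as np
import pytest

import ssivcar as sv


ALL_CONSTRUCTORS = [
    lambda: sv.rook_grid(4),
    lambda: sv.bishop_grid(4),
    lambda: sv.case_groups(2, 8),
    lambda: sv.knn_points(sv.disk_coordinates(30, seed=3), k=4),
    lambda: sv.inverse_distance(sv.grid_coordinates(4)),
    lambda: sv.random_weights(30, density=0.2, seed=7),
]


@pytest.mark.parametrize("make", ALL_CONSTRUCTORS)
def test_constructor_invariants(make):
    wm = make()
    assert np.all(np.diagonal(wm.w) == 0)
    assert np.all(wm.w >= 0)
    rs = wm.w.sum(axis=1)
    nz = rs > 0
    assert np.allclose(rs[nz], 1.0, atol=1e-12)


def test_rook_grid_examples():
    assert np.all(sv.rook_grid(1).w == 0)
    w2 = sv.rook_grid(2)
    assert np.all((w2.w > 0).sum(axis=1) == 2)
    assert np.all(w2.w[w2.w > 0] == 0.5)
    assert sv.rook_grid(15).n == 225


def test_bishop_grid_examples():
    assert np.all(sv.bishop_grid(1).w == 0)
    w2 = sv.bishop_grid(2)
    assert np.all((w2.w > 0).sum(axis=1) == 1)
    assert np.all(w2.w[w2.w > 0] == 1.0)
    # corner of a 3x3 grid touches only the centre cell diagonally
    w3 = sv.bishop_grid(3)
    assert w3.neighbours(0).tolist() == [4]


@pytest.mark.parametrize("h", range(2, 7))
def test_rook_bishop_supports_disjoint(h):
    rook = sv.rook_grid(h, standardize=False)
    bishop = sv.bishop_grid(h, standardize=False)
    assert not np.any((rook.w > 0) & (bishop.w > 0))


def test_case_groups():
    assert np.array_equal(sv.case_groups(1, 2).w, [[0, 1], [1, 0]])
    wm = sv.case_groups(3, 75)
    assert wm.n == 225
    assert np.allclose(wm.w.sum(axis=1), 1.0)
    # no cross-group links
    assert np.all(wm.w[:75, 75:] == 0)
    with pytest.raises(ValueError):
        sv.case_groups(2, 1)


def test_knn_examples():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
    wm = sv.knn_points(pts, k=1)
    assert wm.neighbours(0).tolist() == [1]
    assert wm.neighbours(2).tolist() == [1]
    assert not np.array_equal(wm.w, wm.w.T)  # asymmetric
    # k = n-1: all other units are neighbours with equal weight
    full = sv.knn_points(pts, k=2)
    off = ~np.eye(3, dtype=bool)
    assert np.allclose(full.w[off], 0.5)
    with pytest.raises(ValueError):
        sv.knn_points(pts, k=0)
    with pytest.raises(ValueError):
        sv.knn_points(pts, k=3)


def test_knn_row_counts():
    pts = sv.disk_coordinates(40, seed=11)
    for k in (1, 3, 6):
        wm = sv.knn_points(pts, k)
        assert np.all((wm.w > 0).sum(axis=1) == k)
        assert np.allclose(wm.w[wm.w > 0], 1.0 / k)


def test_inverse_distance():
    two = sv.inverse_distance(np.array([[0.0, 0.0], [5.0, 0.0]]))
    assert np.allclose(two.w, [[0, 1], [1, 0]])
    three = sv.inverse_distance(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))
    assert np.allclose(three.w[1], [0.5, 0.0, 0.5])
    with pytest.raises(ValueError):
        sv.inverse_distance(np.array([[0.0, 0.0], [0.0, 0.0]]))


def test_random_weights():
    full = sv.random_weights(10, density=1.0, seed=0)
    off = ~np.eye(10, dtype=bool)
    assert np.allclose(full.w[off], 1.0 / 9)
    a = sv.random_weights(50, density=0.1, seed=42)
    b = sv.random_weights(50, density=0.1, seed=42)
    assert np.array_equal(a.w, b.w)
    big = sv.random_weights(225, density=0.02, seed=1)
    rs = big.w.sum(axis=1)
    assert np.all(np.isclose(rs, 0.0) | np.isclose(rs, 1.0))


def test_row_normalize():
    wm = sv.WeightMatrix(np.array([[0.0, 2.0], [3.0, 0.0]]))
    std = sv.row_normalize(wm)
    assert np.allclose(std.w, [[0, 1], [1, 0]])
    assert np.array_equal(sv.row_normalize(std).w, std.w)  # idempotent
    zero = sv.row_normalize(sv.WeightMatrix(np.zeros((3, 3))))
    assert np.all(zero.w == 0)


@pytest.mark.parametrize("fmt", ["mtx", "gal"])
def test_serialization_round_trip(tmp_path, fmt):
    wm = sv.rook_grid(3, standardize=(fmt == "mtx"))
    path = tmp_path / f"w.{fmt}"
    sv.write_weights(wm, path, fmt=fmt)
    back = sv.read_weights(path, fmt=fmt)
    assert np.allclose(back.w, wm.w, atol=1e-15)


def test_gal_bad_neighbour_index(tmp_path):
    path = tmp_path / "bad.gal"
    path.write_text("2\n1 1\n3\n2 0\n\n")
    with pytest.raises(ValueError):
        sv.read_weights(path, fmt="gal")


def test_mtx_explicit_zeros(tmp_path):
    path = tmp_path / "z.mtx"
    path.write_text("%%MatrixMarket matrix coordinate real general\n"
                    "2 2 2\n1 2 1.0\n2 1 0.0\n")
    wm = sv.read_weights(path, fmt="mtx")
    assert wm.w[0, 1] == 1.0 and wm.w[1, 0] == 0.0
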