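"""SSIVCAR estimator: parameterization, 2SLS stages, profile loss, full fit."""

import numpy as np
import pytest

import ssivcar as sv
from ssivcar.estimator import (FitOptions, _PHI_BALL, _profile_fit,
                               alpha_from_phi, phi_from_alpha)
from ssivcar.splines import TruncatedPowerBasis, basis_matrix, select_knots

OPTS = FitOptions()


def cubic_g(t):
    # bounded on the index range of a 10x10 half-unit grid, exactly
    # representable by the cubic truncated power basis
    return 0.5 - 0.1 * t + 0.01 * t ** 2


@pytest.fixture(scope="module")
def noise_free():
    design = sv.SimulationDesign(h=10, g=cubic_g, sigma2=1e-30)
    return design, sv.simulate(design, seed=2)


def test_index_parameterization_round_trip():
    for phi in ([0.3], [0.86], [-0.5, 0.2]):
        alpha = alpha_from_phi(np.array(phi))
        assert abs(np.linalg.norm(alpha) - 1) < 1e-12
        assert alpha[0] >= 0
        assert np.allclose(phi_from_alpha(alpha), phi)
    # negative leading component maps to its identified representative
    assert np.allclose(phi_from_alpha(np.array([-0.6, -0.8])), [0.8])
    with pytest.raises(ValueError):
        alpha_from_phi(np.array([0.8, 0.8]))


def test_build_instruments_zero_weights():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((30, 2))
    u = rng.standard_normal((30, 2))
    q = sv.build_instruments(x, np.zeros((30, 30)), u)
    # only the covariates survive; spatial transforms are all zero columns
    assert q.shape[1] == 2
    proj = x @ np.linalg.lstsq(x, q, rcond=None)[0]
    assert np.allclose(proj, q, atol=1e-10)


def test_build_instruments_duplicate_column_dropped():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((40, 2))
    x_dup = np.column_stack([x, x[:, 0]])
    w = sv.knn_points(rng.standard_normal((40, 2)), 3).w
    u = rng.standard_normal((40, 2))
    q_plain = sv.build_instruments(x, w, u)
    q_dup = sv.build_instruments(x_dup, w, u)
    # the duplicated covariate (and its spatial transforms) contribute
    # nothing new: the filtered instrument set is unchanged in size and span
    assert q_dup.shape[1] == q_plain.shape[1]
    assert np.linalg.matrix_rank(np.hstack([q_plain, q_dup])) == q_plain.shape[1]


def test_build_instruments_study_design(grid_dataset):
    q = sv.build_instruments(grid_dataset.x, grid_dataset.w.w, grid_dataset.u)
    assert q.shape[1] == 10  # X(2) + WX(2) + W²X(2) + WU(2) + W²U(2)


def test_first_stage_projection_identities(grid_dataset):
    q = sv.build_instruments(grid_dataset.x, grid_dataset.w.w, grid_dataset.u)
    wy = grid_dataset.w.w @ grid_dataset.y
    wy_hat = sv.first_stage(q, wy)
    # idempotence
    assert np.max(np.abs(sv.first_stage(q, wy_hat) - wy_hat)) < 1e-10
    # already in span -> unchanged
    v = q @ np.arange(1.0, q.shape[1] + 1)
    assert np.max(np.abs(sv.first_stage(q, v) - v)) < 1e-8
    # normal-equations oracle
    oracle = q @ np.linalg.solve(q.T @ q, q.T @ wy)
    assert np.max(np.abs(wy_hat - oracle)) < 1e-8


def test_second_stage_noise_free_recovery(noise_free):
    design, ds = noise_free
    wy = ds.w.w @ ds.y
    t = ds.u @ design.alpha
    basis = TruncatedPowerBasis(select_knots(t, 10), 3)
    b = basis_matrix(t, basis)
    # exact fitted lag: the observed one (no noise, no endogeneity)
    beta, delta = sv.second_stage(ds.y, ds.x, b, wy)
    assert np.max(np.abs(beta - design.beta)) < 1e-8
    assert np.max(np.abs(b @ delta - cubic_g(t))) < 1e-8


def test_second_stage_joint_equals_alternating(grid_dataset):
    """Blockwise alternation of the two closed-form updates converges to the
    joint least-squares minimizer."""
    ds = grid_dataset
    wy = ds.w.w @ ds.y
    q = sv.build_instruments(ds.x, ds.w.w, ds.u)
    wy_hat = sv.first_stage(q, wy)
    t = ds.u @ np.array([0.5, np.sqrt(3) / 2])
    b = basis_matrix(t, TruncatedPowerBasis(select_knots(t, 10), 3))
    beta_j, delta_j = sv.second_stage(ds.y, ds.x, b, wy_hat)

    sb = wy_hat[:, None] * b
    delta = np.zeros(b.shape[1])
    for _ in range(4000):
        beta = np.linalg.lstsq(ds.x, ds.y - sb @ delta, rcond=None)[0]
        delta = np.linalg.lstsq(sb, ds.y - ds.x @ beta, rcond=None)[0]
    assert np.max(np.abs(beta - beta_j)) < 1e-8
    assert np.max(np.abs(sb @ delta - sb @ delta_j)) < 1e-6


def test_second_stage_orthogonal_block():
    rng = np.random.default_rng(5)
    n = 120
    x = rng.standard_normal((n, 2))
    b = np.ones((n, 1))
    wy_hat = rng.standard_normal(n)
    # orthogonalize x against the spline block S·B
    sb = wy_hat[:, None] * b
    x = x - sb @ np.linalg.lstsq(sb, x, rcond=None)[0]
    y = rng.standard_normal(n)
    beta, _ = sv.second_stage(y, x, b, wy_hat)
    beta_ols = np.linalg.lstsq(x, y, rcond=None)[0]
    assert np.allclose(beta, beta_ols, atol=1e-10)


def test_second_stage_zero_lag_unidentified():
    rng = np.random.default_rng(6)
    x = rng.standard_normal((50, 2))
    b = np.ones((50, 3))
    with pytest.raises(ValueError):
        sv.second_stage(rng.standard_normal(50), x, b, np.zeros(50))


def test_profile_loss_properties(noise_free):
    design, ds = noise_free
    wy = ds.w.w @ ds.y
    phi_true = np.array([design.alpha[1]])
    l_true = sv.profile_loss(phi_true, ds, wy, OPTS)
    assert 0 <= l_true < 1e-10  # exactly representable DGP
    for shift in (0.1, -0.15, 0.3):
        assert sv.profile_loss(phi_true + shift, ds, wy, OPTS) > l_true
    # degenerate direction maps to +inf, not an exception
    assert sv.profile_loss(np.array([_PHI_BALL]), ds, wy, OPTS) == np.inf


def test_initial_alpha_grid(noise_free):
    design, ds = noise_free
    wy = ds.w.w @ ds.y
    init = sv.initial_alpha(ds, wy, OPTS)
    assert np.max(np.abs(init.alpha - design.alpha)) < 0.05


def test_optimize_index_matches_brute_force(noise_free):
    design, ds = noise_free
    wy = ds.w.w @ ds.y
    init = sv.initial_alpha(ds, wy, OPTS)
    result = sv.optimize_index(ds, wy, init.phi, OPTS)
    grid = np.arange(-0.999, 0.9995, 1e-3)
    losses = [sv.profile_loss(np.array([p]), ds, wy, OPTS) for p in grid]
    brute = grid[int(np.argmin(losses))]
    assert abs(result.phi[0] - brute) < 2e-3
    # never ascends from its start
    assert (sv.profile_loss(result.phi, ds, wy, OPTS)
            <= sv.profile_loss(init.phi, ds, wy, OPTS) + 1e-12)
    assert np.linalg.norm(result.phi) <= 1.0


def test_fit_noise_free_exact_recovery(noise_free):
    design, ds = noise_free
    f = sv.fit(ds)
    assert f.converged
    assert np.max(np.abs(f.alpha - design.alpha)) < 1e-4
    assert np.max(np.abs(f.beta - design.beta)) < 1e-4
    assert np.max(np.abs(f.y_hat - ds.y)) < 1e-6


def test_fit_invariants(small_dataset):
    f = sv.fit(small_dataset)
    assert abs(np.linalg.norm(f.alpha) - 1) < 1e-12
    assert f.alpha[0] >= 0
    assert f.sigma2 >= 0
    assert np.isfinite(f.loss)
    # each index-optimization step is a descent on its own objective
    for before, after in f.loss_path:
        assert after <= before + 1e-9


def test_fit_sign_flip_invariance():
    """Negating both the index vector and g leaves the data, hence the fit,
    unchanged: the constraint picks the nonnegative-leading representative."""
    base = sv.SimulationDesign(h=8)
    flipped = sv.SimulationDesign(
        h=8, alpha=-base.alpha, g=lambda t: np.sin(-t))
    a, b = sv.simulate(base, seed=3), sv.simulate(flipped, seed=3)
    assert np.array_equal(a.y, b.y)
    fa, fb = sv.fit(a), sv.fit(b)
    assert np.allclose(fa.alpha, fb.alpha)


def test_predict_consistency(small_dataset):
    f = sv.fit(small_dataset)
    y_hat = sv.predict(f, small_dataset)
    assert np.allclose(y_hat, f.y_hat, atol=1e-12)
    resid = small_dataset.y - y_hat
    n_par = f.basis.dimension + small_dataset.x.shape[1] + 1
    expected = float(resid @ resid) / (small_dataset.n - n_par)
    assert abs(expected - f.sigma2) < 1e-12


def test_fitted_sigma2_mode(small_dataset):
    f = sv.fit(small_dataset, FitOptions(sigma2_mode="fitted"))
    resid = small_dataset.y - (f.g_hat * f.wy_hat + small_dataset.x @ f.beta)
    assert abs(f.sigma2 - float(resid @ resid) / small_dataset.n) < 1e-12


def test_bootstrap_se_smoke(small_dataset):
    f = sv.fit(small_dataset)
    out = sv.bootstrap_se(small_dataset, f, n_boot=3, seed=0)
    assert out["n_effective"] >= 2
    assert np.all(np.isfinite(out["alpha_se"]))
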