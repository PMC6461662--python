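"""Density transforms and functional PCA against closed-form / brute-force oracles."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import eig as dense_eig, subspace_angles
from scipy.stats import norm

import ssnhist as sh
from ssnhist.fpca import (
    DensityCurve,
    LQDCurve,
    _trapezoid_weights,
    density_to_quantile,
    fit_fpca,
    inverse_lqd,
    lqd_transform,
    mode_of_variation,
    project_scores,
    smooth_histogram_to_density,
)

GRID = np.linspace(-1000.0, 500.0, 151)


def density_from(fn, floor=1e-5, grid=GRID):
    v = np.maximum(fn(grid), 0.0)
    v = np.maximum(v / np.trapezoid(v, grid), floor)
    v = v / np.trapezoid(v, grid)
    return DensityCurve(grid, v)


def uniform_density():
    return DensityCurve(GRID, np.full(GRID.size, 1.0 / 1500.0))


# ---------------------------------------------------------------------------
# quantile function
# ---------------------------------------------------------------------------


def test_uniform_quantile_is_linear():
    q = density_to_quantile(uniform_density())
    assert q.values == pytest.approx(-1000.0 + 1500.0 * q.pgrid, abs=1e-9)
    assert q.values[0] == -1000.0 and q.values[-1] == 500.0


def test_symmetric_density_median():
    d = density_from(lambda x: norm.pdf(x, -250.0, 200.0))
    q = density_to_quantile(d)
    assert np.interp(0.5, q.pgrid, q.values) == pytest.approx(-250.0, abs=10.0)


def test_quantile_matches_fine_cdf_inversion():
    """Q(0.75) of a truncated Gaussian vs brute-force numeric CDF inversion."""
    d = density_from(lambda x: norm.pdf(x, -400.0, 100.0))
    q = density_to_quantile(d)
    fine = np.linspace(-1000.0, 500.0, 150001)
    vals = np.interp(fine, d.grid, d.values)
    cdf = np.concatenate([[0.0], cumulative_trapezoid(vals, fine)])
    cdf /= cdf[-1]
    oracle = fine[np.searchsorted(cdf, 0.75)]
    assert np.interp(0.75, q.pgrid, q.values) == pytest.approx(oracle, abs=1.0)


def test_non_normalised_density_rejected():
    with pytest.raises(ValueError):
        DensityCurve(GRID, np.full(GRID.size, 2.0 / 1500.0))


# ---------------------------------------------------------------------------
# LQD transform pair
# ---------------------------------------------------------------------------


def test_uniform_lqd_is_log_support_width():
    lqd = lqd_transform(uniform_density())
    assert lqd.values == pytest.approx(np.log(1500.0), abs=1e-8)


def test_lqd_requires_strictly_positive_density():
    v = np.maximum(0.0, 1.0 - np.abs(GRID + 400.0) / 200.0)  # exact zeros in the tails
    v /= np.trapezoid(v, GRID)
    with pytest.raises(ValueError):
        lqd_transform(DensityCurve(GRID, v))


def test_lqd_roundtrip_truncated_gaussian():
    d = density_from(lambda x: norm.pdf(x, -250.0, 450.0))
    back = inverse_lqd(lqd_transform(d))
    l1 = np.trapezoid(np.abs(back.values - d.values), d.grid)
    assert l1 < 1e-3


def test_lqd_constant_shift_is_inverse_invariant():
    """Adding c to psi rescales q = e^psi; support renormalisation undoes it."""
    d = density_from(lambda x: norm.pdf(x, -300.0, 350.0))
    lqd = lqd_transform(d)
    shifted = LQDCurve(lqd.pgrid, lqd.values + 1.7)
    a = inverse_lqd(lqd)
    b = inverse_lqd(shifted)
    assert np.trapezoid(b.values, b.grid) == pytest.approx(1.0, abs=1e-9)
    assert b.values == pytest.approx(a.values, abs=1e-9)


# ---------------------------------------------------------------------------
# histogram smoothing
# ---------------------------------------------------------------------------


def test_small_bandwidth_recovers_histogram_envelope(rng):
    probs = norm.pdf(GRID, -500.0, 180.0)
    probs /= probs.sum()
    counts = rng.multinomial(200_000, probs)
    hist = sh.AttenuationHistogram(GRID, counts)
    dens = smooth_histogram_to_density(hist, bandwidth=1.0)
    envelope = counts / (counts.sum() * 10.0)
    l1 = np.trapezoid(np.abs(dens.values - envelope), GRID)
    assert l1 < 0.02


def test_uniform_histogram_smooths_to_uniform_density():
    hist = sh.AttenuationHistogram(GRID, np.full(GRID.size, 100))
    dens = smooth_histogram_to_density(hist, bandwidth=40.0)
    interior = (GRID > -880.0) & (GRID < 380.0)
    assert np.abs(dens.values[interior] * 1500.0 - 1.0).max() < 0.05


def test_smoothed_density_normalised(default_cohort):
    for rec in default_cohort.records[:5]:
        d = smooth_histogram_to_density(rec.histogram)
        assert np.trapezoid(d.values, d.grid) == pytest.approx(1.0, abs=1e-8)
        assert d.values.min() > 0


# ---------------------------------------------------------------------------
# FPCA
# ---------------------------------------------------------------------------


def _unit_norm(f, pgrid):
    w = _trapezoid_weights(pgrid)
    return f / np.sqrt(np.sum(w * f * f))


def test_rank_one_model_recovers_its_eigenfunction():
    pgrid = np.linspace(0.0, 1.0, 101)
    phi = _unit_norm(np.sin(2 * np.pi * pgrid) + 0.3, pgrid)
    mean = 7.0 + 0.5 * pgrid
    scores = np.array([-2.0, -1.0, 0.0, 0.5, 1.0, 3.0])
    curves = [LQDCurve(pgrid, mean + a * phi) for a in scores]
    model = fit_fpca(curves)
    assert model.var_explained[0] >= 1 - 1e-6
    w = _trapezoid_weights(pgrid)
    inner = abs(np.sum(w * model.eigenfunctions[0] * phi))
    assert inner >= 0.999


def test_duplicating_curves_leaves_model_unchanged(lqd_curves):
    base = lqd_curves[:15]
    m1 = fit_fpca(base, n_components=3)
    m2 = fit_fpca(list(base) + list(base), n_components=3)
    assert m2.eigenvalues == pytest.approx(m1.eigenvalues, rel=1e-9)
    assert m2.eigenfunctions == pytest.approx(m1.eigenfunctions, abs=1e-8)


def test_fpca_matches_brute_force_eigendecomposition(rng):
    """20 curves on a 21-point grid vs dense covariance-operator eig at 1e-8."""
    pgrid = np.linspace(0.0, 1.0, 21)
    x = np.cumsum(rng.standard_normal((20, 21)), axis=1) * 0.3 + 7.0
    curves = [LQDCurve(pgrid, row) for row in x]
    model = fit_fpca(curves, n_components=5)
    # oracle: non-symmetric discretised operator C W, generic eigensolver
    w = _trapezoid_weights(pgrid)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / len(x)
    evals, evecs = dense_eig(cov @ np.diag(w))
    order = np.argsort(evals.real)[::-1]
    evals = evals.real[order]
    assert model.eigenvalues == pytest.approx(evals[:5], rel=1e-8)
    for k in range(5):
        v = evecs.real[:, order[k]]
        v = v / np.sqrt(np.sum(w * v * v))
        inner = abs(np.sum(w * v * model.eigenfunctions[k]))
        assert inner == pytest.approx(1.0, abs=1e-8)


def test_orthonormality_centering_and_variance_accounting(fpca_model, lqd_curves):
    w = _trapezoid_weights(fpca_model.pgrid)
    phi = fpca_model.eigenfunctions
    gram = (phi * w) @ phi.T
    assert gram == pytest.approx(np.eye(phi.shape[0]), abs=1e-6)
    assert fpca_model.scores.mean(axis=0) == pytest.approx(0.0, abs=1e-8)
    cov = fpca_model.scores.T @ fpca_model.scores / fpca_model.scores.shape[0]
    off = cov - np.diag(np.diag(cov))
    assert np.abs(off).max() <= 1e-6 * cov.diagonal().max()
    assert cov.diagonal() == pytest.approx(fpca_model.eigenvalues, rel=1e-8)
    # total eigenvalue mass equals the integrated pointwise sample variance
    x = np.vstack([c.values for c in lqd_curves])
    integrated_var = float(np.sum(w * x.var(axis=0)))
    assert fpca_model.total_variance == pytest.approx(integrated_var, rel=1e-6)
    assert np.all(np.diff(fpca_model.var_explained) <= 1e-12)
    assert fpca_model.var_explained.sum() <= 1 + 1e-12


def test_two_component_parameter_recovery(rng):
    """A known Legendre-pair model (eigenvalue ratio 4:1) is recovered at n=200."""
    pgrid = np.linspace(0.0, 1.0, 101)
    phi1 = np.sqrt(3.0) * (2 * pgrid - 1)
    phi2 = np.sqrt(5.0) * (6 * pgrid**2 - 6 * pgrid + 1)
    lam = (0.04, 0.01)
    a = rng.standard_normal((200, 2)) * np.sqrt(lam)
    mean = np.log(1500.0) * np.ones_like(pgrid)
    curves = [LQDCurve(pgrid, mean + ai[0] * phi1 + ai[1] * phi2) for ai in a]
    model = fit_fpca(curves, n_components=2)
    assert model.var_explained[0] == pytest.approx(0.8, abs=0.05)
    assert model.var_explained[1] == pytest.approx(0.2, abs=0.05)
    w = np.sqrt(_trapezoid_weights(pgrid))
    found = (model.eigenfunctions * w).T
    truth = np.stack([phi1 * w, phi2 * w], axis=1)
    angle = np.degrees(subspace_angles(found, truth)).max()
    assert angle < 5.0


def test_projection_contracts(fpca_model):
    pgrid = fpca_model.pgrid
    mean_curve = LQDCurve(pgrid, fpca_model.mean)
    assert project_scores(fpca_model, mean_curve) == pytest.approx(0.0, abs=1e-8)
    shifted = LQDCurve(pgrid, fpca_model.mean + 2.0 * fpca_model.eigenfunctions[0])
    s = project_scores(fpca_model, shifted)
    assert s[0] == pytest.approx(2.0, abs=1e-6)
    assert s[1:] == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(ValueError):
        project_scores(fpca_model, LQDCurve(np.linspace(0, 1, 51), np.zeros(51)))


def test_training_scores_reproduced_by_projection(fpca_model, lqd_curves):
    scores = project_scores(fpca_model, lqd_curves)
    assert scores == pytest.approx(fpca_model.scores, abs=1e-8)


def test_reconstruction_error_nested_in_k(fpca_model, lqd_curves):
    w = _trapezoid_weights(fpca_model.pgrid)
    x = lqd_curves[7].values - fpca_model.mean
    errs = []
    for k in range(fpca_model.n_components + 1):
        recon = fpca_model.scores[7, :k] @ fpca_model.eigenfunctions[:k]
        errs.append(float(np.sum(w * (x - recon) ** 2)))
    assert np.all(np.diff(errs) <= 1e-12)


def test_fpca_input_validation(lqd_curves):
    with pytest.raises(ValueError):
        fit_fpca(lqd_curves[:2])
    other = LQDCurve(np.linspace(0, 1, 51), np.zeros(51))
    with pytest.raises(ValueError):
        fit_fpca([lqd_curves[0], lqd_curves[1], other])


def test_mode_of_variation_contracts(fpca_model):
    with pytest.raises(ValueError):
        mode_of_variation(fpca_model, fpca_model.n_components + 1)
    curves = mode_of_variation(fpca_model, 1)
    for c in curves:
        assert np.trapezoid(c.values, c.grid) == pytest.approx(1.0, abs=1e-9)


def test_mode_one_orders_density_spread(fpca_model):
    """High first-mode scores give visibly wider (more heterogeneous) densities."""

    def iqr(c):
        cdf = np.concatenate([[0.0], cumulative_trapezoid(c.values, c.grid)])
        cdf /= cdf[-1]
        lo, hi = np.interp([0.25, 0.75], cdf, c.grid)
        return hi - lo

    low, *_, high = mode_of_variation(fpca_model, 1, (0.1, 0.5, 0.9))
    assert iqr(high) > iqr(low)


def test_zero_eigenvalue_mode_collapses():
    pgrid = np.linspace(0.0, 1.0, 101)
    phi = _unit_norm(np.cos(np.pi * pgrid), pgrid)
    curves = [LQDCurve(pgrid, 7.0 + a * phi) for a in (-1.0, 0.0, 1.0, 2.0)]
    model = fit_fpca(curves)  # second component has eigenvalue ~0
    assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)
    ms = mode_of_variation(model, 2, (0.1, 0.5, 0.9))
    for c in ms[1:]:
        assert c.values == pytest.approx(ms[0].values, abs=1e-6)


def test_model_json_roundtrip(fpca_model):
    back = sh.FPCAModel.from_json(fpca_model.to_json())
    assert back.eigenvalues == pytest.approx(fpca_model.eigenvalues)
    assert back.scores == pytest.approx(fpca_model.scores)
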