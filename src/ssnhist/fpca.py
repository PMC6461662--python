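"""Functional PCA of CT-attenuation densities via the log-quantile-density map.

Histograms are smoothed into strictly positive probability densities on the
fixed attenuation window [-1000, 500] HU, mapped to the unconstrained
log-quantile-density (LQD) domain

    psi(p) = log q(p) = log dQ/dp = -log f(Q(p)),   p in [0, 1],

and linear functional PCA is run there.  The LQD map is the standard device
for FPCA of probability densities: densities form a nonlinear constrained
set (non-negative, unit mass), while their LQD images form a linear space in
which means and principal components are well defined and every
reconstruction maps back to a bona-fide density on the same support.

The per-nodule FPC scores (fpc1, fpc2, ...) are the data-driven attenuation
features used alongside the a-priori histogram features in classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import PchipInterpolator

from .cohort import SUPPORT_HU, AttenuationHistogram
from .features import histogram_moments, histogram_quantiles

__all__ = [
    "DensityCurve",
    "QuantileFunction",
    "LQDCurve",
    "FPCAModel",
    "smooth_histogram_to_density",
    "density_to_quantile",
    "lqd_transform",
    "inverse_lqd",
    "fit_fpca",
    "project_scores",
    "mode_of_variation",
]

_SUPPORT_WIDTH = SUPPORT_HU[1] - SUPPORT_HU[0]


def _uniform_grid(size: int, lo: float = SUPPORT_HU[0], hi: float = SUPPORT_HU[1]):
    return np.linspace(lo, hi, size)


@dataclass(frozen=True)
class DensityCurve:
    """A probability density on the attenuation support, trapezoid-normalised."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.shape != values.shape or grid.ndim != 1 or grid.size < 3:
            raise ValueError("grid and values must be matching 1-D arrays (size >= 3)")
        if np.any(values < 0):
            raise ValueError("density values must be non-negative")
        integral = np.trapezoid(values, grid)
        if abs(integral - 1.0) > 1e-8:
            raise ValueError(f"density must integrate to 1 (got {integral:.3e})")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class QuantileFunction:
    """Quantile function Q(p) on a uniform probability grid, endpoints pinned."""

    pgrid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        pgrid = np.asarray(self.pgrid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if pgrid.shape != values.shape or pgrid.ndim != 1:
            raise ValueError("pgrid and values must be matching 1-D arrays")
        if np.any(np.diff(values) < -1e-9):
            raise ValueError("quantile function must be non-decreasing")
        object.__setattr__(self, "pgrid", pgrid)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class LQDCurve:
    """log quantile-density, finite everywhere thanks to the density floor."""

    pgrid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        pgrid = np.asarray(self.pgrid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if pgrid.shape != values.shape or pgrid.ndim != 1:
            raise ValueError("pgrid and values must be matching 1-D arrays")
        if not np.all(np.isfinite(values)):
            raise ValueError("LQD values must be finite (density floor missing?)")
        object.__setattr__(self, "pgrid", pgrid)
        object.__setattr__(self, "values", values)


# ---------------------------------------------------------------------------
# histogram -> density
# ---------------------------------------------------------------------------


def _silverman_bandwidth(hist: AttenuationHistogram) -> float:
    mom = histogram_moments(hist)
    q25, q75 = histogram_quantiles(hist, [0.25, 0.75])
    spread = min(mom.sd, (q75 - q25) / 1.34) if q75 > q25 else mom.sd
    n = hist.total_voxels
    return float(max(0.9 * spread * n ** (-0.2), hist.bin_width / 2.0))


def smooth_histogram_to_density(
    hist: AttenuationHistogram,
    bandwidth: float | str = "auto",
    floor: float = 1e-5,
    grid_size: int = 151,
) -> DensityCurve:
    """Gaussian-kernel smooth of a histogram into a floored density.

    Boundary bias is handled by reflecting kernel mass at both support edges,
    so the smoother is mass-preserving on the window.  ``bandwidth`` is in HU
    ("auto" = Silverman's rule on the count-weighted sample); ``floor`` is the
    minimum density level (per HU) required by the downstream log transform.
    """
    if hist.total_voxels <= 0:
        raise ValueError("empty histogram")
    if not 0 < floor < 1.0 / _SUPPORT_WIDTH:
        raise ValueError("floor must lie in (0, 1/support-width)")
    if bandwidth == "auto":
        h = _silverman_bandwidth(hist)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    lo, hi = SUPPORT_HU
    grid = _uniform_grid(grid_size)
    centers = hist.bin_centers
    w = hist.counts / hist.total_voxels

    def kern(x):
        z = (grid[:, None] - x[None, :]) / h
        return np.exp(-0.5 * z * z) / (h * np.sqrt(2 * np.pi))

    dens = (kern(centers) + kern(2 * lo - centers) + kern(2 * hi - centers)) @ w
    dens = np.maximum(dens, floor)
    dens = dens / np.trapezoid(dens, grid)
    return DensityCurve(grid, dens)


# ---------------------------------------------------------------------------
# density -> quantile -> LQD and back
# ---------------------------------------------------------------------------


def density_to_quantile(density: DensityCurve, pgrid_size: int = 101) -> QuantileFunction:
    """Invert the trapezoid CDF of a density by monotone interpolation."""
    cdf = np.concatenate(
        [[0.0], cumulative_trapezoid(density.values, density.grid)]
    )
    if abs(cdf[-1] - 1.0) > 1e-6:
        raise ValueError("density is not normalised")
    cdf = cdf / cdf[-1]
    cdf = np.maximum.accumulate(cdf)
    pgrid = np.linspace(0.0, 1.0, pgrid_size)
    values = np.interp(pgrid, cdf, density.grid)
    values[0] = density.grid[0]
    values[-1] = density.grid[-1]
    return QuantileFunction(pgrid, values)


def lqd_transform(density: DensityCurve, pgrid_size: int = 101) -> LQDCurve:
    """Forward log-quantile-density map: psi(p) = -log f(Q(p))."""
    if np.any(density.values <= 0):
        raise ValueError("density must be strictly positive (apply a floor)")
    q = density_to_quantile(density, pgrid_size)
    f_at_q = np.interp(q.values, density.grid, density.values)
    return LQDCurve(q.pgrid, -np.log(f_at_q))


def inverse_lqd(
    lqd: LQDCurve, grid_size: int = 151, refine: int = 40
) -> DensityCurve:
    """Map an LQD curve back to a density on the fixed attenuation support.

    The quantile density q = exp(psi) is integrated on a monotone-cubic
    refinement of the probability grid and rescaled so the reconstructed
    support width is exactly the attenuation window; adding a constant to an
    LQD curve therefore leaves the reconstructed density unchanged.
    """
    pgrid = lqd.pgrid
    # refine to tame the stiff exp(psi) integrand near the support edges
    p_fine = np.linspace(pgrid[0], pgrid[-1], refine * (pgrid.size - 1) + 1)
    psi = PchipInterpolator(pgrid, lqd.values)(p_fine)
    psi = psi - psi.max()  # scale-invariant: guard overflow only
    q = np.exp(psi)
    integral = np.concatenate([[0.0], cumulative_trapezoid(q, p_fine)])
    width = integral[-1]
    if width <= 0:
        raise ValueError("degenerate LQD curve")
    scale = _SUPPORT_WIDTH / width
    q_pos = SUPPORT_HU[0] + scale * integral
    f_at_q = 1.0 / (scale * q)
    grid = _uniform_grid(grid_size)
    values = np.interp(grid, q_pos, f_at_q)
    values = np.maximum(values, 0.0)
    values = values / np.trapezoid(values, grid)
    return DensityCurve(grid, values)


# ---------------------------------------------------------------------------
# FPCA in the LQD domain
# ---------------------------------------------------------------------------


def _trapezoid_weights(pgrid: np.ndarray) -> np.ndarray:
    w = np.empty_like(pgrid)
    w[1:-1] = (pgrid[2:] - pgrid[:-2]) / 2.0
    w[0] = (pgrid[1] - pgrid[0]) / 2.0
    w[-1] = (pgrid[-1] - pgrid[-2]) / 2.0
    return w


@dataclass(frozen=True)
class FPCAModel:
    """Mean LQD curve, orthonormal eigenfunctions, eigenvalues and scores.

    Eigenfunctions are orthonormal under the trapezoid inner product on the
    probability grid; ``scores[:, k]`` are the centred projections of the
    training curves on eigenfunction k (fpc1 = column 0).  Eigenvalues use
    the 1/n covariance normalisation, so duplicating every curve leaves the
    model unchanged.
    """

    pgrid: np.ndarray
    mean: np.ndarray
    eigenfunctions: np.ndarray  # (K, M)
    eigenvalues: np.ndarray  # (K,)
    var_explained: np.ndarray  # (K,)
    scores: np.ndarray  # (n, K)
    total_variance: float

    @property
    def n_components(self) -> int:
        return int(self.eigenvalues.size)

    def to_json(self) -> str:
        payload = {
            "pgrid": self.pgrid.tolist(),
            "mean": self.mean.tolist(),
            "eigenfunctions": self.eigenfunctions.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "var_explained": self.var_explained.tolist(),
            "scores": self.scores.tolist(),
            "total_variance": self.total_variance,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FPCAModel":
        raw = json.loads(text)
        return cls(
            pgrid=np.asarray(raw["pgrid"]),
            mean=np.asarray(raw["mean"]),
            eigenfunctions=np.asarray(raw["eigenfunctions"]),
            eigenvalues=np.asarray(raw["eigenvalues"]),
            var_explained=np.asarray(raw["var_explained"]),
            scores=np.asarray(raw["scores"]),
            total_variance=float(raw["total_variance"]),
        )


def _as_curve_matrix(curves) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curves, np.ndarray):
        raise TypeError("pass a sequence of LQDCurve objects")
    curves = list(curves)
    if not curves:
        raise ValueError("no curves")
    pgrid = curves[0].pgrid
    for c in curves[1:]:
        if c.pgrid.shape != pgrid.shape or not np.allclose(c.pgrid, pgrid):
            raise ValueError("curves are defined on mismatched probability grids")
    return pgrid, np.vstack([c.values for c in curves])


def fit_fpca(
    curves: Sequence[LQDCurve],
    var_threshold: float = 0.85,
    n_components: int | None = None,
    min_components: int = 2,
) -> FPCAModel:
    """Eigen-decompose the sample covariance operator of LQD curves.

    The number of retained components is the smallest K whose cumulative
    explained-variance fraction reaches ``var_threshold`` (at least
    ``min_components``), unless ``n_components`` fixes it explicitly.  Each
    eigenfunction's sign is fixed to have positive trapezoid integral
    (positive inner product with the constant upward-shift direction), with
    a positive mid-grid value as tie-break.
    """
    pgrid, x = _as_curve_matrix(curves)
    n, m = x.shape
    if n < 3:
        raise ValueError("need at least 3 curves for FPCA")
    w = _trapezoid_weights(pgrid)
    sw = np.sqrt(w)
    mean = x.mean(axis=0)
    xc = x - mean
    b = xc * sw  # n x m, rows in the weighted l2 geometry
    cov_w = (b.T @ b) / n
    evals, evecs = np.linalg.eigh(cov_w)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total_var = float(evals.sum())
    if total_var <= 0:
        raise ValueError("curves have zero variance")
    frac = evals / total_var
    max_rank = min(n - 1, m)
    if n_components is not None:
        k = int(n_components)
        if not 1 <= k <= max_rank:
            raise ValueError(f"n_components must lie in [1, {max_rank}]")
    else:
        cum = np.cumsum(frac)
        k = int(np.searchsorted(cum, var_threshold) + 1)
        k = max(k, min_components)
        k = min(k, max_rank)
    phi = (evecs[:, :k] / sw[:, None]).T  # orthonormal under trapezoid product
    integral = phi @ w
    mid = phi[:, m // 2]
    sign = np.where(np.abs(integral) > 1e-10, np.sign(integral), np.sign(mid))
    sign = np.where(sign == 0, 1.0, sign)
    phi = phi * sign[:, None]
    scores = xc @ (phi * w).T
    return FPCAModel(
        pgrid=pgrid,
        mean=mean,
        eigenfunctions=phi,
        eigenvalues=evals[:k],
        var_explained=frac[:k],
        scores=scores,
        total_variance=total_var,
    )


def project_scores(model: FPCAModel, curve: LQDCurve | Sequence[LQDCurve]) -> np.ndarray:
    """FPC scores of one curve (1-D) or several curves (2-D) under a model."""
    single = isinstance(curve, LQDCurve)
    curves = [curve] if single else list(curve)
    pgrid, x = _as_curve_matrix(curves)
    if pgrid.shape != model.pgrid.shape or not np.allclose(pgrid, model.pgrid):
        raise ValueError("curve grid does not match the model grid")
    w = _trapezoid_weights(model.pgrid)
    scores = (x - model.mean) @ (model.eigenfunctions * w).T
    return scores[0] if single else scores


def mode_of_variation(
    model: FPCAModel,
    k: int,
    quantile_levels: Sequence[float] = (0.1, 0.25, 0.5, 0.75, 0.9),
    grid_size: int = 151,
) -> list[DensityCurve]:
    """Densities along eigenfunction k at empirical score quantiles.

    ``k`` is 1-based (k=1 is the first mode).  Each returned curve is
    ``inverse_lqd(mean + s * phi_k)`` with s the requested score quantile.
    """
    if not 1 <= k <= model.n_components:
        raise ValueError(f"component k must lie in [1, {model.n_components}]")
    levels = np.asarray(quantile_levels, dtype=float)
    if levels.size and (levels.min() <= 0 or levels.max() >= 1):
        raise ValueError("quantile levels must lie strictly inside (0, 1)")
    s = np.quantile(model.scores[:, k - 1], levels)
    phi = model.eigenfunctions[k - 1]
    return [
        inverse_lqd(LQDCurve(model.pgrid, model.mean + si * phi), grid_size=grid_size)
        for si in s
    ]
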