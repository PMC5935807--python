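"""Presmoothing and functional principal component analysis of daily series.

Each user's 0/1 daily log-in series is first presmoothed into a continuous
engagement-intensity curve by Nadaraya-Watson kernel regression on the day
index (Epanechnikov kernel, default bandwidth 28 days, boundary weights
renormalized rather than reflected). The sample of smoothed curves is then
decomposed by FPCA on a dense common grid mapped to [0, 1]:

    X_i(t) ~= mu(t) + sum_k  xi_ik phi_k(t),

where the eigenfunctions ``phi_k`` are orthonormal in L2([0, 1]) under
trapezoid quadrature and the scores ``xi_ik`` are quadrature integrals of
the centered curves against each eigenfunction. The number of retained
components K is the smallest number reaching a fraction-of-variance-
explained threshold (default 0.90), capped at ``max_components``.

Because the daily grid is complete and dense, the covariance operator is
estimated as the plain sample covariance of the smoothed curves (the
presmoothing step already attenuates Bernoulli noise, so no diagonal
correction is applied) and eigenpairs come from the symmetrized,
quadrature-weighted discretized operator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DailyEngagementMatrix

__all__ = [
    "SmoothedTrajectorySet",
    "FPCAModel",
    "DegenerateCovarianceError",
    "presmooth",
    "fit_fpca",
    "transform_scores",
]


class DegenerateCovarianceError(ValueError):
    """The sample covariance of the smoothed curves has no positive spectrum."""


def trajectory_grid(n_days: int) -> np.ndarray:
    """Uniform grid mapping days 1..D to [0, 1]: t_d = (d - 1) / (D - 1)."""
    if n_days < 2:
        raise ValueError("need at least 2 days")
    return np.linspace(0.0, 1.0, n_days)


def _trapezoid_weights(n_days: int) -> np.ndarray:
    dt = 1.0 / (n_days - 1)
    w = np.full(n_days, dt)
    w[0] = w[-1] = dt / 2.0
    return w


@dataclass
class SmoothedTrajectorySet:
    """N x D smoothed engagement intensities on a shared grid in [0, 1]."""

    values: np.ndarray  # (N, D), entries in [0, 1]
    grid: np.ndarray  # (D,)
    bandwidth_days: float

    @property
    def n_curves(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]


def epanechnikov_weights(n_days: int, bandwidth_days: float) -> np.ndarray:
    """Row-stochastic D x D Nadaraya-Watson weight matrix on the day index.

    Row d holds the kernel weights K((d - d') / h) renormalized to sum to 1;
    near the boundaries the kernel support is simply truncated and the
    remaining weights rescaled (no reflection or padding).
    """
    days = np.arange(n_days, dtype=float)
    u = (days[:, None] - days[None, :]) / bandwidth_days
    k = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)
    return k / k.sum(axis=1, keepdims=True)


def presmooth(
    matrix: DailyEngagementMatrix | np.ndarray,
    bandwidth_days: float = 28.0,
) -> SmoothedTrajectorySet:
    """Kernel-presmooth each binary daily series into a continuous curve.

    Output values are convex combinations of 0/1 inputs and hence lie in
    [0, 1]; the grid has the same D points as the input, mapped to [0, 1].
    """
    values = matrix.values if isinstance(matrix, DailyEngagementMatrix) else np.asarray(matrix)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need an N x D matrix with D >= 2")
    if values.size and not np.isin(values, (0, 1)).all():
        raise ValueError("presmoothing expects binary (0/1) input")
    if bandwidth_days < 1:
        raise ValueError(f"bandwidth_days must be >= 1, got {bandwidth_days}")
    n_days = values.shape[1]
    weights = epanechnikov_weights(n_days, float(bandwidth_days))
    smoothed = values.astype(float) @ weights.T
    return SmoothedTrajectorySet(smoothed, trajectory_grid(n_days), float(bandwidth_days))


@dataclass
class FPCAModel:
    """Mean function, orthonormal eigenfunctions, eigenvalues and scores."""

    grid: np.ndarray  # (D,)
    mean: np.ndarray  # (D,)
    eigenfunctions: np.ndarray  # (K, D), orthonormal under trapezoid quadrature
    eigenvalues: np.ndarray  # (K,), non-increasing, positive
    scores: np.ndarray  # (N, K)
    fve: np.ndarray  # (K,) cumulative fraction of variance explained

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


# eigenvalues this far below the leading one are treated as numerical zero
_RELATIVE_RANK_TOL = 1e-10


def fit_fpca(
    smoothed: SmoothedTrajectorySet,
    fve_threshold: float = 0.90,
    max_components: int = 10,
) -> FPCAModel:
    """Fit FPCA to a set of smoothed curves on a dense common grid.

    Eigenpairs are obtained from ``W^{1/2} C W^{1/2}`` where C is the D x D
    sample covariance of the curves and W the diagonal trapezoid-quadrature
    weights; eigenvectors are rescaled to quadrature-orthonormal
    eigenfunctions. Negative/near-zero eigenvalues from discretization are
    discarded. Each eigenfunction's sign is fixed so its largest-magnitude
    element is positive, making runs reproducible.
    """
    if not (0.0 < fve_threshold <= 1.0):
        raise ValueError(f"fve_threshold must be in (0, 1], got {fve_threshold}")
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    x = smoothed.values
    n, d = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 curves, got {n}")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / (n - 1)
    w = _trapezoid_weights(d)
    sw = np.sqrt(w)
    sym = sw[:, None] * cov * sw[None, :]
    sym = (sym + sym.T) / 2.0
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = evals > max(evals[0], 0.0) * _RELATIVE_RANK_TOL
    positive &= evals > 0.0
    if not positive.any():
        raise DegenerateCovarianceError("all smoothed curves are identical; covariance is zero")
    evals, evecs = evals[positive], evecs[:, positive]
    total = evals.sum()
    cumulative = np.cumsum(evals) / total
    k = int(np.searchsorted(cumulative, fve_threshold - 1e-12) + 1)
    k = min(k, max_components, len(evals))
    phi = (evecs[:, :k] / sw[:, None]).T  # (K, D), quadrature-orthonormal
    flip = phi[np.arange(k), np.argmax(np.abs(phi), axis=1)] < 0
    phi[flip] *= -1.0
    scores = xc @ (w[None, :] * phi).T
    return FPCAModel(
        grid=smoothed.grid.copy(),
        mean=mean,
        eigenfunctions=phi,
        eigenvalues=evals[:k],
        scores=scores,
        fve=cumulative[:k],
    )


def transform_scores(model: FPCAModel, smoothed: SmoothedTrajectorySet) -> np.ndarray:
    """Project curves onto a fitted model: xi_ik = integral (X_i - mu) phi_k dt."""
    if smoothed.n_points != len(model.grid) or not np.allclose(smoothed.grid, model.grid):
        raise ValueError("grid of the curves does not match the model grid")
    w = _trapezoid_weights(len(model.grid))
    return (smoothed.values - model.mean) @ (w[None, :] * model.eigenfunctions).T
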