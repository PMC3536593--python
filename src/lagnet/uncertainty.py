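"""First-order propagation of measurement errors through the topology stage.

The chain runs measurement error -> covariance -> correlation -> distance ->
stress:

* ``delta_S(t) = delta_X(t) + delta_Xbar`` (centered-value error, absolute sum);
* per-time covariance error combines the two centered-value errors in
  quadrature, ``sqrt((dS_i S_j)^2 + (S_i dS_j)^2)``, and ``delta_C(tau)`` is
  their time mean — the density-error contribution is assumed negligible and
  dropped;
* ``delta_r`` combines the covariance errors in quadrature with the 1/2
  factors from the square root of the variances;
* ``delta_d = (dc_ii + 2 dc_ij + dc_jj) / (2 d)`` with
  ``dc = max_tau |delta_r(tau)|`` (absolute sum, matching the square-root
  distance form);
* ``delta_S_D = (1/S_D) * sum |d_ij - ||z_i - z_j||| * delta_d_ij``.

All propagated errors are first order; no Monte-Carlo resampling is done.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .config import DEFAULT_CONFIG, InferenceConfig
from .data_io import TimeSeriesSet
from .lagcorr import DistanceMatrix, LagGrid, LaggedCorrelation, _centered_pair

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorBudget",
    "covariance_error",
    "correlation_error",
    "distance_error",
    "stress_error",
    "error_budget",
]


@dataclass
class ErrorBudget:
    """Propagated absolute errors at each stage of the topology analysis."""

    species: list[str]
    delta_C: np.ndarray  # N x N x L
    delta_r: np.ndarray  # N x N x L
    delta_c_star: np.ndarray  # N x N, max over lags of |delta_r|
    delta_d: Optional[np.ndarray] = None  # N x N


def covariance_error(
    ts: TimeSeriesSet, grid: LagGrid, config: InferenceConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Absolute error ``delta_C_ij(tau)`` on every covariance entry.

    Uses measured per-value errors when present, otherwise the configured
    relative error.  The per-time error of the product ``S_i(t) S_j(t+tau)``
    is formed in the absolute form ``sqrt((dS_i S_j)^2 + (S_i dS_j)^2)``
    (identical to the relative root-sum-square where the centered values are
    nonzero, and finite where they vanish); ``delta_C(tau)`` is the plain
    time mean of the per-time errors.
    """
    dX = ts.error_matrix(config.default_relative_error)
    dXbar = dX.mean(axis=0)
    dS = dX + dXbar[None, :]  # absolute-sum error of the centered value
    N, L = ts.n_species, grid.n_lags
    out = np.full((N, N, L), np.nan)
    for a in range(N):
        for b in range(N):
            for ell, s in enumerate(grid.lag_samples):
                s = int(s)
                Si, Sj, _, _ = _centered_pair(ts, a, b, s)
                if Si.size < config.min_pairs:
                    continue
                dSi = dS[: ts.n_samples - s if s else None, a]
                dSj = dS[s:, b]
                per_time = np.sqrt((dSi * Sj) ** 2 + (Si * dSj) ** 2)
                out[a, b, ell] = per_time.mean()
    return out


def correlation_error(
    corr: LaggedCorrelation, delta_C: np.ndarray, config: InferenceConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Absolute error ``delta_r_ij(tau)`` on the correlation coefficients.

    ``delta_r = sqrt((dC_ij / sqrt|C_ii C_jj|)^2
    + r^2/4 ((dC_ii/C_ii)^2 + (dC_jj/C_jj)^2))`` — the algebraically stable
    form of the quadrature rule, finite as ``C_ij -> 0`` (where only the
    leading covariance term survives).
    """
    C, r = corr.covariance, corr.correlation
    N, L = C.shape[0], C.shape[2]
    out = np.full_like(delta_C, np.nan)
    floor = config.rel_error_floor
    for a in range(N):
        for b in range(N):
            Caa = np.abs(C[a, a, :])
            Cbb = np.abs(C[b, b, :])
            denom = np.sqrt(np.maximum(Caa * Cbb, floor**2))
            var_terms = 0.25 * (
                (delta_C[a, a, :] / np.maximum(Caa, floor)) ** 2
                + (delta_C[b, b, :] / np.maximum(Cbb, floor)) ** 2
            )
            out[a, b, :] = np.sqrt(
                (delta_C[a, b, :] / denom) ** 2 + r[a, b, :] ** 2 * var_terms
            )
    return out


def distance_error(
    dist: DistanceMatrix, delta_c_star: np.ndarray, config: InferenceConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Absolute error on the distances.

    ``delta_d_ij = (dc_ii + 2 dc_ij + dc_jj) / (2 d_ij)``, where ``dc`` is
    the lag maximum of ``|delta_r|``; the off-diagonal ``dc_ij`` is taken
    conservatively as the larger of the two lag directions (the undirected
    ``c`` is their maximum).  Vanishing off-diagonal distances with nonzero
    error budget get ``delta_d = sqrt(dc-sum)`` (the limit of the root form)
    and a warning.
    """
    dc = np.fmax(delta_c_star, delta_c_star.T)
    dcii = np.diag(dc)
    numer = dcii[:, None] + 2 * dc + dcii[None, :]
    d = dist.d
    out = np.zeros_like(d)
    off = ~np.eye(d.shape[0], dtype=bool)
    zero_d = off & (d <= config.rel_error_floor) & (numer > 0)
    if np.any(zero_d):
        logger.warning(
            "distance_error: %d off-diagonal zero distances; using sqrt limit",
            int(zero_d.sum() // 2),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out[off] = numer[off] / (2 * np.maximum(d[off], config.rel_error_floor))
    out[zero_d] = np.sqrt(numer[zero_d])
    np.fill_diagonal(out, 0.0)
    return out


def stress_error(
    coords: np.ndarray, dist: np.ndarray, delta_d: np.ndarray, stress_value: float
) -> float:
    """First-order error ``delta_S_D`` on the stress from the distance errors.

    ``delta_S = (1/S) sum_{i<j} |d_ij - ||z_i - z_j||| * delta_d_ij``;
    returns 0 at a perfect embedding (where the stress error is unneeded).
    """
    if stress_value <= 0:
        return 0.0
    fitted = squareform(pdist(coords))
    iu = np.triu_indices_from(dist, k=1)
    resid = np.abs(dist[iu] - fitted[iu])
    dd = delta_d[iu]
    ok = np.isfinite(resid) & np.isfinite(dd)
    return float(np.sum(resid[ok] * dd[ok]) / stress_value)


def error_budget(
    ts: TimeSeriesSet,
    corr: LaggedCorrelation,
    dist: Optional[DistanceMatrix] = None,
    config: InferenceConfig = DEFAULT_CONFIG,
) -> ErrorBudget:
    """Full error budget; fills ``dist.delta_d`` in place when given."""
    dC = covariance_error(ts, corr.grid, config)
    dr = correlation_error(corr, dC, config)
    with np.errstate(invalid="ignore"):
        dc_star = np.nanmax(np.abs(dr), axis=2)
    budget = ErrorBudget(
        species=list(ts.species), delta_C=dC, delta_r=dr, delta_c_star=dc_star
    )
    if dist is not None:
        budget.delta_d = distance_error(dist, dc_star, config)
        dist.delta_d = budget.delta_d
    return budget
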