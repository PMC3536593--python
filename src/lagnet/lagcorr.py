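"""Time-lagged correlation analysis with Voronoi pair-density estimation.

The topology stage turns a set of concentration time series into an
interspecies distance matrix in four steps:

1. a per-species response timescale ``<tau_i>`` bounds the lag grid
   (``tau_min = min_i <tau_i>``);
2. for every ordered species pair and lag, the scatter of
   ``(X_i(t), X_j(t + tau))`` is tessellated with Voronoi cells whose inverse
   areas estimate the pair density ``p``;
3. the density-weighted, mean-centered time average gives the lagged
   covariance ``C_ij(tau)`` and correlation
   ``r_ij(tau) = C_ij / sqrt|C_ii C_jj|``;
4. ``c_ij = max_tau |r_ij(tau)|`` defines the distance
   ``d_ij = sqrt|c_ii - 2 c_ij + c_jj|``, small for species coupled by a
   direct reaction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.spatial import QhullError, Voronoi

from .config import DEFAULT_CONFIG, InferenceConfig
from .data_io import TimeSeriesSet

logger = logging.getLogger(__name__)

__all__ = [
    "LagGrid",
    "LaggedCorrelation",
    "DistanceMatrix",
    "derivative",
    "species_lag",
    "lag_grid",
    "voronoi_density",
    "lagged_covariance",
    "correlation_tensor",
    "distance_matrix",
]


class UninformativeSeriesError(ValueError):
    """Raised when a series admits no lag estimate (e.g. constant data)."""


def derivative(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """dX/dt at each sample from the monotone interpolant of the series.

    Uses the PCHIP shape-preserving interpolant, which is exact on affine
    data and does not overshoot monotone segments.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 samples for derivative estimation")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return PchipInterpolator(times, values).derivative()(times)


def species_lag(times: np.ndarray, values: np.ndarray) -> float:
    """Characteristic response timescale ``<tau_i>`` of one series.

    Mean over k = 2..m of ``|X(t_k) - X(t_{k-1})| / |dX/dt(t_k)|``; terms with
    a vanishing derivative are skipped with a warning.  The result bounds the
    lag grid: correlations are only scanned over delays up to the fastest
    species' timescale.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    deriv = derivative(times, values)[1:]
    increments = np.abs(np.diff(values))
    ok = np.abs(deriv) > 0
    if not np.all(ok):
        logger.warning(
            "species_lag: skipping %d terms with zero derivative", int((~ok).sum())
        )
    if not np.any(ok):
        raise UninformativeSeriesError("series uninformative for lag estimation")
    return float(np.mean(increments[ok] / np.abs(deriv[ok])))


@dataclass
class LagGrid:
    """Discrete lag grid ``{0, dtau, ..., L*dtau}`` with ``L*dtau <= tau_min``."""

    step: float
    lags: np.ndarray
    lag_samples: np.ndarray  # lags expressed in sampling-step counts
    species_lags: dict[str, float]
    tau_min: float

    def __post_init__(self) -> None:
        if self.lags[0] != 0 or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must start at 0 and increase")
        if self.lags.size > 1 and self.lags[-1] > self.tau_min + 1e-12:
            raise ValueError("largest lag exceeds tau_min")

    @property
    def n_lags(self) -> int:
        return int(self.lags.size)


def lag_grid(ts: TimeSeriesSet, config: InferenceConfig = DEFAULT_CONFIG) -> LagGrid:
    """Lag grid bounded by the fastest species timescale.

    Lags are integer multiples of the (uniform) sampling step; when
    ``tau_min`` spans more than ``config.lag_max_points`` samples the stride
    is raised to the smallest integer multiple that fits the cap.  A
    ``tau_min`` below one sampling step yields the degenerate grid ``{0}``.
    """
    steps = np.diff(ts.times)
    dt = float(steps[0])
    if not np.allclose(steps, dt, rtol=1e-6, atol=1e-12):
        raise ValueError("lag_grid requires uniformly sampled times; resample first")
    taus = {sp: species_lag(ts.times, ts.values[:, k]) for k, sp in enumerate(ts.species)}
    tau_min = min(taus.values())
    max_samples = int(np.floor(tau_min / dt + 1e-9))
    max_samples = min(max_samples, ts.n_samples - int(DEFAULT_CONFIG.min_pairs))
    if max_samples < 1:
        logger.warning("tau_min=%.4g below one sampling step; lag grid is {0}", tau_min)
        lag_samples = np.array([0])
    else:
        stride = max(1, int(np.ceil(max_samples / max(config.lag_max_points - 1, 1))))
        lag_samples = np.arange(0, max_samples + 1, stride)
    return LagGrid(
        step=dt * (lag_samples[1] - lag_samples[0]) if lag_samples.size > 1 else dt,
        lags=lag_samples * dt,
        lag_samples=lag_samples,
        species_lags=taus,
        tau_min=tau_min,
    )


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_density(
    points: np.ndarray, config: InferenceConfig = DEFAULT_CONFIG
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Pair-density estimate ``p = 1/Area(V)`` per scatter point.

    The scatter is reflected across the four edges of its bounding box
    (expanded by half the median nearest-neighbour distance), so every cell
    of an original point is bounded and exactly clipped to the box.
    Densities are normalized so that ``sum(p * Area) = 1`` over the clipped
    region.  Degenerate scatters (fewer than 4 points, collinear points, or
    qhull failure) fall back to uniform weights with ``areas = None``.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    uniform = np.full(n, 1.0 / n)
    if n < 4:
        return uniform, None
    lo, hi = points.min(axis=0), points.max(axis=0)
    if np.any(hi - lo <= 0):
        logger.warning("voronoi_density: degenerate (axis-collapsed) scatter")
        return uniform, None
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-12 * sv[0]:
        logger.warning("voronoi_density: collinear scatter, uniform fallback")
        return uniform, None
    # pad the box by half the median nearest-neighbour distance
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    nn = tree.query(points, k=2)[0][:, 1]
    pad = 0.5 * float(np.median(nn))
    if pad <= 0:
        pad = 1e-9 * float(np.max(hi - lo))
    lo, hi = lo - pad, hi + pad
    mirrored = [points]
    for axis, bound in ((0, lo[0]), (0, hi[0]), (1, lo[1]), (1, hi[1])):
        refl = points.copy()
        refl[:, axis] = 2 * bound - refl[:, axis]
        mirrored.append(refl)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vor = Voronoi(np.vstack(mirrored))
    except QhullError:
        logger.warning("voronoi_density: qhull failure, falling back to uniform weights")
        return uniform, None
    areas = np.empty(n)
    for k in range(n):
        region = vor.regions[vor.point_region[k]]
        if -1 in region or len(region) < 3:
            logger.warning("voronoi_density: unbounded cell, uniform fallback")
            return uniform, None
        areas[k] = _polygon_area(vor.vertices[region])
    if np.any(areas <= 0) or not np.all(np.isfinite(areas)):
        logger.warning("voronoi_density: degenerate cell areas, uniform fallback")
        return uniform, None
    # raw p = 1/A gives sum(p * A) = n; divide by n to normalize
    density = 1.0 / (n * areas)
    return density, areas


@dataclass
class LaggedCorrelation:
    """Covariance and correlation tensors over the lag grid (N x N x L)."""

    species: list[str]
    grid: LagGrid
    covariance: np.ndarray
    correlation: np.ndarray

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export (i, j, tau, C, r) for external heat-mapping."""
        rows = []
        for a, si in enumerate(self.species):
            for b, sj in enumerate(self.species):
                for L, tau in enumerate(self.grid.lags):
                    rows.append(
                        (si, sj, tau, self.covariance[a, b, L], self.correlation[a, b, L])
                    )
        return pd.DataFrame(rows, columns=["i", "j", "tau", "C", "r"])


def _centered_pair(
    ts: TimeSeriesSet, i: int, j: int, lag_samples: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Centered/raw overlapping segments of series i and lagged series j."""
    s = lag_samples
    xi_raw = ts.values[: ts.n_samples - s if s else None, i]
    xj_raw = ts.values[s:, j]
    xi = xi_raw - ts.values[:, i].mean()
    xj = xj_raw - ts.values[:, j].mean()
    return xi, xj, xi_raw, xj_raw


def lagged_covariance(
    ts: TimeSeriesSet,
    i: int,
    j: int,
    lag_samples: int,
    config: InferenceConfig = DEFAULT_CONFIG,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Density-weighted lagged covariance ``C_ij(tau)``.

    Each series is centered on its own full-series time mean; each scatter
    point ``(X_i(t_k), X_j(t_k + tau))`` is weighted by its Voronoi pair
    density.  ``weights`` overrides the density (used by the uniform-weight
    oracle in tests).  Returns ``nan`` if fewer than ``config.min_pairs``
    pairs overlap.
    """
    xi, xj, xi_raw, xj_raw = _centered_pair(ts, i, j, lag_samples)
    if xi.size < config.min_pairs:
        return float("nan")
    if weights is None:
        weights, _ = voronoi_density(np.column_stack([xi_raw, xj_raw]), config)
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(weights * xi * xj) / np.sum(weights))


def correlation_tensor(
    ts: TimeSeriesSet, grid: LagGrid, config: InferenceConfig = DEFAULT_CONFIG
) -> LaggedCorrelation:
    """Full lagged covariance/correlation tensor over the grid.

    By default each slice is normalized by the variances computed under the
    same Voronoi weights (a weighted Pearson coefficient, whose bound
    |r| <= 1 is guaranteed by the Cauchy-Schwarz inequality); the
    ``correlation_denominator = "tensor"`` variant divides by the
    independently weighted autocovariance tensor entries
    ``sqrt|C_ii(tau) C_jj(tau)|`` instead, which can exceed the bound on
    weighted data and is clipped.  Zero-variance species are marked
    undefined (NaN rows/columns) with a warning.
    """
    N, L = ts.n_species, grid.n_lags
    C = np.full((N, N, L), np.nan)
    r = np.full((N, N, L), np.nan)
    variances = np.array(
        [float(np.var(ts.values[:, k])) for k in range(N)]
    )
    zero_var = ~(variances > 0)
    if np.any(zero_var):
        names = [ts.species[k] for k in np.flatnonzero(zero_var)]
        logger.warning("zero-variance species excluded from correlations: %s", names)
    for a in range(N):
        for b in range(N):
            for ell, s in enumerate(grid.lag_samples):
                s = int(s)
                xi, xj, xi_raw, xj_raw = _centered_pair(ts, a, b, s)
                if xi.size < config.min_pairs:
                    continue
                w, _ = voronoi_density(np.column_stack([xi_raw, xj_raw]), config)
                wsum = np.sum(w)
                C[a, b, ell] = float(np.sum(w * xi * xj) / wsum)
                if zero_var[a] or zero_var[b]:
                    continue
                if config.correlation_denominator == "matched":
                    denom = np.sqrt(
                        float(np.sum(w * xi**2) * np.sum(w * xj**2)) / wsum**2
                    )
                    if denom > 0:
                        r[a, b, ell] = C[a, b, ell] / denom
    if config.correlation_denominator != "matched":
        for a in range(N):
            for b in range(N):
                if zero_var[a] or zero_var[b]:
                    continue
                denom = np.sqrt(np.abs(C[a, a, :] * C[b, b, :]))
                with np.errstate(invalid="ignore", divide="ignore"):
                    r[a, b, :] = np.where(denom > 0, C[a, b, :] / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    return LaggedCorrelation(species=list(ts.species), grid=grid, covariance=C, correlation=r)


@dataclass
class DistanceMatrix:
    """Max-|correlation| matrix and the derived interspecies distances.

    ``c_ordered[a, b] = max_tau |r_ab(tau)|`` keeps the directional values;
    the undirected ``c`` is their pairwise maximum, and
    ``d = sqrt|c_ii - 2 c_ij + c_jj|`` (or the literal no-root form when
    ``distance_square_root`` is off).  ``delta_d`` is filled by the
    uncertainty module.
    """

    species: list[str]
    c: np.ndarray
    c_ordered: np.ndarray
    d: np.ndarray
    tau_star: np.ndarray  # argmax lag (hours) per ordered pair
    delta_d: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, si in enumerate(self.species):
            for b, sj in enumerate(self.species):
                if a < b:
                    dd = self.delta_d[a, b] if self.delta_d is not None else np.nan
                    rows.append((si, sj, self.d[a, b], dd))
        return pd.DataFrame(rows, columns=["i", "j", "d", "delta_d"])


def distance_matrix(
    corr: LaggedCorrelation, config: InferenceConfig = DEFAULT_CONFIG
) -> DistanceMatrix:
    """Distances from the correlation tensor (symmetrized over lag direction)."""
    absr = np.abs(corr.correlation)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        c_ordered = np.nanmax(absr, axis=2)
        argmax = np.nanargmax(np.where(np.isnan(absr), -np.inf, absr), axis=2)
    tau_star = corr.grid.lags[argmax]
    c = np.fmax(c_ordered, c_ordered.T)
    cii = np.diag(c)
    quad = cii[:, None] - 2 * c + cii[None, :]
    if config.distance_square_root:
        d = np.sqrt(np.abs(quad))
    else:
        d = np.abs(quad)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        species=list(corr.species), c=c, c_ordered=c_ordered, d=d, tau_star=tau_star
    )
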