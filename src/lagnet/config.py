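"""Run-time configuration for the inference pipeline.

Every numerical tolerance, grid rule and threshold used by the pipeline is a
field of :class:`InferenceConfig`, so a single object (optionally loaded from
a YAML file) pins down an entire run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class InferenceConfig:
    """All tunable settings of the two-stage inference procedure.

    Attributes
    ----------
    eps_num:
        Numerical tolerance for identities such as ``r_ii(0) = 1``.
    default_relative_error:
        Relative measurement error assumed when a time series carries no
        explicit error columns (0.07 mirrors the synthetic noise level).
    min_pairs:
        Minimum number of overlapping ``(t, t + tau)`` sample pairs required
        for a lagged covariance to be defined.
    resample_step:
        Grid step (hours) for uniform resampling; ``None`` uses the smallest
        observed inter-sample gap.
    lag_max_points:
        Upper bound on the number of lag-grid points.  The lag stride is the
        smallest integer multiple of the sampling step that keeps the grid
        within this size.
    distance_square_root:
        ``True`` uses d = sqrt|c_ii - 2 c_ij + c_jj| (consistent with the
        1/(2d) factor of the distance-error formula); ``False`` restores the
        literal absolute-value form.
    correlation_denominator:
        ``"matched"`` normalizes each correlation slice by the variances
        computed under the same Voronoi weights (a weighted Pearson
        coefficient, |r| <= 1 guaranteed); ``"tensor"`` divides by the
        independently weighted autocovariance tensor entries, which can
        exceed the correlation bound on weighted data and is clipped.
    rel_error_floor:
        Floor applied to denominators (centered values, distances) before
        forming relative errors.
    mds_restarts / mds_fatol / mds_xatol / mds_max_iter_factor:
        Nelder-Mead settings for stress minimization; the iteration cap is
        ``mds_max_iter_factor * N * D``.
    normalized_stress:
        Divide the raw residual stress by sqrt(sum d_ij^2) (Kruskal stress-1
        style) instead of the raw residual form.
    histogram_min_bins:
        Bin rule for the distance histogram: ``max(histogram_min_bins,
        ceil(sqrt(P)))`` for P off-diagonal distances.
    threshold_override:
        Fixed edge threshold; ``None`` derives it from the histogram.
    threshold_fallback:
        Threshold used when fewer than three off-diagonal distances exist and
        no histogram can be formed (0.8, the fixed value used for the
        four-point experimental run).
    threshold_on_embedding:
        Threshold embedded distances when MDS ran; raw distances otherwise.
    orientation_tail_tol:
        Tolerance on the tail-decay statistic below which a zero-lag edge is
        marked reversible with no leader.
    weak_correlation:
        Edges whose correlation profile never exceeds this value are
        annotated "weak".
    prune_relative_error:
        Pruning threshold rho: reactions with ``dk/k >= rho`` (or ``k <= 0``)
        are removed.  1.0 follows the stated rule; 0.5 reproduces the
        50-percent-relative-error variant.
    sigma_floor_scale:
        Noise-level floor, as a fraction of the median absolute observation.
    gauss_hermite_nodes:
        Quadrature order for monomial expectations with non-integer
        exponents.
    bounds_factor:
        Optimizer box: each rate constant is bounded by ``bounds_factor``
        times its initial guess.
    """

    eps_num: float = 1e-9
    default_relative_error: float = 0.07
    min_pairs: int = 4
    resample_step: Optional[float] = None
    lag_max_points: int = 25
    distance_square_root: bool = True
    correlation_denominator: str = "matched"
    rel_error_floor: float = 1e-12
    mds_restarts: int = 20
    mds_fatol: float = 1e-8
    mds_xatol: float = 1e-8
    mds_max_iter_factor: int = 400
    normalized_stress: bool = False
    histogram_min_bins: int = 10
    threshold_override: Optional[float] = None
    threshold_fallback: float = 0.8
    threshold_on_embedding: bool = True
    orientation_tail_tol: float = 0.02
    weak_correlation: float = 0.05
    prune_relative_error: float = 1.0
    sigma_floor_scale: float = 1e-8
    gauss_hermite_nodes: int = 11
    bounds_factor: float = 10.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "InferenceConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InferenceConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_CONFIG = InferenceConfig()
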