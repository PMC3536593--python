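"""Lag estimation, Voronoi density, lagged covariance/correlation, distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lagnet.config import InferenceConfig
from lagnet.lagcorr import (
    UninformativeSeriesError,
    correlation_tensor,
    derivative,
    distance_matrix,
    lag_grid,
    lagged_covariance,
    species_lag,
    voronoi_density,
)

from conftest import make_timeseries


# ---------------------------------------------------------------- derivative


def test_derivative_exact_on_lines_and_constants():
    t = np.linspace(0, 10, 11)
    np.testing.assert_allclose(derivative(t, 3 * t + 1), 3.0, atol=1e-12)
    np.testing.assert_allclose(derivative(t, np.full_like(t, 7.0)), 0.0, atol=1e-12)


def test_derivative_quadratic_within_five_percent():
    t = np.arange(0.0, 11.0)
    d = derivative(t, t**2)
    assert d[5] == pytest.approx(10.0, rel=0.05)


def test_derivative_needs_three_points():
    with pytest.raises(ValueError):
        derivative(np.array([0.0, 1.0]), np.array([1.0, 2.0]))


# ---------------------------------------------------------------- species_lag


def test_species_lag_linear_series_equals_step():
    t = np.arange(0.0, 10.0, 0.5)
    assert species_lag(t, t) == pytest.approx(0.5, rel=1e-9)


def test_species_lag_matches_term_by_term_oracle():
    """Exponential series: compare against a brute-force sum of the defining terms."""
    t = np.linspace(0.0, 2.0, 40)
    x = np.exp(2 * t)
    deriv = derivative(t, x)
    terms = [
        abs(x[k] - x[k - 1]) / abs(deriv[k])
        for k in range(1, len(t))
        if deriv[k] != 0
    ]
    oracle = float(np.mean(terms))
    assert species_lag(t, x) == pytest.approx(oracle, rel=1e-12)


def test_species_lag_rejects_constant_series():
    t = np.linspace(0, 5, 20)
    with pytest.raises(UninformativeSeriesError):
        species_lag(t, np.full_like(t, 2.0))


# ---------------------------------------------------------------- lag grid


def test_lag_grid_bounded_by_fastest_timescale():
    t = np.arange(0.0, 40.0)
    ts = make_timeseries(t, {"A": np.exp(t / 3.0), "B": np.exp(t / 5.0)})
    grid = lag_grid(ts)
    # max lag never exceeds the fastest species timescale
    assert grid.lags[0] == 0
    assert grid.lags[-1] <= grid.tau_min + 1e-12
    assert grid.tau_min == pytest.approx(min(grid.species_lags.values()))
    if grid.lags.size > 1:
        assert np.allclose(np.diff(grid.lag_samples), grid.lag_samples[1])


def test_lag_grid_degenerates_to_zero_lag():
    t = np.linspace(0.0, 10.0, 11)
    # sawtooth: increments ~ derivative * dt, so <tau> ~ dt; force tau < step
    x = np.exp(5 * t)
    ts = make_timeseries(t, {"A": x})
    grid = lag_grid(ts)
    assert grid.lags[0] == 0.0
    assert grid.lags[-1] <= grid.tau_min + 1e-12


def test_lag_grid_requires_uniform_sampling():
    ts = make_timeseries([0, 1, 3, 7], {"A": [1, 2, 3, 4]})
    with pytest.raises(ValueError, match="uniform"):
        lag_grid(ts)


# ---------------------------------------------------------------- Voronoi


def test_voronoi_unit_square_corners_equal_density():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    p, areas = voronoi_density(pts)
    assert areas is not None
    np.testing.assert_allclose(areas, areas[0])
    np.testing.assert_allclose(p, p[0])
    assert np.sum(p * areas) == pytest.approx(1.0, abs=1e-6)


def test_voronoi_regular_grid_interior_cells_equal():
    xx, yy = np.meshgrid(np.arange(10.0), np.arange(10.0))
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    p, areas = voronoi_density(pts)
    interior = ((pts[:, 0] > 0) & (pts[:, 0] < 9) & (pts[:, 1] > 0) & (pts[:, 1] < 9))
    np.testing.assert_allclose(areas[interior], 1.0, rtol=1e-9)
    np.testing.assert_allclose(p[interior], p[interior][0], rtol=1e-9)
    assert np.sum(p * areas) == pytest.approx(1.0, abs=1e-6)


def test_voronoi_density_integrates_to_one(rng):
    pts = rng.standard_normal((300, 2))
    p, areas = voronoi_density(pts)
    assert areas is not None
    assert np.sum(p * areas) == pytest.approx(1.0, abs=1e-6)


def test_voronoi_agrees_with_fixed_grid_histogram(rng):
    """Per-cell density within a factor 2 of a 10x10 histogram estimate for
    at least 80% of points in interior histogram cells."""
    pts = rng.standard_normal((500, 2))
    p, areas = voronoi_density(pts)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    edges_x = np.linspace(lo[0], hi[0], 11)
    edges_y = np.linspace(lo[1], hi[1], 11)
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[edges_x, edges_y])
    cell_area = np.diff(edges_x)[0] * np.diff(edges_y)[0]
    ix = np.clip(np.searchsorted(edges_x, pts[:, 0]) - 1, 0, 9)
    iy = np.clip(np.searchsorted(edges_y, pts[:, 1]) - 1, 0, 9)
    hist_density = counts / (len(pts) * cell_area)
    # compare cell by cell: mean Voronoi density of the points in an
    # interior, occupied histogram cell vs that cell's histogram density
    ok = 0
    total = 0
    for cx in range(1, 9):
        for cy in range(1, 9):
            mask = (ix == cx) & (iy == cy)
            if not np.any(mask):
                continue
            total += 1
            ratio = p[mask].mean() / hist_density[cx, cy]
            ok += bool(0.5 < ratio < 2.0)
    assert total > 20
    assert ok / total >= 0.8


def test_voronoi_degenerate_scatters_fall_back_to_uniform():
    collinear = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
    p, areas = voronoi_density(collinear)
    assert areas is None
    np.testing.assert_allclose(p, 0.1)
    few = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
    p, areas = voronoi_density(few)
    assert areas is None


# ---------------------------------------------------------------- covariance


def test_lagged_covariance_trivial_identities():
    t = np.linspace(0, 10, 30)
    x = np.sin(t)
    ts = make_timeseries(t, {"A": x, "negA": -x, "const": np.full_like(t, 3.0)})
    c_aa = lagged_covariance(ts, 0, 0, 0)
    assert c_aa > 0
    assert lagged_covariance(ts, 0, 1, 0) == pytest.approx(-c_aa, rel=1e-12)
    assert lagged_covariance(ts, 0, 2, 0) == pytest.approx(0.0, abs=1e-12)
    assert lagged_covariance(ts, 2, 0, 0) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("lag", [0, 1, 3])
def test_uniform_weights_equal_textbook_cross_covariance(rng, lag):
    """With all densities equal, the estimator is the plain sample
    cross-covariance at that lag (full-series means, 1/n normalization)."""
    t = np.arange(0.0, 25.0)
    x = rng.uniform(0, 10, t.size)
    y = rng.uniform(0, 10, t.size)
    ts = make_timeseries(t, {"X": x, "Y": y})
    n = t.size - lag
    got = lagged_covariance(ts, 0, 1, lag, weights=np.ones(n))
    xc = x - x.mean()
    yc = y - y.mean()
    oracle = float(np.mean(xc[: t.size - lag if lag else None] * yc[lag:]))
    assert got == pytest.approx(oracle, abs=1e-12)


def test_lagged_covariance_undefined_with_too_few_pairs():
    ts = make_timeseries(np.arange(5.0), {"A": [1, 4, 2, 8, 5], "B": [2, 1, 7, 3, 6]})
    assert np.isnan(lagged_covariance(ts, 0, 1, 3))


# ---------------------------------------------------------------- correlation


def _noisy_pair_ts(rng, n=60):
    t = np.linspace(0, 6, n)
    x = np.exp(-t) + 0.05 * rng.standard_normal(n)
    y = 1 - np.exp(-t) + 0.05 * rng.standard_normal(n)
    return make_timeseries(t, {"A": x, "B": y, "C": 2 * x + 5})


def test_correlation_unit_diagonal_and_bound(rng):
    ts = _noisy_pair_ts(rng)
    corr = correlation_tensor(ts, lag_grid(ts))
    r0 = corr.correlation[:, :, 0]
    np.testing.assert_allclose(np.diag(r0), 1.0, atol=1e-9)
    finite = corr.correlation[np.isfinite(corr.correlation)]
    assert np.all(np.abs(finite) <= 1 + 1e-9)


def test_correlation_affine_invariance(rng):
    """r is unchanged when one series is rescaled affinely: A vs 2A+5 gives r=1."""
    ts = _noisy_pair_ts(rng)
    corr = correlation_tensor(ts, lag_grid(ts))
    a, c = ts.species.index("A"), ts.species.index("C")
    assert corr.correlation[a, c, 0] == pytest.approx(1.0, abs=1e-9)


def test_independent_white_noise_has_low_correlation(rng):
    """Sampling bound: two independent white-noise series of length 200 keep
    |r(0)| below 0.3 (checked across simulated replicates)."""
    t = np.arange(200.0)
    worst = 0.0
    for _ in range(30):
        ts = make_timeseries(t, {"A": rng.standard_normal(200), "B": rng.standard_normal(200)})
        corr = correlation_tensor(ts, lag_grid(ts))
        worst = max(worst, abs(corr.correlation[0, 1, 0]))
    assert worst < 0.3


def test_zero_variance_species_marked_undefined(rng):
    from lagnet.lagcorr import LagGrid

    t = np.linspace(0, 6, 30)
    ts = make_timeseries(t, {"A": np.sin(t), "Z": np.full_like(t, 4.0)})
    # the constant series admits no lag estimate, so supply the grid directly
    grid = LagGrid(step=t[1], lags=np.array([0.0, t[1]]), lag_samples=np.array([0, 1]),
                   species_lags={"A": 1.0, "Z": 1.0}, tau_min=1.0)
    corr = correlation_tensor(ts, grid)
    a, z = 0, 1
    assert np.all(np.isnan(corr.correlation[z, :, :]))
    assert np.all(np.isnan(corr.correlation[:, z, :]))
    assert np.isfinite(corr.correlation[a, a, 0])


# ---------------------------------------------------------------- distances


def _corr_from_matrix(c01: float):
    """Build a 2-species LaggedCorrelation with a prescribed |r| maximum."""
    from lagnet.lagcorr import LagGrid, LaggedCorrelation

    grid = LagGrid(
        step=1.0,
        lags=np.array([0.0]),
        lag_samples=np.array([0]),
        species_lags={"A": 1.0, "B": 1.0},
        tau_min=1.0,
    )
    r = np.ones((2, 2, 1))
    r[0, 1, 0] = r[1, 0, 0] = c01
    return LaggedCorrelation(species=["A", "B"], grid=grid, covariance=r.copy(), correlation=r)


@pytest.mark.parametrize(
    "c,expected",
    [(1.0, 0.0), (0.0, np.sqrt(2.0)), (0.68, 0.8)],
)
def test_distance_values(c, expected):
    dist = distance_matrix(_corr_from_matrix(c))
    assert dist.d[0, 1] == pytest.approx(expected, abs=1e-12)
    assert dist.d[0, 0] == 0.0


def test_distance_literal_no_root_variant():
    cfg = InferenceConfig(distance_square_root=False)
    dist = distance_matrix(_corr_from_matrix(0.68), cfg)
    assert dist.d[0, 1] == pytest.approx(2 * 0.32, abs=1e-12)


@given(st.floats(min_value=0.0, max_value=1.0))
@settings(max_examples=50, deadline=None)
def test_distance_monotone_decreasing_in_correlation(c):
    d = distance_matrix(_corr_from_matrix(c)).d[0, 1]
    d_higher = distance_matrix(_corr_from_matrix(min(1.0, c + 0.05))).d[0, 1]
    assert d_higher <= d + 1e-12
    assert 0.0 <= d <= 2.0
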