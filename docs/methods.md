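# Methods

This note documents the models, numerical choices and known limitations of
`lagnet`.  It is written for users who need to judge what the package's
results do and do not establish, and for maintainers who need to know why
each design decision was made.

## 1. Scope and data model

The package identifies first-order (and, in the calibration stage,
general mass-action) reaction networks among *measured* species from their
concentration time series.  A `TimeSeriesSet` holds strictly increasing
sampling times (hours), an m×N matrix of concentrations (nM) and optional
per-value absolute errors.  When errors are unmeasured, downstream error
propagation assumes a relative error of 7% of |X| (configurable), matching
the noise level of the validation benchmark.  Unmeasured intermediates
(enzymes, transporters) are not modeled; their effect surfaces as
"plausible" shortcut reactions between observed species.

Non-uniformly sampled data must be resampled (`resample_uniform`) before
lag analysis.  Interpolation uses the shape-preserving piecewise-cubic
PCHIP interpolant: it is exact on affine series, never overshoots monotone
segments, and its derivative is the package's estimate of dX/dt.  PCHIP
sets the derivative to zero at interior local extrema; on noisy dense data
many samples are extrema, and the corresponding terms of the timescale
estimator below are skipped.

## 2. Lag grid

The characteristic response timescale of species i is estimated as

    ⟨τ_i⟩ = mean over k of |X_i(t_k) − X_i(t_{k−1})| / |dX_i/dt(t_k)| ,

terms with vanishing derivative skipped; a constant series admits no
estimate and is an error.  The lag grid spans [0, τ_min] with
τ_min = min_i ⟨τ_i⟩, in integer multiples of the sampling step (no
interpolation is ever applied to form lagged pairs).  When τ_min covers
many samples the stride is raised to the smallest multiple keeping at most
`lag_max_points` (default 25) grid points.  On densely sampled noisy data
this estimator is dominated by the noise-to-derivative ratio and typically
yields a τ_min of one to a few sampling steps, so most of the correlation
signal is carried by the zero-lag slice; coarsely sampled data (the
intended experimental regime) yield multi-hour lag windows.

## 3. Voronoi pair density and lagged correlation

For each ordered pair (i, j) and lag τ, the scatter of
(X_i(t_k), X_j(t_k+τ)) is tessellated with Voronoi cells and the pair
density at each point is the inverse cell area, normalized so that
Σ p·Area = 1.  Unbounded hull cells are clipped exactly by reflecting the
scatter across the four edges of its bounding box before tessellating; the
box is padded by half the median nearest-neighbour distance.  Scatters
with fewer than 4 points, collinear points (detected by singular-value
rank), coincident points producing invalid cells, or qhull failures fall
back to uniform weights with a logged warning — on the benchmark about 5%
of slices (mostly the degenerate diagonal scatters at lag 0) take this
path.

The lagged covariance is the density-weighted time average of the product
of centered series, each centered on its own full-series mean.  With
uniform weights it reduces exactly to the textbook sample cross-covariance
(1/n normalization, full-series means), which the tests verify to 1e−12.

Correlations are normalized per slice by the variances computed **under
the same Voronoi weights** (a weighted Pearson coefficient), so
|r| ≤ 1 holds by the Cauchy–Schwarz inequality and r_ii(0) = 1 exactly.
Normalizing instead by the independently weighted autocovariance tensor
entries (`correlation_denominator="tensor"`) reproduces the literal
ratio C_ij/√|C_ii C_jj| but routinely exceeds the correlation bound on
weighted data — on the benchmark dozens of pairs clip at exactly 1,
collapsing their distances to zero — and is therefore not the default.

Distances are d_ij = √|c_ii − 2c_ij + c_jj| with c_ij = max_τ |r_ij(τ)|
symmetrized by the larger of the two lag directions.  The square root is
the default because the distance-error formula carries the 1/(2d) factor
of a root; `distance_square_root=false` restores the plain absolute-value
form (d = 2(1−c) on the unit diagonal).

## 4. Error propagation

All propagation is first order, with the density-error contribution
assumed negligible:

* centered-value error: δS(t) = δX(t) + δX̄ (absolute sum);
* per-time covariance error: √((δS_i S_j)² + (S_i δS_j)²) — the absolute
  form of the relative root-sum-square, finite where a centered value
  vanishes; δC(τ) is the plain time mean;
* correlation error: δr = √((δC_ij/√|C_ii C_jj|)² + r²(δC_ii/C_ii)²/4
  + r²(δC_jj/C_jj)²/4), evaluated in the form that stays finite as
  C_ij → 0;
* distance error: δd = (δc_ii + 2δc_ij + δc_jj)/(2d) with
  δc = max_τ |δr(τ)|, the off-diagonal entry taken conservatively as the
  larger lag direction; a vanishing off-diagonal distance gets the
  root-form limit δd = √(δc-sum) and a warning;
* stress error: δS_D = (1/S_D) Σ_{i<j} |d_ij − ‖z_i−z_j‖| δd_ij (zero at a
  perfect embedding) — the standard first-order propagation of the stress
  through the distance errors, verified against a numeric Jacobian in the
  tests.

The mixture of absolute-sum and quadrature conventions follows the source
formulas exactly; the tests' finite-difference oracles use matching
conventions.  Note that at 7% measurement noise these formulas are
conservative: on the benchmark δd typically *exceeds* d, so the embedding
admissibility band is generous and a 2-D or 3-D embedding is almost always
accepted.

## 5. Embedding, dimension choice, thresholding

The Kruskal–Shepard stress is the raw residual root-sum-of-squares over
unordered pairs counted once (doubling the sum would only rescale S by √2;
the choice is fixed and documented).  A normalized (stress-1 style)
variant is available behind `normalized_stress`.  Minimization is
derivative-free Nelder–Mead over the N·D coordinates with 20 seeded
restarts: restart 0 starts from classical (Torgerson) scaling, the rest
from uniform random configurations on a box scaled to the largest
distance.  Convergence tolerances are 1e−8 with an iteration cap of
400·N·D; profiling showed tighter settings (1e−10, 10⁴·N·D) cost two
orders of magnitude more time with no stress improvement beyond 1e−8.
The translation gauge is fixed by centering; rotations are left free (the
stress is rotation invariant, which the tests check).

Dimension selection fits D = 2 and D = 3; a dimension is admissible when
every embedded distance lies within [d − δd, d + δd], and D = 3 is chosen
over an admissible D = 2 only when S₃ + δS₃ ≤ S₂ + δS₂.  When neither is
admissible the scaling step is skipped and the raw distance matrix is
thresholded directly.

The edge threshold is derived from a histogram of the off-diagonal
distances — embedded distances when scaling ran (that being its purpose),
raw otherwise, overridable by config — with
max(10, ⌈√P⌉) bins; the threshold is the mean center of the modal bin(s).
With fewer than three off-diagonal distances no histogram exists and a
fixed fallback threshold of 0.8 is used (the value used for the four-point
experimental data set).  Species at distance ≤ threshold are connected.

## 6. Orientation

Only positive lags are scanned.  r_ij(τ) correlates X_i(t) with X_j(t+τ),
so a peak at τ > 0 means i leads j.  If exactly one ordering peaks at a
positive lag, that species leads at that lag.  Otherwise the two
orderings' tail decays are compared (mean |r| over the upper half of the
lag grid, tolerance 0.02): the slower-decaying ordering leads;
indistinguishable tails mark the edge reversible with no leader.  Edges
whose profile never exceeds 0.05 are annotated weak.  Orientation is an
annotation only: both opposed first-order conversions are always emitted
per edge, and elimination is delegated to the calibration stage.

## 7. Calibration: increment likelihood

Each reaction contributes one nonnegative rate constant; a reaction
A → B adds −k·X_A to f_A and +k·X_A to f_B.  The rate equations are
discretized as increments with the explicit time-step factor,
D_i(t_k) ≈ (t_k − t_{k−1})·f_i(X(t_{k−1})) — the factor is required for
dimensional consistency at non-unit steps.  I.i.d. Gaussian measurement
noise with variance σ² makes each species' increment vector Gaussian with
tridiagonal covariance (2σ² diagonal, −σ² off-diagonals); its determinant
is (M+1)σ^{2M} and solves use the symmetric banded factorization.  The
mean uses E[f_i] under the Gaussian posterior of the true state: Gaussian
moments in closed form for integer exponents, Gauss–Hermite quadrature
(11 nodes, integrand clipped at zero with a warning when X̂ − 4σ < 0) for
non-integer ones.

Fitting maximizes the joint likelihood over (θ, σ) with L-BFGS-B:
warm start from a nonnegative least-squares regression of increments on
monomial values; box bounds [0, 10× initial guess] per parameter (a zero
initial guess gets 10× the median positive guess); σ floored at
1e−8 × median |X̂|.  Standard errors are the square roots of the diagonal
of the pseudo-inverse of a central-difference Hessian of the negative
log-likelihood at the optimum; a singular or indefinite Hessian marks the
affected parameters unidentifiable (Δk = ∞), which guarantees their
pruning.  Pruning removes reactions with k̂ ≤ 0 or Δk/k̂ ≥ ρ; ρ defaults
to 1.0 (the stated rule), with ρ = 0.5 available for the stricter
50%-relative-error variant.

A caveat verified by simulation: observed-information errors match the
true sampling spread of k̂, which makes the probability of pruning a
genuinely absent reaction roughly 0.85–0.9 per replicate (a boundary zero
or a sub-unit ratio), not 1.  Error-propagation-based standard errors
(as advertised by the original calibration tool, formulas unpublished)
would be larger and prune more aggressively.  This is the main reason the
calibration stage occasionally retains a shortcut reaction.

## 8. Synthetic benchmark

The generator integrates the 19-reaction gemcitabine reference network
(LSODA, rtol 1e−8) and samples 200 equally spaced points on [0, 20] h —
the validation protocol.  Observations are X̂ = X(1 + 0.07ε), ε ~ N(0,1),
clipped at zero, with the per-value error column δX = 0.07·X; the noise
realization is reproducible from the seed, and an additive-noise variant
exists behind a flag.  Initial state: 1000 nM extracellular drug, all
other pools zero (the nM scale of the published concentration figures;
configurable).  Eleven of the nineteen true rate constants use published
point estimates; the remaining eight are set once by analogy with the
homologous steps (0.6 /h forward phosphorylation, 0.25 /h reverse,
0.1 /h extracellular deamination, 0.05 /h monophosphate deamination) and
are not calibrated to any output.

What the generator emulates: relative measurement noise, a realistic
stiff spread of rates (0.05–7 /h), conserved mass, and the bolus-driven
transient of an uptake experiment.  What it does not emulate: replicate
averaging, non-uniform sampling, systematic (non-Gaussian) measurement
error, enzyme saturation (Michaelis–Menten kinetics), and unobserved
species.  Passing the synthetic benchmark therefore demonstrates internal
consistency of the two stages under the stated noise model, not
performance on sparse four-point experimental series.

Because the true constants of the original validation run were never
published, the benchmark's trajectories — and hence the exact sensitivity
and accuracy — are not expected to reproduce the published run
point-for-point.  Under this package's conditions the species are more
strongly mutually correlated than in the published tables, the histogram
threshold lands lower, and the median detected-edge count is smaller;
median sensitivity (plausibles included) sits near the low 50s percent and
median accuracy in the high 50s to mid 60s over ten seeds, with
substantial seed-to-seed spread.  These numbers are computed by
`scripts/acceptance.py` and the end-to-end tests, and nothing in this note
asserts values beyond what those runs print.

## 9. Degenerate inputs and numerical guards

Constant series: rejected by the lag estimator; excluded (NaN) from
correlations with a warning.  Fewer than `min_pairs` (4) overlapping
samples at a lag: that covariance entry is undefined and propagates as
NaN.  Single-species input: the pipeline completes with an empty edge set.
Two-species input: no distance histogram is possible; the fallback
threshold applies.  Relative-error denominators are floored at 1e−12.
|r| is clipped to [−1, 1] (relevant only for the non-default tensor
normalization).  All tolerances are config keys
(`lagnet.config.InferenceConfig`), and every pipeline run is fully
determined by (data, config, seed).

## 10. Known limitations

* The timescale estimator ⟨τ_i⟩ conflates noise with dynamics on densely
  sampled data, shrinking the lag window (Section 2); orientation then
  rests mostly on the zero-lag tail rule.
* Distance-based detection cannot separate direct reactions from strongly
  coupled two-step chains; the plausible (P) class and the pruning stage
  mitigate but do not eliminate this.
* The constant-σ noise model is misspecified under multiplicative noise;
  large-amplitude species dominate σ̂, and standard errors for parameters
  tied to small-amplitude species are optimistic.
* The histogram threshold is sensitive to the bin rule (hence a config
  key) and to run-to-run variation in the distance distribution.
* Nelder–Mead stress minimization offers no global guarantee; restarts
  plus the classical-scaling start recover exactly embeddable
  configurations in practice (tested), but high-stress fits may be local.
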