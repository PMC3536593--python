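"""Maximum-likelihood estimation of generalized-mass-action rate constants.

Each species obeys a generalized mass action (GMA) rate law,

    dX_i/dt = f_i(X; theta) = sum_h  +/- theta_h  prod_w X_w^{alpha_w},

and a reaction ``A -> B`` with constant k contributes ``-k X_A`` to f_A and
``+k X_A`` to f_B.  The rate equations are discretized as increments
``D_i(t_k) = X_i(t_k) - X_i(t_{k-1}) ~ (t_k - t_{k-1}) f_i(X(t_{k-1}))``.
Observations carry i.i.d. Gaussian noise with variance sigma^2, which makes
the increment vector of each species Gaussian with tridiagonal covariance
(diagonal 2 sigma^2, off-diagonals -sigma^2: consecutive increments share a
noisy endpoint) and mean ``(t_k - t_{k-1}) E[f_i]``, where the expectation
integrates each monomial over the Gaussian posterior of the true state
(closed-form Gaussian moments for integer exponents, Gauss-Hermite
quadrature otherwise).  The joint likelihood is maximized over the
nonnegative rate constants and the noise level; standard errors come from
the observed information, and reactions whose relative standard error
reaches the pruning threshold are discarded as null kinetics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.linalg import solveh_banded
from scipy.optimize import minimize, nnls
from sklearn.base import BaseEstimator

from .config import DEFAULT_CONFIG, InferenceConfig
from .data_io import Reaction, ReactionNetwork, TimeSeriesSet

logger = logging.getLogger(__name__)

__all__ = [
    "Monomial",
    "GMAModel",
    "IncrementData",
    "ParameterEstimate",
    "build_gma",
    "increments",
    "gaussian_moment",
    "expected_rate",
    "BandedCovariance",
    "banded_covariance",
    "neg_log_likelihood",
    "GMARateEstimator",
    "fit",
    "prune",
]


@dataclass(frozen=True)
class Monomial:
    """One signed power-law term ``sign * theta_param * prod X_w^alpha_w``."""

    sign: float
    param: int
    exponents: tuple[tuple[str, float], ...]


@dataclass
class GMAModel:
    """Rate functions of a reaction network in generalized-mass-action form."""

    species: list[str]
    parameter_names: list[str]
    terms: dict[str, list[Monomial]]

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def species_in_rate(self, sp: str) -> set[str]:
        """Species appearing in f_sp (the K_i index set)."""
        return {w for mono in self.terms[sp] for w, _ in mono.exponents}


def build_gma(
    net: ReactionNetwork, observed_species: Optional[Sequence[str]] = None
) -> GMAModel:
    """Assemble the GMA rate functions induced by a mass-action reaction list.

    Every reactant of a reaction loses one unit of flux ``k * prod(X_r)``
    and every product gains one; distinct reactions keep distinct
    parameters even when structurally identical.  Reactions referencing
    species outside ``observed_species`` (when given) are rejected: the
    likelihood assumes every modeled species is measured.
    """
    species = list(observed_species) if observed_species is not None else net.species
    known = set(species)
    terms: dict[str, list[Monomial]] = {sp: [] for sp in species}
    names: list[str] = []
    for p, rxn in enumerate(net.reactions):
        involved = set(rxn.reactants) | set(rxn.products)
        if not involved <= known:
            raise ValueError(
                f"reaction {rxn.id} references unmeasured species "
                f"{sorted(involved - known)}"
            )
        names.append(rxn.id)
        expo: dict[str, float] = {}
        for r in rxn.reactants:
            expo[r] = expo.get(r, 0.0) + 1.0
        exponents = tuple(sorted(expo.items()))
        for r in rxn.reactants:
            terms[r].append(Monomial(sign=-1.0, param=p, exponents=exponents))
        for pr in rxn.products:
            terms[pr].append(Monomial(sign=+1.0, param=p, exponents=exponents))
    return GMAModel(species=species, parameter_names=names, terms=terms)


@dataclass
class IncrementData:
    """First differences of the observed concentrations."""

    species: list[str]
    times: np.ndarray
    increments: np.ndarray  # (M, N)
    dt: np.ndarray  # (M,) time-step factors for the model prediction

    @property
    def M(self) -> int:
        return int(self.increments.shape[0])


def increments(ts: TimeSeriesSet) -> IncrementData:
    """Per-species increments ``D_i(t_k) = X_i(t_k) - X_i(t_{k-1})``."""
    if ts.n_samples < 2:
        raise ValueError("need at least 2 samples to form increments")
    return IncrementData(
        species=list(ts.species),
        times=ts.times.copy(),
        increments=np.diff(ts.values, axis=0),
        dt=np.diff(ts.times),
    )


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def gaussian_moment(
    xhat: np.ndarray, sigma: float, alpha: float, gh_nodes: int = 11
) -> np.ndarray:
    """``E[X^alpha]`` for ``X ~ N(xhat, sigma^2)``.

    Integer exponents use the closed-form Gaussian moment expansion
    (``E[X] = xhat``, ``E[X^2] = xhat^2 + sigma^2``, ...).  Non-integer
    exponents use Gauss-Hermite quadrature with the integrand clipped at
    zero (a warning is logged where the Gaussian has appreciable mass below
    zero).
    """
    xhat = np.asarray(xhat, dtype=float)
    if sigma == 0:
        return xhat**alpha
    if float(alpha).is_integer():
        n = int(alpha)
        out = np.zeros_like(xhat)
        for j in range(0, n + 1, 2):
            out += (
                math.comb(n, j)
                * xhat ** (n - j)
                * sigma**j
                * _double_factorial(j - 1)
            )
        return out
    if np.any(xhat - 4 * sigma < 0):
        logger.warning(
            "gaussian_moment: non-integer exponent with mass below zero; clipping"
        )
    nodes, weights = np.polynomial.hermite.hermgauss(gh_nodes)
    x = xhat[..., None] + math.sqrt(2.0) * sigma * nodes
    vals = np.clip(x, 0.0, None) ** alpha
    return (vals @ weights) / math.sqrt(math.pi)


def _design_matrices(
    model: GMAModel, values: np.ndarray, sigma: float, gh_nodes: int
) -> dict[str, np.ndarray]:
    """Per species, the (M, n_terms) matrix of signed monomial expectations
    evaluated at the observed states ``t_0 .. t_{M-1}``."""
    idx = {sp: k for k, sp in enumerate(model.species)}
    states = values[:-1, :]  # X-hat(t_{k-1})
    moment_cache: dict[tuple[str, float], np.ndarray] = {}

    def moment(sp: str, alpha: float) -> np.ndarray:
        key = (sp, alpha)
        if key not in moment_cache:
            moment_cache[key] = gaussian_moment(states[:, idx[sp]], sigma, alpha, gh_nodes)
        return moment_cache[key]

    out: dict[str, np.ndarray] = {}
    for sp in model.species:
        monos = model.terms[sp]
        B = np.empty((states.shape[0], len(monos)))
        for h, mono in enumerate(monos):
            col = np.full(states.shape[0], mono.sign)
            for w, alpha in mono.exponents:
                col = col * moment(w, alpha)
            B[:, h] = col
        out[sp] = B
    return out


def expected_rate(
    model: GMAModel,
    state: Union[np.ndarray, dict[str, float]],
    theta: np.ndarray,
    sigma: float,
    gh_nodes: int = 11,
) -> np.ndarray:
    """Expected rates ``m_i = E[f_i]`` at one observed state.

    Each true concentration is independently normal around its observed
    value with variance ``sigma^2``; expectations of monomials factorize over
    species.
    """
    if isinstance(state, dict):
        state = np.array([state[sp] for sp in model.species], dtype=float)
    values = np.vstack([state, state])  # _design_matrices drops the last row
    B = _design_matrices(model, values, sigma, gh_nodes)
    theta = np.asarray(theta, dtype=float)
    out = np.empty(len(model.species))
    for k, sp in enumerate(model.species):
        params = np.array([m.param for m in model.terms[sp]], dtype=int)
        out[k] = B[sp][0] @ theta[params] if params.size else 0.0
    return out


@dataclass
class BandedCovariance:
    """Tridiagonal covariance of an increment vector: 2 sigma^2 on the
    diagonal, -sigma^2 on the first off-diagonals."""

    sigma: float
    M: int

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma = 0 gives a singular covariance; floor sigma first")

    def dense(self) -> np.ndarray:
        s2 = self.sigma**2
        C = 2 * s2 * np.eye(self.M)
        off = -s2 * np.ones(self.M - 1)
        C += np.diag(off, 1) + np.diag(off, -1)
        return C

    def log_determinant(self) -> float:
        # det of the unit tridiagonal (2, -1) matrix is M + 1
        return float(2 * self.M * math.log(self.sigma) + math.log(self.M + 1))

    def determinant(self) -> float:
        return float(math.exp(self.log_determinant()))

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        if self.M == 1:
            return np.asarray(rhs, dtype=float) / (2 * self.sigma**2)
        ab = np.zeros((2, self.M))
        ab[0, 1:] = -1.0
        ab[1, :] = 2.0
        return solveh_banded(ab, np.asarray(rhs, dtype=float)) / self.sigma**2


def banded_covariance(sigma: float, M: int) -> BandedCovariance:
    return BandedCovariance(sigma=float(sigma), M=int(M))


def neg_log_likelihood(
    model: GMAModel,
    data: Union[TimeSeriesSet, IncrementData],
    theta: np.ndarray,
    sigma: float,
    values: Optional[np.ndarray] = None,
    gh_nodes: int = 11,
    _design: Optional[dict[str, np.ndarray]] = None,
) -> float:
    """Exact negative log-likelihood of the observed increments.

    ``sum_i 1/2 (D_i - m_i)^T C^{-1} (D_i - m_i) + (N/2) log det C
    + (N M / 2) log 2 pi`` with ``m_i(t_{k-1}) = (t_k - t_{k-1}) E[f_i]``
    (the time-step factor of the finite-difference discretization).
    Non-finite predictions return ``+inf`` so optimizers can recover.
    """
    if isinstance(data, TimeSeriesSet):
        inc = increments(data)
        values = data.values
    else:
        inc = data
        if values is None:
            raise ValueError("values of the observed states are required")
    theta = np.asarray(theta, dtype=float)
    if sigma <= 0:
        return float("inf")
    cov = BandedCovariance(sigma=float(sigma), M=inc.M)
    B = _design if _design is not None else _design_matrices(model, values, sigma, gh_nodes)
    nll = 0.0
    N = len(model.species)
    for k, sp in enumerate(model.species):
        params = np.array([m.param for m in model.terms[sp]], dtype=int)
        pred = inc.dt * (B[sp] @ theta[params]) if params.size else np.zeros(inc.M)
        if not np.all(np.isfinite(pred)):
            logger.warning("non-finite model prediction for %s", sp)
            return float("inf")
        resid = inc.increments[:, k] - pred
        nll += 0.5 * float(resid @ cov.solve(resid))
    nll += 0.5 * N * cov.log_determinant()
    nll += 0.5 * N * inc.M * math.log(2 * math.pi)
    return float(nll)


@dataclass
class ParameterEstimate:
    """Fitted rate constants with standard errors and noise level."""

    parameter_names: list[str]
    theta: np.ndarray
    stderr: np.ndarray
    sigma: float
    nll: float
    converged: bool
    message: str = ""

    @property
    def relative_error(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.theta > 0, self.stderr / self.theta, np.inf)

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            name: (float(k), float(dk))
            for name, k, dk in zip(self.parameter_names, self.theta, self.stderr)
        }


def _numeric_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    H = np.empty((n, n))
    f0 = fun(x)
    for a in range(n):
        ea = np.zeros(n)
        ea[a] = h[a]
        fpp = fun(x + ea)
        fmm = fun(x - ea)
        H[a, a] = (fpp - 2 * f0 + fmm) / h[a] ** 2
        for b in range(a + 1, n):
            eb = np.zeros(n)
            eb[b] = h[b]
            H[a, b] = H[b, a] = (
                fun(x + ea + eb) - fun(x + ea - eb) - fun(x - ea + eb) + fun(x - ea - eb)
            ) / (4 * h[a] * h[b])
    return H


class GMARateEstimator(BaseEstimator):
    """Joint maximum-likelihood fit of rate constants and noise level.

    Parameters
    ----------
    network : ReactionNetwork
        Hypothesized mass-action reactions; one rate constant each.
    config : InferenceConfig, optional
        Carries the variance floor, bounds factor and quadrature order.

    Attributes
    ----------
    theta_ : ndarray
        Estimated rate constants (nonnegative).
    stderr_ : ndarray
        Standard errors from the observed information; ``inf`` marks an
        unidentifiable parameter (which the pruning rule then removes).
    sigma_ : float
        Estimated measurement noise level.
    nll_ : float
        Negative log-likelihood at the optimum.
    estimate_ : ParameterEstimate
    """

    def __init__(self, network: Optional[ReactionNetwork] = None,
                 config: Optional[InferenceConfig] = None):
        self.network = network
        self.config = config

    def fit(self, X: TimeSeriesSet, y=None) -> "GMARateEstimator":
        if self.network is None:
            raise ValueError("network must be provided")
        cfg = self.config or DEFAULT_CONFIG
        ts = X
        model = build_gma(self.network, observed_species=None)
        missing = set(model.species) - set(ts.species)
        if missing:
            raise ValueError(f"network references unmeasured species {sorted(missing)}")
        # reorder the model onto the time-series species that actually appear
        model = build_gma(self.network, observed_species=ts.species)
        inc = increments(ts)
        P = model.n_parameters
        if P < 1:
            raise ValueError("need at least one parameter to fit")
        if inc.M * len(model.species) <= P + 1:
            raise ValueError("more parameters than increments; underdetermined fit")

        # --- warm start: nonnegative least squares on raw monomials (sigma = 0)
        B0 = _design_matrices(model, ts.values, 0.0, cfg.gauss_hermite_nodes)
        rows = []
        targets = []
        for k, sp in enumerate(model.species):
            params = np.array([m.param for m in model.terms[sp]], dtype=int)
            G = np.zeros((inc.M, P))
            if params.size:
                np.add.at(G.T, params, (inc.dt[:, None] * B0[sp]).T)
            rows.append(G)
            targets.append(inc.increments[:, k])
        G = np.vstack(rows)
        yvec = np.concatenate(targets)
        theta0, _ = nnls(G, yvec)
        resid0 = yvec - G @ theta0
        sigma_floor = max(
            cfg.sigma_floor_scale * float(np.median(np.abs(ts.values))), 1e-12
        )
        sigma0 = max(math.sqrt(float(np.mean(resid0**2)) / 2.0), sigma_floor)

        # --- bounds: [0, bounds_factor x initial guess] per parameter
        positive = theta0[theta0 > 0]
        ref = float(np.median(positive)) if positive.size else 1.0
        upper = cfg.bounds_factor * np.maximum(theta0, ref)
        bounds = [(0.0, float(u)) for u in upper]
        bounds.append((sigma_floor, cfg.bounds_factor * max(sigma0, sigma_floor)))
        x0 = np.append(np.minimum(theta0, upper), sigma0)

        design_cache: dict[float, dict[str, np.ndarray]] = {}

        def designs(sigma: float) -> dict[str, np.ndarray]:
            if sigma not in design_cache:
                if len(design_cache) > 8:
                    design_cache.clear()
                design_cache[sigma] = _design_matrices(
                    model, ts.values, sigma, cfg.gauss_hermite_nodes
                )
            return design_cache[sigma]

        def objective(x: np.ndarray) -> float:
            return neg_log_likelihood(
                model, inc, x[:P], x[P], values=ts.values,
                gh_nodes=cfg.gauss_hermite_nodes, _design=designs(float(x[P])),
            )

        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "maxfun": 200_000},
        )
        xopt = res.x if res.fun <= objective(x0) else x0
        nll_opt = min(float(res.fun), objective(x0))
        if not res.success:
            logger.warning("GMA fit did not converge: %s", res.message)

        # --- standard errors from the observed information
        stderr = np.full(P, np.inf)
        try:
            H = _numeric_hessian(objective, xopt)
            cov = np.linalg.pinv(H)
            diag = np.diag(cov)[:P]
            good = np.isfinite(diag) & (diag > 0)
            stderr[good] = np.sqrt(diag[good])
        except Exception as exc:  # singular/noisy Hessian: parameters unidentifiable
            logger.warning("Hessian inversion failed (%s); stderr set to inf", exc)

        self.model_ = model
        self.theta_ = xopt[:P]
        self.stderr_ = stderr
        self.sigma_ = float(xopt[P])
        self.nll_ = nll_opt
        self.converged_ = bool(res.success)
        self.estimate_ = ParameterEstimate(
            parameter_names=list(model.parameter_names),
            theta=self.theta_.copy(),
            stderr=stderr.copy(),
            sigma=self.sigma_,
            nll=self.nll_,
            converged=self.converged_,
            message=str(res.message),
        )
        return self


def fit(
    model_or_network: Union[GMAModel, ReactionNetwork],
    ts: TimeSeriesSet,
    config: InferenceConfig = DEFAULT_CONFIG,
) -> ParameterEstimate:
    """Functional wrapper over :class:`GMARateEstimator`."""
    if isinstance(model_or_network, GMAModel):
        raise TypeError("pass the ReactionNetwork; the GMA model is rebuilt internally")
    est = GMARateEstimator(network=model_or_network, config=config).fit(ts)
    return est.estimate_


def prune(
    net: ReactionNetwork,
    estimate: Optional[ParameterEstimate] = None,
    rho: float = 1.0,
) -> ReactionNetwork:
    """Remove null-kinetics reactions.

    A reaction is discarded when its rate constant is nonpositive or its
    relative standard error ``dk/k`` is **equal or greater than** ``rho``
    (default 1).  Rates come from ``estimate`` (matched by reaction id) or,
    when absent, from the ``k ± dk`` annotations on the network itself.
    Surviving reactions carry their estimates.
    """
    rates: dict[str, tuple[float, float]]
    if estimate is not None:
        rates = estimate.as_dict()
    else:
        rates = {}
        for r in net.reactions:
            if r.rate is None or r.rate_error is None:
                raise ValueError(
                    f"reaction {r.id} has no rate estimate; fit before pruning"
                )
            rates[r.id] = (r.rate, r.rate_error)
    kept: list[Reaction] = []
    for r in net.reactions:
        if r.id not in rates:
            raise KeyError(f"no estimate for reaction {r.id}")
        k, dk = rates[r.id]
        if k <= 0 or not np.isfinite(dk) or dk / k >= rho:
            continue
        kept.append(Reaction(id=r.id, reactants=r.reactants, products=r.products,
                             rate=k, rate_error=dk))
    return ReactionNetwork(reactions=kept, species_universe=net.species_universe)
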