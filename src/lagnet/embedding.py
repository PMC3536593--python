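"""Least-squares (Kruskal-Shepard) multidimensional scaling and graph extraction.

The distance matrix is embedded in D = 2 or 3 dimensions by minimizing the
raw residual stress

    S_D = sqrt( sum_{i<j} (d_ij - ||z_i - z_j||)^2 )

with a derivative-free downhill-simplex (Nelder-Mead) search restarted from
seeded random configurations (plus one classical-scaling warm start).  A
dimension is admissible when every embedded distance lies within the error
band ``[d_ij - delta_d_ij, d_ij + delta_d_ij]``; D = 3 is preferred over
D = 2 only when ``S_3 + dS_3 <= S_2 + dS_2``.  When no dimension is
admissible, scaling is skipped and the raw distances are thresholded
directly.  The edge threshold is the mean bin center of the modal bin(s) of
the distance histogram; species closer than the threshold are connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Union

import networkx as nx
import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .config import DEFAULT_CONFIG, InferenceConfig
from .lagcorr import DistanceMatrix
from .uncertainty import stress_error

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "UndirectedNetwork",
    "stress",
    "StressMDS",
    "fit_embedding",
    "select_dimension",
    "edge_threshold",
    "build_undirected",
]


def stress(coords: np.ndarray, dist: np.ndarray, normalized: bool = False) -> float:
    """Residual stress of a configuration against target distances.

    Each unordered pair is counted once; undefined (NaN) target distances are
    excluded with a warning.  ``normalized`` divides by ``sqrt(sum d^2)``
    (Kruskal stress-1 style) instead of the raw residual form.
    """
    coords = np.asarray(coords, dtype=float)
    dist = np.asarray(dist, dtype=float)
    iu = np.triu_indices_from(dist, k=1)
    target = dist[iu]
    ok = np.isfinite(target)
    if not np.all(ok):
        logger.warning("stress: excluding %d undefined distances", int((~ok).sum()))
    fitted = pdist(coords)
    ss = np.sum((target[ok] - fitted[ok]) ** 2)
    if normalized:
        denom = np.sum(target[ok] ** 2)
        return float(np.sqrt(ss / denom)) if denom > 0 else 0.0
    return float(np.sqrt(ss))


def _classical_scaling(dist: np.ndarray, n_components: int) -> np.ndarray:
    """Torgerson double-centering start for the simplex search."""
    D2 = np.where(np.isfinite(dist), dist, np.nanmean(dist)) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:n_components]
    w = np.clip(w[idx], 0, None)
    return V[:, idx] * np.sqrt(w)[None, :]


class StressMDS(BaseEstimator):
    """Kruskal-Shepard scaling of a precomputed distance matrix.

    Parameters
    ----------
    n_components : int
        Embedding dimension D (1, 2 or 3 in practice).
    n_restarts : int
        Number of Nelder-Mead restarts; restart 0 starts from classical
        scaling, the rest from uniform random configurations on a box scaled
        to the largest distance.
    random_state : int
        Seed for the restart initializations.
    fatol, xatol : float
        Simplex convergence tolerances.
    max_iter_factor : int
        Iteration cap ``max_iter_factor * N * D``.
    normalized : bool
        Use the normalized stress variant.

    Attributes
    ----------
    embedding_ : ndarray of shape (N, D)
        Best coordinates found, centered at the origin.
    stress_ : float
        Stress of ``embedding_``.
    delta_stress_ : float or None
        Propagated stress error (set when distance errors are supplied).
    converged_ : bool
        Whether the best restart reported convergence.
    best_restart_ : int
    """

    def __init__(
        self,
        n_components: int = 2,
        n_restarts: int = 20,
        random_state: int = 0,
        fatol: float = 1e-8,
        xatol: float = 1e-8,
        max_iter_factor: int = 400,
        normalized: bool = False,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.fatol = fatol
        self.xatol = xatol
        self.max_iter_factor = max_iter_factor
        self.normalized = normalized

    def fit(self, X: np.ndarray, y=None, delta_d: Optional[np.ndarray] = None) -> "StressMDS":
        """Embed the precomputed distance matrix ``X``."""
        D = np.asarray(X, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("X must be a square distance matrix")
        n = D.shape[0]
        if n < 2:
            raise ValueError("need at least 2 items to embed")
        dim = int(self.n_components)
        rng = np.random.default_rng(self.random_state)
        scale = float(np.nanmax(D)) or 1.0
        maxiter = self.max_iter_factor * n * dim

        # precompute the residual bookkeeping once; equivalent to stress()
        iu = np.triu_indices(n, k=1)
        target = D[iu]
        ok = np.isfinite(target)
        target_ok = target[ok]
        denom = float(np.sum(target_ok**2)) if self.normalized else 1.0
        ia, ib = iu[0][ok], iu[1][ok]

        def objective(flat: np.ndarray) -> float:
            coords = flat.reshape(n, dim)
            diff = coords[ia] - coords[ib]
            fitted = np.sqrt(np.einsum("ij,ij->i", diff, diff))
            ss = float(np.sum((target_ok - fitted) ** 2))
            return np.sqrt(ss / denom) if denom != 1.0 else np.sqrt(ss)

        best = None
        for restart in range(max(1, int(self.n_restarts))):
            if restart == 0:
                x0 = _classical_scaling(D, dim)
            else:
                x0 = rng.uniform(-scale / 2, scale / 2, size=(n, dim))
            res = minimize(
                objective,
                x0.ravel(),
                method="Nelder-Mead",
                options={
                    "fatol": self.fatol,
                    "xatol": self.xatol,
                    "maxiter": maxiter,
                    "maxfev": maxiter,
                },
            )
            if best is None or res.fun < best[0]:
                best = (res.fun, res.x, bool(res.success), restart)
            if best[0] < 1e-12:  # cannot improve meaningfully
                break
        assert best is not None
        coords = best[1].reshape(n, dim)
        coords = coords - coords.mean(axis=0)  # fix the translation gauge
        self.embedding_ = coords
        self.stress_ = float(best[0])
        self.converged_ = best[2]
        self.best_restart_ = best[3]
        self.n_features_in_ = n
        self.delta_stress_ = (
            stress_error(coords, D, delta_d, self.stress_) if delta_d is not None else None
        )
        if not self.converged_:
            logger.warning("StressMDS: best restart did not report convergence")
        return self

    def fit_transform(self, X: np.ndarray, y=None, **kwargs) -> np.ndarray:
        return self.fit(X, y, **kwargs).embedding_


@dataclass
class Embedding:
    """A fitted D-dimensional configuration with its stress and error."""

    dimension: int
    coordinates: np.ndarray
    stress: float
    delta_stress: Optional[float] = None
    converged: bool = True
    best_restart: int = 0
    species: Optional[list[str]] = None

    def pairwise_distances(self) -> np.ndarray:
        return squareform(pdist(self.coordinates))


def fit_embedding(
    dist: Union[np.ndarray, DistanceMatrix],
    n_components: int = 2,
    n_restarts: int = 20,
    random_state: int = 0,
    config: InferenceConfig = DEFAULT_CONFIG,
    delta_d: Optional[np.ndarray] = None,
) -> Embedding:
    """Thin functional wrapper over :class:`StressMDS`."""
    species = None
    if isinstance(dist, DistanceMatrix):
        species = dist.species
        if delta_d is None:
            delta_d = dist.delta_d
        dist = dist.d
    mds = StressMDS(
        n_components=n_components,
        n_restarts=n_restarts,
        random_state=random_state,
        fatol=config.mds_fatol,
        xatol=config.mds_xatol,
        max_iter_factor=config.mds_max_iter_factor,
        normalized=config.normalized_stress,
    ).fit(dist, delta_d=delta_d)
    return Embedding(
        dimension=n_components,
        coordinates=mds.embedding_,
        stress=mds.stress_,
        delta_stress=mds.delta_stress_,
        converged=mds.converged_,
        best_restart=mds.best_restart_,
        species=species,
    )


def select_dimension(
    dist: Union[np.ndarray, DistanceMatrix],
    delta_d: Optional[np.ndarray] = None,
    config: InferenceConfig = DEFAULT_CONFIG,
    random_state: int = 0,
    n_restarts: Optional[int] = None,
) -> tuple[Union[int, Literal["skip-MDS"]], dict[int, Embedding]]:
    """Choose the embedding dimension, or skip scaling altogether.

    Fits D = 2 and D = 3; a dimension is admissible when every embedded
    distance lies inside ``[d - delta_d, d + delta_d]``.  D = 3 wins over an
    admissible D = 2 only when ``S_3 + dS_3 <= S_2 + dS_2``; with no
    admissible dimension the caller should threshold the raw distances
    ("skip-MDS").
    """
    if isinstance(dist, DistanceMatrix):
        if delta_d is None:
            delta_d = dist.delta_d
        dmat = dist.d
    else:
        dmat = np.asarray(dist, dtype=float)
    if delta_d is None:
        raise ValueError("select_dimension needs distance errors (run error_budget first)")
    if n_restarts is None:
        n_restarts = config.mds_restarts
    fits: dict[int, Embedding] = {}
    admissible: dict[int, bool] = {}
    iu = np.triu_indices_from(dmat, k=1)
    for dim in (2, 3):
        emb = fit_embedding(
            dmat,
            n_components=dim,
            n_restarts=n_restarts,
            random_state=random_state + dim,
            config=config,
            delta_d=delta_d,
        )
        fits[dim] = emb
        fitted = emb.pairwise_distances()
        resid = np.abs(dmat[iu] - fitted[iu])
        band = delta_d[iu]
        ok = np.isfinite(resid)
        admissible[dim] = bool(np.all(resid[ok] <= band[ok] + config.eps_num))
    if not any(admissible.values()):
        return "skip-MDS", fits
    if admissible[2] and admissible[3]:
        s2 = fits[2].stress + (fits[2].delta_stress or 0.0)
        s3 = fits[3].stress + (fits[3].delta_stress or 0.0)
        return (3 if s3 <= s2 else 2), fits
    return (2 if admissible[2] else 3), fits


def edge_threshold(
    distances: np.ndarray, config: InferenceConfig = DEFAULT_CONFIG
) -> tuple[float, dict]:
    """Histogram-mode threshold on the off-diagonal distances.

    Bins all distances with ``max(histogram_min_bins, ceil(sqrt(P)))`` bins
    and returns the mean of the centers of every bin attaining the maximal
    count, plus the histogram metadata.
    """
    distances = np.asarray(distances, dtype=float).ravel()
    distances = distances[np.isfinite(distances)]
    if distances.size < 3:
        raise ValueError("edge_threshold needs at least 3 off-diagonal distances")
    if np.ptp(distances) == 0:
        logger.warning("edge_threshold: all distances identical")
        value = float(distances[0])
        return value, {"bin_edges": np.array([value, value]), "counts": np.array([distances.size])}
    bins = max(config.histogram_min_bins, int(np.ceil(np.sqrt(distances.size))))
    counts, edges = np.histogram(distances, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    modal = centers[counts == counts.max()]
    return float(modal.mean()), {"bin_edges": edges, "counts": counts}


@dataclass
class UndirectedNetwork:
    """Thresholded interaction graph (no self-edges)."""

    graph: nx.Graph
    threshold: float
    histogram: dict = field(default_factory=dict)
    distance_source: str = "raw"  # "raw" or "embedded"

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def edge_list_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(u, v, d["distance"]) for u, v, d in self.graph.edges(data=True)],
            columns=["i", "j", "distance"],
        )


def build_undirected(
    dist: Union[np.ndarray, DistanceMatrix, Embedding],
    threshold: float,
    species: Optional[list[str]] = None,
    histogram: Optional[dict] = None,
) -> UndirectedNetwork:
    """Connect every pair whose distance does not exceed the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    source = "raw"
    if isinstance(dist, Embedding):
        species = species or dist.species
        dmat = dist.pairwise_distances()
        source = "embedded"
    elif isinstance(dist, DistanceMatrix):
        species = species or dist.species
        dmat = dist.d
    else:
        dmat = np.asarray(dist, dtype=float)
    n = dmat.shape[0]
    if species is None:
        species = [f"S{k}" for k in range(n)]
    g = nx.Graph()
    g.add_nodes_from(species)
    for a in range(n):
        for b in range(a + 1, n):
            if np.isfinite(dmat[a, b]) and dmat[a, b] <= threshold:
                g.add_edge(species[a], species[b], distance=float(dmat[a, b]))
    return UndirectedNetwork(
        graph=g, threshold=float(threshold), histogram=histogram or {}, distance_source=source
    )
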