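"""Temporal ordering of undirected edges from the lag of maximum correlation.

For an edge (i, j), ``r_ij(tau)`` correlates ``X_i(t)`` with
``X_j(t + tau)``; a peak at a positive lag therefore means that variation in
i precedes variation in j.  Only positive lags are scanned.  When both
orderings peak at zero lag, the ordering whose |r| decays more slowly over
the positive lags marks the leader; indistinguishable tails mark the edge
reversible with no leader.  Precedence is an annotation only: both opposed
first-order conversions are always emitted per edge, and elimination of the
spurious direction is delegated to the calibration stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import DEFAULT_CONFIG, InferenceConfig
from .data_io import Reaction, ReactionNetwork
from .embedding import UndirectedNetwork
from .lagcorr import LaggedCorrelation

logger = logging.getLogger(__name__)

__all__ = ["EdgeAnnotation", "DirectedHypotheses", "orient"]


@dataclass(frozen=True)
class EdgeAnnotation:
    """Precedence metadata for one undirected edge."""

    i: str
    j: str
    leader: Optional[str]  # species whose variation precedes, None if reversible
    tau_star: float  # lag (hours) of the leading ordering's |r| maximum
    reversible: bool
    weak: bool  # all |r| below the weak-correlation tolerance
    r_peak: float  # signed correlation at the peak of the leading ordering


@dataclass
class DirectedHypotheses:
    """Reaction hypotheses (both directions per edge) with edge annotations."""

    reactions: list[Reaction]
    annotations: list[EdgeAnnotation]

    def to_network(self, species_universe: Optional[list[str]] = None) -> ReactionNetwork:
        return ReactionNetwork(reactions=list(self.reactions), species_universe=species_universe)

    def __len__(self) -> int:
        return len(self.reactions)


def _tail_mean(absr: np.ndarray, lags: np.ndarray) -> float:
    """Mean |r| over the upper half of the positive-lag grid."""
    if lags.size < 2:
        return 0.0
    half = lags[-1] / 2.0
    mask = lags > half
    if not np.any(mask):
        mask = np.zeros_like(lags, dtype=bool)
        mask[-1] = True
    vals = absr[mask]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else 0.0


def orient(
    corr: LaggedCorrelation,
    net: UndirectedNetwork,
    config: InferenceConfig = DEFAULT_CONFIG,
) -> DirectedHypotheses:
    """Annotate each undirected edge with a temporal ordering.

    Rules, in order:

    1. exactly one ordering attains its |r| maximum at a positive lag ->
       that species leads at that lag;
    2. otherwise compare tail decays (mean |r| over the upper half of the
       lag grid): the slower-decaying ordering leads, unless the difference
       is below ``orientation_tail_tol``, in which case the edge is
       reversible with no leader.

    Edges whose profile never exceeds ``weak_correlation`` are annotated
    weak but still emitted.
    """
    species = corr.species
    lags = corr.grid.lags
    index = {s: k for k, s in enumerate(species)}
    annotations: list[EdgeAnnotation] = []
    reactions: list[Reaction] = []
    counter = 0
    for si, sj in sorted(net.edges):
        a, b = index[si], index[sj]
        r_ij = corr.correlation[a, b, :]  # i leading j
        r_ji = corr.correlation[b, a, :]  # j leading i
        abs_ij = np.abs(np.where(np.isfinite(r_ij), r_ij, -np.inf))
        abs_ji = np.abs(np.where(np.isfinite(r_ji), r_ji, -np.inf))
        peak_ij, peak_ji = int(np.argmax(abs_ij)), int(np.argmax(abs_ji))
        weak = bool(
            max(abs_ij.max(initial=0.0), abs_ji.max(initial=0.0)) < config.weak_correlation
        )
        leader: Optional[str]
        if (peak_ij > 0) != (peak_ji > 0):
            if peak_ij > 0:
                leader, tau_star, r_peak = si, float(lags[peak_ij]), float(r_ij[peak_ij])
            else:
                leader, tau_star, r_peak = sj, float(lags[peak_ji]), float(r_ji[peak_ji])
            reversible = False
        else:
            tail_ij = _tail_mean(np.abs(r_ij), lags)
            tail_ji = _tail_mean(np.abs(r_ji), lags)
            if abs(tail_ij - tail_ji) < config.orientation_tail_tol:
                leader, reversible = None, True
                tau_star = float(lags[peak_ij])
                r_peak = float(r_ij[peak_ij])
            elif tail_ij > tail_ji:
                leader, reversible = si, False
                tau_star, r_peak = float(lags[peak_ij]), float(r_ij[peak_ij])
            else:
                leader, reversible = sj, False
                tau_star, r_peak = float(lags[peak_ji]), float(r_ji[peak_ji])
        annotations.append(
            EdgeAnnotation(
                i=si, j=sj, leader=leader, tau_star=tau_star,
                reversible=reversible, weak=weak, r_peak=r_peak,
            )
        )
        if weak:
            logger.warning("flat correlation profile on edge (%s, %s)", si, sj)
        # both opposed conversions are always emitted; pruning happens later
        ordered = [(si, sj), (sj, si)]
        if leader == sj:
            ordered.reverse()
        for reactant, product in ordered:
            counter += 1
            reactions.append(
                Reaction(id=f"R{counter}", reactants=(reactant,), products=(product,))
            )
    return DirectedHypotheses(reactions=reactions, annotations=annotations)
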