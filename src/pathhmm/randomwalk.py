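"""Random-walk machinery: stationary distributions and global correspondence scores.

A random walker on an undirected weighted network jumps from a node to one of
its neighbors with probability proportional to the edge reliability. Its
stationary distribution is the closed form strength/total-strength. Two such
walkers, one per network, with a holding time at the joint state ``(u, v)``
proportional to the individual node similarity ``h(u, v)``, form a semi-Markov
walk whose long-run occupancy

    s(u, v) = pi1(u) * pi2(v) * h(u, v) / Z,   Z = sum over all pairs,

is the *global correspondence score*: it integrates sequence similarity with
topological context (hub nodes accumulate occupancy) and needs no tuning
parameter — scaling ``h`` by any positive constant leaves ``s`` unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict

import numpy as np

from .network_io import Network, NetworkValidationError, SimilarityTable


@dataclass
class StationaryDistribution:
    """Long-run visit probabilities of a weighted random walk; isolated nodes get 0."""

    probs: Dict[str, float]

    def __getitem__(self, node: str) -> float:
        return self.probs.get(node, 0.0)


def _require_edges(net: Network) -> None:
    if net.n_edges == 0:
        raise NetworkValidationError(f"network {net.name!r} has no edges")


def transition_matrix(net: Network) -> np.ndarray:
    """Row-stochastic jump matrix over ``net.node_list``.

    Entry ``(i, j)`` is ``w(i, j) / strength(i)`` for neighbors ``j`` of ``i``;
    rows of isolated nodes are all-zero.
    """
    _require_edges(net)
    nodes = net.node_list
    index = {n: i for i, n in enumerate(nodes)}
    P = np.zeros((len(nodes), len(nodes)))
    for u, v, w in net.edge_list():
        P[index[u], index[v]] = w
        P[index[v], index[u]] = w
    sums = P.sum(axis=1, keepdims=True)
    np.divide(P, sums, out=P, where=sums > 0)
    return P


def stationary_distribution(net: Network) -> StationaryDistribution:
    """Stationary vector of the reliability-weighted walk.

    For an undirected weighted graph this is node strength over total strength
    (detailed balance), which satisfies pi' P = pi' on every component.
    """
    _require_edges(net)
    strengths = {n: net.strength(n) for n in net.node_list}
    total = math.fsum(strengths.values())
    return StationaryDistribution({n: s / total for n, s in strengths.items()})


def global_correspondence(
    net1: Network, net2: Network, h: SimilarityTable
) -> SimilarityTable:
    """Semi-Markov random-walk occupancy scores ``s = pi1 * pi2 * h / Z``.

    The sparsity pattern of the result is a subset of ``h``'s (pairs involving
    isolated nodes, which the walk never visits, drop out). Raises if no
    similarity mass lies on the walk's support (``Z = 0``).
    """
    pi1 = stationary_distribution(net1)
    pi2 = stationary_distribution(net2)
    raw = {
        (u, v): pi1[u] * pi2[v] * score
        for (u, v), score in h.items()
        if pi1[u] > 0 and pi2[v] > 0 and score > 0
    }
    Z = math.fsum(raw.values())
    if Z <= 0:
        raise NetworkValidationError("no similarity mass on walk support (Z = 0)")
    return SimilarityTable({pair: val / Z for pair, val in raw.items()})


def rescale_to_reference(s: SimilarityTable, reference: SimilarityTable) -> SimilarityTable:
    """Affinely map the scores in ``s`` onto the value range of ``reference``.

    Correspondence scores are long-run occupancies whose spread covers several
    orders of magnitude, while raw similarity scores live in a narrow band
    (e.g. BLAST bit scores above a reporting threshold). Before either kind is
    used as an emission score the two are normalized so that they lie in the
    same range; otherwise the score type with the wider spread distorts the
    balance between node similarity and path structure in the aligner. The
    mapping is rank-preserving; absent (zero) entries stay absent.
    """
    if len(s) == 0 or len(reference) == 0:
        raise NetworkValidationError("cannot rescale an empty score table")
    lo_r, hi_r = min(reference.scores.values()), reference.max_score()
    lo_s, hi_s = min(s.scores.values()), s.max_score()
    if hi_s == lo_s:
        return SimilarityTable({pair: hi_r for pair in s.scores})
    span = (hi_r - lo_r) / (hi_s - lo_s)
    return SimilarityTable(
        {pair: lo_r + (val - lo_s) * span for pair, val in s.items()}
    )


def correspondence_emission_scores(
    net1: Network, net2: Network, h: SimilarityTable
) -> SimilarityTable:
    """Global correspondence scores normalized to the range of ``h``.

    This is the score table actually fed to the aligner in global mode:
    the semi-Markov occupancy of :func:`global_correspondence`, mapped onto
    the same range as the individual similarity scores it replaces.
    """
    return rescale_to_reference(global_correspondence(net1, net2, h), h)
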