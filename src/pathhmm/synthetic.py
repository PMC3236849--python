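"""Synthetic scale-free benchmark pairs with planted ortholog groups.

The generator emulates a pair of protein-interaction networks from two related
species: a random seed network is grown by preferential attachment into a
scale-free network, duplicated, and each copy is independently perturbed
(edge deletion, node deletion, regrowth). Corresponding original nodes form
planted ortholog groups; similarity scores are Gaussian — one distribution for
ortholog pairs, an overlapping one (mean ``mu``, the difficulty knob) for a
sparse set of non-ortholog pairs — thresholded to sparse support the way BLAST
bit-score tables are in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .network_io import AnnotationMap, Network, SimilarityTable


@dataclass
class BenchmarkParams:
    """Generator settings; defaults are the benchmark's reference conditions.

    The seed network has ``seed_size`` nodes and average degree
    ``seed_avg_degree``; preferential attachment with ``m`` links per new node
    grows it to ``target_size``. Ortholog similarities are
    ``N(mu_o, sigma_o)``, non-ortholog ones ``N(mu, sigma)`` with at most
    ``max_nonortho`` partners per node; scores below ``sim_threshold`` are
    dropped. Each copy then loses ``edge_del_frac`` of its edges and
    ``node_del_frac`` of its nodes and is regrown to size.
    """

    seed_size: int = 20
    seed_avg_degree: float = 10.0
    target_size: int = 1000
    m: int = 10
    mu_o: float = 300.0
    sigma_o: float = 100.0
    mu: float = 200.0
    sigma: float = 100.0
    sim_threshold: float = 50.0
    max_nonortho: int = 10
    edge_del_frac: float = 0.10
    node_del_frac: float = 0.10
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.edge_del_frac < 1 and 0 <= self.node_del_frac < 1):
            raise ValueError("deletion fractions must lie in [0, 1)")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.target_size <= self.seed_size:
            raise ValueError("target_size must exceed seed_size")


@dataclass
class BenchmarkPair:
    """Two perturbed copies with planted truth and similarity table.

    ``truth`` maps node id -> group id for original (pre-perturbation) nodes
    still present in either network; nodes inserted during regrowth carry no
    truth entry. ``n_truth_both`` counts truth pairs surviving in both
    networks.
    """

    net1: Network
    net2: Network
    sim: SimilarityTable
    truth: AnnotationMap
    params: BenchmarkParams
    n_truth_both: int = 0


def generate_seed_network(n: int, avg_degree: float, rng: np.random.Generator) -> Network:
    """Erdős–Rényi G(n, M) seed with M = round(n * avg_degree / 2) edges, unit weights."""
    M = round(n * avg_degree / 2)
    max_edges = n * (n - 1) // 2
    if M > max_edges:
        raise ValueError(f"{M} edges infeasible on {n} nodes (max {max_edges})")
    names = [f"n{i:04d}" for i in range(n)]
    pairs = [(names[i], names[j]) for i in range(n) for j in range(i + 1, n)]
    chosen = rng.choice(len(pairs), size=M, replace=False)
    net = Network("seed", nodes=names)
    for idx in sorted(chosen):
        net.add_edge(*pairs[idx], 1.0)
    return net


def _degree_weighted_sample(
    rng: np.random.Generator, nodes: Sequence[str], degrees: np.ndarray, m: int
) -> List[str]:
    """m distinct nodes, degree-proportional without replacement.

    Zero-degree nodes can only be drawn (uniformly) once every positive-degree
    node has been taken.
    """
    total = degrees.sum()
    n_pos = int((degrees > 0).sum())
    if total > 0 and n_pos >= m:
        idx = rng.choice(len(nodes), size=m, replace=False, p=degrees / total)
        return [nodes[i] for i in idx]
    chosen = [i for i in np.flatnonzero(degrees > 0)]
    rest = [i for i in np.flatnonzero(degrees == 0)]
    extra = rng.choice(len(rest), size=m - len(chosen), replace=False)
    chosen += [rest[i] for i in extra]
    return [nodes[i] for i in chosen]


def grow_preferential_attachment(
    net: Network,
    target_n: int,
    m: int,
    rng: np.random.Generator,
    name_prefix: str = "n",
) -> Network:
    """Grow ``net`` to ``target_n`` nodes by Barabási–Albert preferential attachment.

    Each new node attaches with unit-weight edges to ``m`` distinct existing
    nodes drawn with probability proportional to current degree, yielding a
    scale-free (power-law) degree distribution.
    """
    if target_n < net.n_nodes:
        raise ValueError("target_n smaller than current network size")
    if net.n_nodes < m:
        raise ValueError("network must have at least m nodes")
    net = net.copy()
    existing = set(net.graph.nodes)
    serial = 0
    while net.n_nodes < target_n:
        while f"{name_prefix}{serial:04d}" in existing:
            serial += 1
        new = f"{name_prefix}{serial:04d}"
        nodes = net.node_list
        degrees = np.array([net.graph.degree(x) for x in nodes], dtype=float)
        for partner in _degree_weighted_sample(rng, nodes, degrees, m):
            net.add_edge(new, partner, 1.0)
        existing.add(new)
    return net


def _draw_score(rng: np.random.Generator, mu: float, sigma: float, threshold: float) -> float:
    score = max(rng.normal(mu, sigma), 0.0)  # negative draws clipped to 0
    return score if score >= threshold else 0.0


def _assign_nonortho(
    rng: np.random.Generator,
    sources: Sequence[str],
    targets: Sequence[str],
    counts: Dict[str, int],
    sim: SimilarityTable,
    params: BenchmarkParams,
    source_is_net1: bool,
) -> None:
    """Sample up to ``max_nonortho`` cross-network non-ortholog partners per source.

    Partners are uniform over target nodes still under their own fan-out cap,
    so the cap holds on both sides of the table.
    """
    cap = params.max_nonortho
    targets = sorted(targets)
    for u in sorted(sources):
        room = cap - counts.get(u, 0)
        if room <= 0:
            continue
        cands = [
            v
            for v in targets
            if counts.get(v, 0) < cap
            and v != u  # ortholog partner shares the original node id
            and (u, v) not in sim.scores
            and (v, u) not in sim.scores
        ]
        if not cands:
            continue
        take = min(room, len(cands))
        idx = rng.choice(len(cands), size=take, replace=False)
        for i in sorted(idx):
            v = cands[i]
            score = _draw_score(rng, params.mu, params.sigma, params.sim_threshold)
            pair = (u, v) if source_is_net1 else (v, u)
            if score > 0:
                sim.set(*pair, score)
            # the slot is consumed whether or not the draw survives the threshold
            counts[u] = counts.get(u, 0) + 1
            counts[v] = counts.get(v, 0) + 1


def _perturb(
    net: Network,
    rng: np.random.Generator,
    params: BenchmarkParams,
    insert_prefix: str,
) -> Network:
    """Delete edges, then nodes (with incident edges), then regrow to size."""
    net = net.copy()
    edges = net.edge_list()
    n_del = math.floor(params.edge_del_frac * len(edges))
    if n_del:
        idx = rng.choice(len(edges), size=n_del, replace=False)
        net.remove_edges([(edges[i][0], edges[i][1]) for i in idx])
    nodes = net.node_list
    n_del = math.floor(params.node_del_frac * len(nodes))
    if n_del:
        idx = rng.choice(len(nodes), size=n_del, replace=False)
        for i in idx:
            net.graph.remove_node(nodes[i])
    return grow_preferential_attachment(
        net, params.target_size, params.m, rng, name_prefix=insert_prefix
    )


def make_benchmark_pair(params: Optional[BenchmarkParams] = None, **overrides) -> BenchmarkPair:
    """Full benchmark pipeline: grow, duplicate, plant truth + similarities, perturb."""
    if params is None:
        params = BenchmarkParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    rng = np.random.default_rng(params.rng_seed)

    seed = generate_seed_network(params.seed_size, params.seed_avg_degree, rng)
    base = grow_preferential_attachment(seed, params.target_size, params.m, rng)

    net1, net2 = base.copy(), base.copy()
    net1.name, net2.name = "net1", "net2"
    originals = base.node_list
    truth: AnnotationMap = {n: f"g{i:04d}" for i, n in enumerate(originals)}

    sim = SimilarityTable()
    for n in originals:  # ortholog pair (n in net1, n in net2)
        score = _draw_score(rng, params.mu_o, params.sigma_o, params.sim_threshold)
        if score > 0:
            sim.set(n, n, score)
    counts: Dict[str, int] = {}
    _assign_nonortho(rng, originals, originals, counts, sim, params, source_is_net1=True)

    net1 = _perturb(net1, rng, params, insert_prefix="x1_")
    net2 = _perturb(net2, rng, params, insert_prefix="x2_")

    nodes1, nodes2 = set(net1.graph.nodes), set(net2.graph.nodes)
    for (u, v) in list(sim.scores):
        if u not in nodes1 or v not in nodes2:
            del sim.scores[(u, v)]
    truth = {n: g for n, g in truth.items() if n in nodes1 or n in nodes2}

    inserted1 = sorted(n for n in nodes1 if n not in truth)
    inserted2 = sorted(n for n in nodes2 if n not in truth)
    _assign_nonortho(rng, inserted1, sorted(nodes2), counts, sim, params, source_is_net1=True)
    _assign_nonortho(rng, inserted2, sorted(nodes1), counts, sim, params, source_is_net1=False)

    n_both = sum(1 for n in truth if n in nodes1 and n in nodes2)
    return BenchmarkPair(
        net1=net1, net2=net2, sim=sim, truth=truth, params=params, n_truth_both=n_both
    )


def make_illustrative_pair():
    """A small planted-core fixture showing why topology matters.

    Two networks each contain a five-node core path whose nodes are hubs with
    matching periphery, plus two "decoy" pairs: peripheral, low-degree nodes in
    topologically dissimilar positions that are given an exceptionally high
    individual similarity (like sequence-similar proteins with no functional
    relationship). With raw similarities the top length-5 alignment is pulled
    through a decoy; global correspondence scores suppress the decoys (their
    stationary probabilities are small) and recover the core path pair.

    Returns ``(net1, net2, h, core_pairs, decoy_pairs)``.
    """
    net1 = Network("toy1")
    # core path a1..a5 (unit-reliability interactions); periphery leaves carry
    # lower reliabilities chosen so every core hub has the same strength, i.e.
    # the walk visits all core nodes equally often
    core1 = [f"a{i}" for i in range(1, 6)]
    for x, y in zip(core1, core1[1:]):
        net1.add_edge(x, y)
    periphery1 = {
        "a1": [("p1", 0.8), ("p2", 0.8)],
        "a2": [("p3", 0.3), ("p4", 0.3)],
        "a3": [("p5", 0.3), ("p6", 0.3)],
        "a4": [("p5", 0.3), ("p7", 0.3)],  # p5 bridges two core levels
        "a5": [("p8", 0.8), ("p9", 0.8)],
    }
    for hub, leaves in periphery1.items():
        for leaf, w in leaves:
            net1.add_edge(hub, leaf, w)
    net1.add_edge("p5", "p6", 0.3)  # the bridge node also touches the periphery

    net2 = Network("toy2")
    core2 = [f"b{i}" for i in range(1, 6)]
    for x, y in zip(core2, core2[1:]):
        net2.add_edge(x, y)
    periphery2 = {
        "b1": [("q1", 0.8), ("q2", 0.8)],
        "b2": [("q3", 0.3), ("q4", 0.3)],
        "b3": [("q5", 0.3), ("q6", 0.3)],
        "b4": [("q7", 0.3), ("q10", 0.3)],
        "b5": [("q7", 0.3), ("q8", 0.65), ("q9", 0.65)],  # q7 bridges levels 4-5
    }
    for hub, leaves in periphery2.items():
        for leaf, w in leaves:
            net2.add_edge(hub, leaf, w)
    net2.add_edge("q7", "q10", 0.3)

    h = SimilarityTable()
    for x, y in zip(core1, core2):  # true ortholog core pairs
        h.set(x, y, 150.0)
    # vertical-level similarity: hubs one level apart are still fairly similar
    for i, x in enumerate(core1):
        for j, y in enumerate(core2):
            if abs(i - j) == 1:
                h.set(x, y, 140.0)
    # same-level periphery gets modest similarity
    for hub1, hub2 in zip(core1, core2):
        for leaf1, _ in periphery1[hub1]:
            for leaf2, _ in periphery2[hub2]:
                if h.get(leaf1, leaf2) == 0:
                    h.set(leaf1, leaf2, 100.0)
    # decoys: exceptionally similar, topologically dissimilar peripheral nodes
    decoys = [("p5", "q7"), ("p3", "q8")]
    for u, v in decoys:
        h.set(u, v, 1200.0)
    core_pairs = list(zip(core1, core2))
    return net1, net2, h, core_pairs, decoys
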