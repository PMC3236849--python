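"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's DP machinery: walks are enumerated
recursively and scored by direct summation, so they provide an independent
check of the aligner.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from pathhmm import Network, SimilarityTable
from pathhmm.align import build_transition_scores, emission_scores

NEG_INF = float("-inf")


def enumerate_walks(net: Network, L: int) -> List[Tuple[str, ...]]:
    """All directed walks of L nodes following edges (nodes may repeat)."""
    adj = {n: net.neighbors(n) for n in net.node_list}
    out: List[Tuple[str, ...]] = []

    def rec(path):
        if len(path) == L:
            out.append(tuple(path))
            return
        for nxt in adj[path[-1]]:
            rec(path + [nxt])

    for n in net.node_list:
        rec([n])
    return out


def oracle_best_score(
    net1: Network,
    net2: Network,
    s: SimilarityTable,
    L: int,
    mode: str = "weighted",
) -> Optional[float]:
    """Exhaustive gap-free maximum over ordered walk pairs of length L.

    Walk pairs that align the same node pair at two different steps are
    excluded, matching the aligner's feasibility rule. Returns None when no
    walk pair has a finite score.
    """
    t1 = build_transition_scores(net1, mode)
    t2 = build_transition_scores(net2, mode)
    e = emission_scores(s)

    w1 = enumerate_walks(net1, L)
    w2 = enumerate_walks(net2, L)
    if not w1 or not w2:
        return None

    idx1 = {n: i for i, n in enumerate(net1.node_list)}
    idx2 = {n: i for i, n in enumerate(net2.node_list)}
    E = np.full((len(idx1), len(idx2)), NEG_INF)
    for (u, v), val in e.items():
        if u in idx1 and v in idx2:
            E[idx1[u], idx2[v]] = val

    W1 = np.array([[idx1[n] for n in w] for w in w1])
    W2 = np.array([[idx2[n] for n in w] for w in w2])
    t1sum = np.array([sum(t1.get(a, b) for a, b in zip(w, w[1:])) for w in w1])
    t2sum = np.array([sum(t2.get(a, b) for a, b in zip(w, w[1:])) for w in w2])

    esum = E[W1[:, None, :], W2[None, :, :]].sum(axis=2)
    total = esum + t1sum[:, None] + t2sum[None, :]
    for a in range(L):
        for b in range(a + 1, L):
            dup = (W1[:, a] == W1[:, b])[:, None] & (W2[:, a] == W2[:, b])[None, :]
            total[dup] = NEG_INF
    best = float(total.max())
    return None if best == NEG_INF else best


def random_instance(rng: np.random.Generator, max_nodes: int = 7):
    """A small random weighted network pair plus sparse similarity table."""
    from pathhmm import NetworkValidationError

    def rand_net(name: str) -> Network:
        n = int(rng.integers(4, max_nodes + 1))
        nodes = [f"{name}{i}" for i in range(n)]
        net = Network(name)
        pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        k = max(n - 1, int(0.45 * len(pairs)))
        for i in rng.choice(len(pairs), size=k, replace=False):
            net.add_edge(*pairs[i], float(rng.uniform(0.1, 1.0)))
        return net

    net1, net2 = rand_net("u"), rand_net("v")
    s = SimilarityTable()
    for u in net1.node_list:
        for v in net2.node_list:
            if rng.random() < 0.5:
                s.set(u, v, float(rng.uniform(1.0, 100.0)))
    if len(s) == 0:
        s.set(net1.node_list[0], net2.node_list[0], 5.0)
    return net1, net2, s
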