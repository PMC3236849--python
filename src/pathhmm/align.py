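"""HMM-based local alignment of two networks: find the most probable pair of paths.

Each network is turned into an HMM whose hidden states are its nodes and whose
transitions follow the edges, weighted by interaction reliability. A virtual
observation sequence of length ``L`` is jointly emitted by the two HMMs with
emission probability driven by the node similarity of the currently paired
states, so the best pair of state paths is the best pair of matching network
paths. Auxiliary gap states let one network's path advance while the other
holds, modeling node insertions/deletions in a conserved pathway.

The dynamic program keeps three score layers per step ``t`` and state pair
``(i, j)``::

    M[t](i,j)  = e(i,j) + max over predecessors (p,q) of
                   best[t-1](p,q) + t1(p,i) + t2(q,j)
    G1[t](i,j) = gap + max over p in N1(i) of max(M, G2)[t-1](p,j) + t1(p,i)
    G2[t](i,j) = gap + max over q in N2(j) of max(M, G1)[t-1](i,q) + t2(q,j)

with ``best = max(M, G1, G2)``, start transitions free at ``t = 1`` (uniform
initial state), emissions ``e(i,j) = log(s(i,j) / max s)`` and transitions
``t(p,i) = log(w(p,i) / strength(p))`` (or ``log(1/deg(p))`` in binary mode).
Gap layers feed on the opposite gap layer or the match layer only, so the same
network side never gaps twice in a row, and the first step is always a match.

Traceback is a best-first (A*) backward search over the trellis using the DP
scores as admissible look-ahead; branches that would align the same node pair
twice are pruned, so the first completed path is the exact optimum under the
no-repeated-pair rule. A depth-first feasible traceback provides a lower
bound and a fallback if the search budget runs out. The top-k procedure
repeats the alignment after removing the traversed interactions from both
networks.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .network_io import GAP, Network, NetworkValidationError, SimilarityTable

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")

# state layer indices
_M, _G1, _G2 = 0, 1, 2


@dataclass
class AlignParams:
    """Knobs of the path-pair aligner.

    L
        virtual alignment length: number of DP steps (emissions); gap steps
        consume length. Must be >= 2.
    k
        number of alignments extracted by iterative interaction removal.
    gap_penalty
        log-scale score of a gap step (<= 0); ``-inf`` disables gaps. The
        default ``log(0.001)`` makes entering a gap state far less likely
        than following any real interaction, so gaps act as a last resort
        for bridging an unmatched node rather than a cheap way to skip
        emissions.
    transition_mode
        ``"weighted"`` uses reliability-normalized transitions,
        ``"binary"`` uses 1/degree (presence/absence of an interaction).
    max_traceback_candidates
        effort budget of the traceback search for a path without repeated
        aligned pairs (the A* search may expand 20x this many nodes before
        falling back to the depth-first feasible path).
    """

    L: int
    k: int = 1
    gap_penalty: float = math.log(0.001)
    transition_mode: str = "weighted"
    max_traceback_candidates: int = 100

    def __post_init__(self):
        if self.L < 2:
            raise ValueError("virtual length L must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.gap_penalty > 0:
            raise ValueError("gap_penalty must be nonpositive (log scale)")
        if self.transition_mode not in ("weighted", "binary"):
            raise ValueError(f"unknown transition mode {self.transition_mode!r}")


@dataclass
class PathAlignment:
    """A pair of gapped node paths with its total log score.

    ``steps`` holds ``L`` pairs ``(node-of-net1 | None, node-of-net2 | None)``
    where ``None`` marks a gap on that side; no step is a double gap and no
    (non-gap, non-gap) pair occurs twice.
    """

    steps: List[Tuple[Optional[str], Optional[str]]]
    score: float

    @property
    def L(self) -> int:
        return len(self.steps)

    def matched_pairs(self) -> List[Tuple[str, str]]:
        return [(u, v) for u, v in self.steps if u is not None and v is not None]

    def path1(self) -> List[str]:
        return [u for u, _ in self.steps if u is not None]

    def path2(self) -> List[str]:
        return [v for _, v in self.steps if v is not None]


@dataclass
class TransitionScores:
    """Per-network log transition scores over ordered node pairs."""

    mode: str
    scores: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def get(self, i: str, j: str) -> float:
        return self.scores.get((i, j), NEG_INF)


def build_transition_scores(net: Network, mode: str = "weighted") -> TransitionScores:
    """Log transition scores: reliability-normalized or degree-normalized.

    ``weighted``: t(i, j) = log(w(i, j) / strength(i)); ``binary``:
    t(i, j) = log(1 / deg(i)). Absent pairs are -inf. On a uniform-weight
    network the two modes coincide.
    """
    if net.n_edges == 0:
        raise NetworkValidationError(f"network {net.name!r} has no edges")
    if mode not in ("weighted", "binary"):
        raise ValueError(f"unknown transition mode {mode!r}")
    ts = TransitionScores(mode=mode)
    for i in net.node_list:
        nbrs = net.neighbors(i)
        if not nbrs:
            continue
        if mode == "weighted":
            denom = net.strength(i)
            for j in nbrs:
                ts.scores[(i, j)] = math.log(net.weight(i, j) / denom)
        else:
            val = -math.log(len(nbrs))
            for j in nbrs:
                ts.scores[(i, j)] = val
    return ts


def emission_scores(s: SimilarityTable) -> Dict[Tuple[str, str], float]:
    """Log emission scores: similarities scaled by their maximum, then logged.

    Pairs with zero similarity are absent (match forbidden); the top pair
    scores ``log 1 = 0``.
    """
    m = s.max_score()  # raises on an empty/all-zero table
    return {pair: math.log(val / m) for pair, val in s.items()}


class _Instance:
    """Index arrays for one aligner run (nodes sorted, numpy-backed)."""

    def __init__(self, net1: Network, net2: Network, s: SimilarityTable, params: AlignParams):
        self.nodes1 = net1.node_list
        self.nodes2 = net2.node_list
        self.idx1 = {n: i for i, n in enumerate(self.nodes1)}
        self.idx2 = {n: i for i, n in enumerate(self.nodes2)}
        n1, n2 = len(self.nodes1), len(self.nodes2)

        t1 = build_transition_scores(net1, params.transition_mode)
        t2 = build_transition_scores(net2, params.transition_mode)
        # incoming neighbor arrays: in_nbrs[i] lists p with an edge (p, i),
        # in_sc[i][k] = t(p_k, i)
        self.in_nbrs1, self.in_sc1 = self._incoming(net1, t1, self.nodes1, self.idx1)
        self.in_nbrs2, self.in_sc2 = self._incoming(net2, t2, self.nodes2, self.idx2)
        # index-keyed transition lookups for exact path re-scoring
        self.t1_idx = {
            (self.idx1[p], self.idx1[q]): v for (p, q), v in t1.scores.items()
        }
        self.t2_idx = {
            (self.idx2[p], self.idx2[q]): v for (p, q), v in t2.scores.items()
        }

        self.E = np.full((n1, n2), NEG_INF)
        e = emission_scores(s)
        self.n_pairs = 0
        for (u, v), val in e.items():
            iu, iv = self.idx1.get(u), self.idx2.get(v)
            if iu is not None and iv is not None:
                self.E[iu, iv] = val
                self.n_pairs += 1

    @staticmethod
    def _incoming(net, ts, nodes, idx):
        in_nbrs, in_sc = [], []
        for i in nodes:
            nbrs = net.neighbors(i)
            in_nbrs.append(np.array([idx[p] for p in nbrs], dtype=np.intp))
            in_sc.append(np.array([ts.get(p, i) for p in nbrs]))
        return in_nbrs, in_sc


def _forward(inst: _Instance, params: AlignParams) -> np.ndarray:
    """Fill the DP trellis; returns S of shape (L+1, 3, n1, n2) (index t=1..L)."""
    n1, n2 = inst.E.shape
    L, gap = params.L, params.gap_penalty
    S = np.full((L + 1, 3, n1, n2), NEG_INF)
    S[1, _M] = inst.E
    use_gaps = gap > NEG_INF
    for t in range(2, L + 1):
        prev = S[t - 1]
        best_prev = prev.max(axis=0)
        # A[i, :] = max_p best_prev[p, :] + t1(p, i)
        A = np.full((n1, n2), NEG_INF)
        for i in range(n1):
            ps = inst.in_nbrs1[i]
            if ps.size:
                A[i] = (best_prev[ps] + inst.in_sc1[i][:, None]).max(axis=0)
        M_new = S[t, _M]
        for j in range(n2):
            qs = inst.in_nbrs2[j]
            if qs.size:
                M_new[:, j] = (A[:, qs] + inst.in_sc2[j][None, :]).max(axis=1)
        M_new += inst.E
        if use_gaps:
            MG2 = np.maximum(prev[_M], prev[_G2])
            MG1 = np.maximum(prev[_M], prev[_G1])
            G1_new = S[t, _G1]
            for i in range(n1):
                ps = inst.in_nbrs1[i]
                if ps.size:
                    G1_new[i] = (MG2[ps] + inst.in_sc1[i][:, None]).max(axis=0) + gap
            G2_new = S[t, _G2]
            for j in range(n2):
                qs = inst.in_nbrs2[j]
                if qs.size:
                    G2_new[:, j] = (MG1[:, qs] + inst.in_sc2[j][None, :]).max(axis=1) + gap
    return S


_EMPTY_CANDS = (
    np.empty(0), np.empty(0, np.int8), np.empty(0, np.intp), np.empty(0, np.intp)
)


def _pred_arrays(inst: _Instance, S: np.ndarray, gap: float, t: int, state: int, i: int, j: int):
    """Predecessor arcs into trellis cell (t, state, i, j), as flat arrays.

    Returns ``(bound, pred_state, p, q)`` arrays where
    ``bound = S[t-1][pred] + omega`` and ``omega`` is the cost added at step
    ``t``. Unreachable arcs carry ``-inf`` bounds and are filtered by callers.
    """
    prev = S[t - 1]
    if state == _M:
        ps, sc1 = inst.in_nbrs1[i], inst.in_sc1[i]
        qs, sc2 = inst.in_nbrs2[j], inst.in_sc2[j]
        if not ps.size or not qs.size:
            return _EMPTY_CANDS
        dp, dq = ps.size, qs.size
        omega = inst.E[i, j] + sc1[:, None] + sc2[None, :]
        vals = (prev[:, ps[:, None], qs[None, :]] + omega[None]).ravel()
        sts = np.repeat(np.array([_M, _G1, _G2], np.int8), dp * dq)
        P = np.tile(np.repeat(ps, dq), 3)
        Q = np.tile(np.tile(qs, dp), 3)
        return vals, sts, P, Q
    if state == _G1:
        ps, sc1 = inst.in_nbrs1[i], inst.in_sc1[i]
        if not ps.size:
            return _EMPTY_CANDS
        vals = np.concatenate([prev[_M, ps, j] + sc1 + gap, prev[_G2, ps, j] + sc1 + gap])
        sts = np.repeat(np.array([_M, _G2], np.int8), ps.size)
        P = np.tile(ps, 2)
        Q = np.full(2 * ps.size, j, np.intp)
        return vals, sts, P, Q
    qs, sc2 = inst.in_nbrs2[j], inst.in_sc2[j]
    if not qs.size:
        return _EMPTY_CANDS
    vals = np.concatenate([prev[_M, i, qs] + sc2 + gap, prev[_G1, i, qs] + sc2 + gap])
    sts = np.repeat(np.array([_M, _G1], np.int8), qs.size)
    P = np.full(2 * qs.size, i, np.intp)
    Q = np.tile(qs, 2)
    return vals, sts, P, Q


def _feasible_sorted_cands(inst, S, gap, t, state, i, j, pairs, cutoff):
    """Feasible predecessor arcs above ``cutoff``, sorted for deterministic pops.

    Sort order is descending bound with ties broken lexicographically by
    (node1, node2, state).
    """
    vals, sts, P, Q = _pred_arrays(inst, S, gap, t, state, i, j)
    if not vals.size:
        return _EMPTY_CANDS
    keep = vals > cutoff
    if pairs:
        m_layer = sts == _M
        for pp, qq in pairs:
            keep &= ~(m_layer & (P == pp) & (Q == qq))
    if not keep.any():
        return _EMPTY_CANDS
    vals, sts, P, Q = vals[keep], sts[keep], P[keep], Q[keep]
    order = np.lexsort((sts, Q, P, -vals))
    return vals[order], sts[order], P[order], Q[order]


def _cells_to_alignment(inst: _Instance, cells, score: float) -> PathAlignment:
    steps: List[Tuple[Optional[str], Optional[str]]] = []
    for st, ci, cj in cells:
        if st == _M:
            steps.append((inst.nodes1[ci], inst.nodes2[cj]))
        elif st == _G1:
            steps.append((inst.nodes1[ci], GAP))
        else:
            steps.append((GAP, inst.nodes2[cj]))
    return PathAlignment(steps=steps, score=score)


def _score_cells(inst: _Instance, cells, gap: float) -> float:
    """Exact score of a trellis cell path, re-summed from its arc costs."""
    st0, i0, j0 = cells[0]
    total = float(inst.E[i0, j0])
    prev = cells[0]
    for st, i, j in cells[1:]:
        _, pi, pj = prev
        if st == _M:
            total += float(inst.E[i, j]) + inst.t1_idx[(pi, i)] + inst.t2_idx[(pj, j)]
        elif st == _G1:
            total += gap + inst.t1_idx[(pi, i)]
        else:
            total += gap + inst.t2_idx[(pj, j)]
        prev = (st, i, j)
    return total


def _greedy_traceback(
    inst: _Instance, S: np.ndarray, params: AlignParams, start, backtracks: int = 200
) -> Optional[PathAlignment]:
    """Greedy feasible traceback from one final cell: a fast lower bound.

    Follows the best-bound predecessor that does not repeat an aligned pair,
    backtracking (within a small budget) when a branch dead-ends. The returned
    score is the true score of the chosen path, re-summed from its arc costs.
    """
    gap = params.gap_penalty
    state, i, j = start
    # frame: (cell, candidate arrays, next candidate index)
    cands0 = _feasible_sorted_cands(
        inst, S, gap, params.L, state, i, j, {(i, j)} if state == _M else set(), NEG_INF
    )
    stack = [((state, i, j), cands0, 0)]
    while stack:
        cell, (vals, sts, P, Q), idx = stack[-1]
        if idx >= vals.size:
            stack.pop()  # dead end: back out one step
            backtracks -= 1
            if backtracks < 0 or not stack:
                return None
            continue
        stack[-1] = (cell, (vals, sts, P, Q), idx + 1)
        nxt = (int(sts[idx]), int(P[idx]), int(Q[idx]))
        pairs = {(c[1], c[2]) for c, _, _ in stack if c[0] == _M}
        if nxt[0] == _M:
            pairs.add((nxt[1], nxt[2]))
        t_next = params.L - len(stack)  # step index of nxt
        if t_next == 1:
            cells = [nxt] + [frame[0] for frame in reversed(stack)]
            return _cells_to_alignment(inst, cells, _score_cells(inst, cells, gap))
        nxt_cands = _feasible_sorted_cands(
            inst, S, gap, t_next, nxt[0], nxt[1], nxt[2], pairs, NEG_INF
        )
        stack.append((nxt, nxt_cands, 0))


def _traceback(inst: _Instance, S: np.ndarray, params: AlignParams) -> Optional[PathAlignment]:
    """Best-first backward search for the best path without repeated aligned pairs.

    Each heap item is a feasible suffix of steps ``t..L`` anchored at a trellis
    cell, keyed by the unconstrained DP value at the anchor plus the exact
    suffix cost — an upper bound on any completion of that suffix, so this is
    an A* search whose first completed path is the exact optimum under the
    no-repeated-pair constraint. Branches that would align an already-used
    pair are pruned as they arise, as are branches that cannot beat a greedy
    feasible lower bound computed up front. The search effort is capped; on
    overrun the greedy path (feasible, possibly suboptimal) is returned with
    a warning.
    """
    L, gap = params.L, params.gap_penalty
    final = S[L]
    finite = np.argwhere(np.isfinite(final))
    if finite.size == 0:
        return None
    scores = final[finite[:, 0], finite[:, 1], finite[:, 2]]
    # descending score; ties broken lexicographically by (node1, node2, state)
    order = np.lexsort((finite[:, 0], finite[:, 2], finite[:, 1], -scores))
    finite, scores = finite[order], scores[order]

    fallback = None
    successes = 0
    for fidx in range(min(400, len(scores))):
        cand = _greedy_traceback(inst, S, params, tuple(int(x) for x in finite[fidx]))
        if cand is not None:
            successes += 1
            if fallback is None or cand.score > fallback.score:
                fallback = cand
            if successes >= 5:
                break
    bound = fallback.score if fallback is not None else NEG_INF

    counter = itertools.count()
    # Lazy sibling expansion: each pop pushes at most its best feasible
    # predecessor and the next sibling from its parent's candidate list, so the
    # heap stays small. An item is
    #   (-f, tiebreak, t, state, i, j, suffix, sib_cands, sib_idx)
    # where sib_cands is the parent's sorted candidate arrays (f, state, p, q)
    # and sib_idx the next unpushed position (siblings share the suffix).
    heap: List[tuple] = []

    def push(f, t, state, i, j, suffix, sib_cands, sib_idx):
        if f > bound or fallback is None:
            heapq.heappush(
                heap, (-f, next(counter), t, state, i, j, suffix, sib_cands, sib_idx)
            )

    # the sorted final cells act as the root's candidate list
    root_cands = (
        scores,
        finite[:, 0].astype(np.int8),
        finite[:, 1].astype(np.intp),
        finite[:, 2].astype(np.intp),
    )
    push(float(scores[0]), L, int(finite[0][0]), int(finite[0][1]), int(finite[0][2]),
         None, root_cands, 1)

    max_pops = params.max_traceback_candidates * 20
    pops = 0
    while heap:
        negf, _, t, state, i, j, suffix, sib_cands, sib_idx = heapq.heappop(heap)
        f = -negf
        pops += 1
        if pops > max_pops:
            logger.info(
                "traceback search exceeded its budget; returning greedy path"
                if fallback is not None
                else "traceback search exceeded its budget with no feasible path"
            )
            return fallback
        if sib_idx < sib_cands[0].size:  # release the next sibling
            push(
                float(sib_cands[0][sib_idx]), t, int(sib_cands[1][sib_idx]),
                int(sib_cands[2][sib_idx]), int(sib_cands[3][sib_idx]),
                suffix, sib_cands, sib_idx + 1,
            )
        if t == 1:
            cells = [(state, i, j)]
            node = suffix
            while node is not None:
                cells.append(node[0])
                node = node[1]
            return _cells_to_alignment(inst, cells, f)
        # matched pairs used by this suffix (current cell included)
        pairs = {(i, j)} if state == _M else set()
        node = suffix
        while node is not None:
            cst, ci, cj = node[0]
            if cst == _M:
                pairs.add((ci, cj))
            node = node[1]
        suffix_cost = f - S[t, state, i, j]
        cutoff = (bound - suffix_cost) if fallback is not None else NEG_INF
        vals, sts, P, Q = _feasible_sorted_cands(inst, S, gap, t, state, i, j, pairs, cutoff)
        if vals.size:
            new_suffix = ((state, i, j), suffix)
            cands = (vals + suffix_cost, sts, P, Q)
            push(float(cands[0][0]), t - 1, int(sts[0]), int(P[0]), int(Q[0]),
                 new_suffix, cands, 1)
    return fallback


def align_pair(
    net1: Network, net2: Network, s: SimilarityTable, params: AlignParams
) -> Optional[PathAlignment]:
    """Highest-scoring path alignment of virtual length exactly ``params.L``.

    Returns ``None`` when no feasible alignment exists (empty-result flag).
    """
    if net1.n_edges == 0 or net2.n_edges == 0:
        raise NetworkValidationError("both networks must have at least one edge")
    inst = _Instance(net1, net2, s, params)
    if inst.n_pairs == 0:
        return None
    S = _forward(inst, params)
    return _traceback(inst, S, params)


def _traversed_edges(path: List[str]) -> List[Tuple[str, str]]:
    return [(path[t], path[t + 1]) for t in range(len(path) - 1)]


def top_k_alignments(
    net1: Network, net2: Network, s: SimilarityTable, params: AlignParams
) -> List[PathAlignment]:
    """Top-k alignments by iterative interaction removal.

    Repeats: align, record, delete every interaction traversed by the
    alignment's path from its network, until ``k`` alignments are found or no
    feasible alignment remains. Scores are reported in discovery order (the
    instance changes between iterations, so they need not be monotone), and no
    interaction is traversed by two returned alignments.
    """
    work1, work2 = net1.copy(), net2.copy()
    out: List[PathAlignment] = []
    for it in range(params.k):
        if work1.n_edges == 0 or work2.n_edges == 0:
            logger.info("networks exhausted after %d alignments", len(out))
            break
        aln = align_pair(work1, work2, s, params)
        if aln is None:
            logger.info("no feasible alignment after %d alignments", len(out))
            break
        out.append(aln)
        logger.info("alignment %d: score %.4f", it + 1, aln.score)
        work1.remove_edges(_traversed_edges(aln.path1()))
        work2.remove_edges(_traversed_edges(aln.path2()))
    return out
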