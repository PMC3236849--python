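"""Readers and writers for the plain tab-separated interchange formats.

All on-disk formats are TSV with ``#`` comment lines:

* network file:      ``nodeA<TAB>nodeB<TAB>weight`` (weight optional, default 1.0)
* similarity file:   ``u<TAB>v<TAB>score``
* annotation file:   ``node<TAB>group``
* alignment file:    ``rank<TAB>step<TAB>node1<TAB>node2<TAB>score`` with ``-`` for gaps

Node identity is the literal string token (no case folding). Undirected edges
are canonicalized with lexicographically sorted endpoints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import networkx as nx

logger = logging.getLogger(__name__)

GAP = None  # gap marker inside PathAlignment steps
GAP_TOKEN = "-"  # gap marker on disk


class NetworkFormatError(ValueError):
    """A line of an input file could not be parsed."""


class NetworkValidationError(ValueError):
    """Parsed content violates a structural invariant (weights, self-loops, ...)."""


def _canonical(u: str, v: str) -> Tuple[str, str]:
    return (u, v) if u <= v else (v, u)


class Network:
    """An undirected, weighted interaction network with named nodes.

    Edge weights are interaction reliabilities in ``(0, 1]``. Self-loops and
    duplicate undirected edges are rejected.
    """

    def __init__(
        self,
        name: str = "",
        edges: Iterable[Tuple[str, str, float]] = (),
        nodes: Iterable[str] = (),
    ):
        self.name = name
        self.graph = nx.Graph()
        for n in nodes:
            self.graph.add_node(str(n))
        for u, v, w in edges:
            self.add_edge(u, v, w)

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        u, v = str(u), str(v)
        if u == v:
            raise NetworkValidationError(f"self-loop on node {u!r}")
        if not (0.0 < weight <= 1.0):
            raise NetworkValidationError(
                f"edge ({u!r}, {v!r}): weight {weight} outside (0, 1]"
            )
        if self.graph.has_edge(u, v):
            raise NetworkValidationError(f"duplicate edge ({u!r}, {v!r})")
        self.graph.add_edge(u, v, weight=float(weight))

    # -- views -------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def node_list(self) -> List[str]:
        """Nodes in sorted order (the canonical indexing used everywhere)."""
        return sorted(self.graph.nodes)

    def edge_list(self) -> List[Tuple[str, str, float]]:
        """Canonicalized, sorted edge triples."""
        out = [(*_canonical(u, v), d["weight"]) for u, v, d in self.graph.edges(data=True)]
        return sorted(out)

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def neighbors(self, u: str) -> List[str]:
        return sorted(self.graph.neighbors(u))

    def strength(self, u: str) -> float:
        """Sum of incident edge weights (node strength)."""
        return sum(d["weight"] for _, _, d in self.graph.edges(u, data=True))

    def copy(self) -> "Network":
        new = Network(self.name)
        new.graph = self.graph.copy()
        return new

    def remove_edges(self, pairs: Iterable[Tuple[str, str]]) -> None:
        for u, v in pairs:
            if self.graph.has_edge(u, v):
                self.graph.remove_edge(u, v)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return set(self.graph.nodes) == set(other.graph.nodes) and self.edge_list() == other.edge_list()

    def __repr__(self) -> str:
        return f"Network({self.name!r}, {self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass
class SimilarityTable:
    """Sparse nonnegative cross-network node similarity scores.

    Absent entries mean score 0; zero scores are never stored.
    """

    scores: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def set(self, u: str, v: str, score: float) -> None:
        if score < 0:
            raise NetworkValidationError(f"similarity ({u!r}, {v!r}): negative score {score}")
        if score == 0:
            self.scores.pop((u, v), None)
        else:
            self.scores[(u, v)] = float(score)

    def get(self, u: str, v: str) -> float:
        return self.scores.get((u, v), 0.0)

    def items(self) -> Iterator[Tuple[Tuple[str, str], float]]:
        return iter(sorted(self.scores.items()))

    def __len__(self) -> int:
        return len(self.scores)

    def max_score(self) -> float:
        if not self.scores:
            raise NetworkValidationError("similarity table is empty")
        return max(self.scores.values())

    def total(self) -> float:
        return math.fsum(self.scores.values())

    def transpose(self) -> "SimilarityTable":
        return SimilarityTable({(v, u): s for (u, v), s in self.scores.items()})

    def copy(self) -> "SimilarityTable":
        return SimilarityTable(dict(self.scores))


#: node id -> functional group id; nodes absent from the map are unannotated
AnnotationMap = Dict[str, str]


# ---------------------------------------------------------------------------
# file parsing helpers


def _data_lines(path: str) -> Iterator[Tuple[int, List[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_network(path: str, name: Optional[str] = None) -> Network:
    """Read a TSV edge list into a validated :class:`Network`.

    Each non-comment line is ``nodeA<TAB>nodeB[<TAB>weight]``; a missing weight
    defaults to 1.0. Duplicate undirected edges, self-loops and weights outside
    ``(0, 1]`` are errors.
    """
    net = Network(name if name is not None else str(path))
    for lineno, fields in _data_lines(path):
        if len(fields) == 1:  # isolated node declaration
            net.graph.add_node(fields[0])
            continue
        if len(fields) not in (2, 3):
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 2 or 3 tab-separated fields, got {len(fields)}"
            )
        u, v = fields[0], fields[1]
        if len(fields) == 3:
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise NetworkFormatError(f"{path}:{lineno}: bad weight {fields[2]!r}") from exc
        else:
            w = 1.0
        try:
            net.add_edge(u, v, w)
        except NetworkValidationError as exc:
            raise NetworkValidationError(f"{path}:{lineno}: {exc}") from exc
    return net


def write_network(net: Network, path: str) -> None:
    """Inverse of :func:`read_network`; isolated nodes appear as bare lines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# node1\tnode2\tweight\n")
        for u, v, w in net.edge_list():
            fh.write(f"{u}\t{v}\t{w!r}\n")
        for n in net.node_list:
            if net.graph.degree(n) == 0:
                fh.write(f"{n}\n")


def read_similarity(
    path: str, net1: Network, net2: Network, strict: bool = True
) -> SimilarityTable:
    """Read a TSV similarity table restricted to nodes of the two networks.

    Zero scores are dropped. Unknown node ids raise in strict mode; otherwise
    they are skipped with a logged count.
    """
    table = SimilarityTable()
    nodes1, nodes2 = set(net1.graph.nodes), set(net2.graph.nodes)
    skipped = 0
    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
            )
        u, v = fields[0], fields[1]
        try:
            score = float(fields[2])
        except ValueError as exc:
            raise NetworkFormatError(f"{path}:{lineno}: bad score {fields[2]!r}") from exc
        if score < 0:
            raise NetworkValidationError(f"{path}:{lineno}: negative score {score}")
        if u not in nodes1 or v not in nodes2:
            if strict:
                raise NetworkValidationError(
                    f"{path}:{lineno}: pair ({u!r}, {v!r}) references unknown node"
                )
            skipped += 1
            continue
        if score > 0:
            if (u, v) in table.scores:
                raise NetworkValidationError(f"{path}:{lineno}: duplicate pair ({u!r}, {v!r})")
            table.set(u, v, score)
    if skipped:
        logger.warning("%s: skipped %d similarity entries with unknown nodes", path, skipped)
    return table


def write_similarity(table: SimilarityTable, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# node1\tnode2\tscore\n")
        for (u, v), s in table.items():
            fh.write(f"{u}\t{v}\t{s!r}\n")


def read_annotations(path: str) -> AnnotationMap:
    """Read a TSV ``node<TAB>group`` map; a node may appear at most once."""
    ann: AnnotationMap = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        node, group = fields
        if node in ann:
            raise NetworkValidationError(f"{path}:{lineno}: node {node!r} annotated twice")
        ann[node] = group
    return ann


def write_annotations(ann: AnnotationMap, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# node\tgroup\n")
        for node in sorted(ann):
            fh.write(f"{node}\t{ann[node]}\n")


ALIGNMENT_HEADER = "# rank\tstep\tnode1\tnode2\tscore"


def write_alignments(alignments, path: str) -> None:
    """Write path alignments: one row per step, gap as ``-``, score repeated."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(ALIGNMENT_HEADER + "\n")
        for rank, aln in enumerate(alignments, start=1):
            for step_no, (u, v) in enumerate(aln.steps, start=1):
                fh.write(
                    f"{rank}\t{step_no}\t{u if u is not None else GAP_TOKEN}"
                    f"\t{v if v is not None else GAP_TOKEN}\t{aln.score!r}\n"
                )


def read_alignments(path: str):
    """Inverse of :func:`write_alignments`."""
    from .align import PathAlignment  # deferred: avoids an import cycle

    rows: Dict[int, List[Tuple[int, Optional[str], Optional[str], float]]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 5:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 5 tab-separated fields, got {len(fields)}"
            )
        try:
            rank, step = int(fields[0]), int(fields[1])
            score = float(fields[4])
        except ValueError as exc:
            raise NetworkFormatError(f"{path}:{lineno}: bad numeric field") from exc
        u = None if fields[2] == GAP_TOKEN else fields[2]
        v = None if fields[3] == GAP_TOKEN else fields[3]
        rows.setdefault(rank, []).append((step, u, v, score))
    out = []
    for rank in sorted(rows):
        steps = sorted(rows[rank])
        out.append(
            PathAlignment(steps=[(u, v) for _, u, v, _ in steps], score=steps[0][3])
        )
    return out
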