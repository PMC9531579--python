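"""Undirected-graph primitives for group-graph comparison.

A brain graph here is a simple undirected graph whose nodes are network
components (e.g. ICA-derived intrinsic connectivity networks) and whose
edges mark conditionally dependent pairs.  Everything downstream --
connected-component bookkeeping, induced subgraphs, simple-path
enumeration and the four-way reachability classification of node pairs
-- is built on the small value types in this module.

Collections returned by these functions are deterministically ordered
(nodes by id, paths by length then lexicographically) so that pipeline
outputs are reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Hashable, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

NodeId = Hashable
Edge = Tuple[NodeId, NodeId]


class PathEnumerationOverflow(RuntimeError):
    """Raised when simple-path enumeration exceeds the configured cap.

    Distinguishable from an empty result: truncating the enumeration
    would silently break the covariance-conservation identity, so the
    caller must raise the cap or bound the path length explicitly.
    """


def canonical_edge(u: NodeId, v: NodeId) -> Edge:
    """Return the unordered pair (u, v) with the smaller endpoint first."""
    return (u, v) if _key(u) <= _key(v) else (v, u)


def _key(x: NodeId):
    # total order across ints and strings so mixed ids still sort
    return (isinstance(x, str), x)


@dataclass(frozen=True)
class Graph:
    """Simple undirected graph with ordered nodes and optional labels.

    Parameters
    ----------
    nodes : sequence of hashable ids
        Declared node set (kept even when isolated).
    edges : iterable of pairs
        Unordered pairs; (u, v) and (v, u) are the same edge.
    labels : mapping id -> (name, domain), optional
        Node metadata, e.g. anatomical label and functional domain.
    """

    nodes: Tuple[NodeId, ...]
    edges: FrozenSet[Edge]
    labels: Optional[Mapping[NodeId, Tuple[str, str]]] = None

    def __init__(self, nodes: Iterable[NodeId], edges: Iterable[Edge] = (),
                 labels: Optional[Mapping[NodeId, Tuple[str, str]]] = None):
        node_tuple = tuple(sorted(set(nodes), key=_key))
        node_set = set(node_tuple)
        edge_set = set()
        for (u, v) in edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r} not allowed")
            if u not in node_set:
                raise ValueError(f"edge endpoint {u!r} is not a declared node")
            if v not in node_set:
                raise ValueError(f"edge endpoint {v!r} is not a declared node")
            edge_set.add(canonical_edge(u, v))
        object.__setattr__(self, "nodes", node_tuple)
        object.__setattr__(self, "edges", frozenset(edge_set))
        object.__setattr__(self, "labels", dict(labels) if labels else None)

    @property
    def node_set(self) -> FrozenSet[NodeId]:
        return frozenset(self.nodes)

    def has_edge(self, u: NodeId, v: NodeId) -> bool:
        return canonical_edge(u, v) in self.edges

    def sorted_edges(self) -> List[Edge]:
        return sorted(self.edges, key=lambda e: (_key(e[0]), _key(e[1])))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if self.labels:
            for nid, (name, domain) in self.labels.items():
                if nid in g:
                    g.nodes[nid]["label"] = name
                    g.nodes[nid]["domain"] = domain
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        return cls(g.nodes(), g.edges())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Graph(n_nodes={len(self.nodes)}, n_edges={len(self.edges)})"


@dataclass(frozen=True)
class ComponentPartition:
    """Partition of a graph's nodes into connected components.

    ``blocks`` are ordered by their smallest contained node id;
    ``index`` maps each node to its block ordinal.
    """

    blocks: Tuple[FrozenSet[NodeId], ...]
    index: Mapping[NodeId, int] = field(compare=False)

    def block_of(self, node: NodeId) -> FrozenSet[NodeId]:
        return self.blocks[self.index[node]]

    def same_block(self, u: NodeId, v: NodeId) -> bool:
        return self.index[u] == self.index[v]

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class NodePath:
    """A simple path stored as its node sequence, canonically oriented.

    A path and its reversal denote the same undirected object; the
    stored orientation is the one whose first node id is smaller, so
    path sets from different graphs can be compared as plain sets.
    """

    sequence: Tuple[NodeId, ...]

    def __init__(self, sequence: Sequence[NodeId]):
        seq = tuple(sequence)
        if len(seq) < 2:
            raise ValueError("a path needs at least two nodes")
        if len(set(seq)) != len(seq):
            raise ValueError("path nodes must be distinct (simple path)")
        if _key(seq[-1]) < _key(seq[0]):
            seq = seq[::-1]
        object.__setattr__(self, "sequence", seq)

    @property
    def t(self) -> int:
        """Number of nodes on the path (>= 2)."""
        return len(self.sequence)

    @property
    def endpoints(self) -> Edge:
        return canonical_edge(self.sequence[0], self.sequence[-1])

    def edges(self) -> List[Edge]:
        s = self.sequence
        return [canonical_edge(s[i], s[i + 1]) for i in range(len(s) - 1)]

    def __iter__(self):
        return iter(self.sequence)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NodePath(" + "-".join(map(str, self.sequence)) + ")"


def connected_components(g: Graph) -> ComponentPartition:
    """Partition ``g`` into connected components.

    Blocks are ordered by smallest contained node id; an empty graph
    yields an empty partition.  Two nodes share a block iff at least one
    path joins them.
    """
    comps = [frozenset(c) for c in nx.connected_components(g.to_networkx())]
    comps.sort(key=lambda c: _key(min(c, key=_key)))
    index: Dict[NodeId, int] = {}
    for i, block in enumerate(comps):
        for node in block:
            index[node] = i
    return ComponentPartition(tuple(comps), index)


def induced_subgraph(g: Graph, node_set: Iterable[NodeId]) -> Graph:
    """Subgraph on ``node_set`` keeping every edge with both ends inside."""
    wanted = set(node_set)
    unknown = wanted - set(g.nodes)
    if unknown:
        raise ValueError(
            "unknown node id(s) in induced_subgraph: "
            + ", ".join(repr(x) for x in sorted(unknown, key=_key)))
    edges = [e for e in g.edges if e[0] in wanted and e[1] in wanted]
    labels = None
    if g.labels:
        labels = {k: v for k, v in g.labels.items() if k in wanted}
    return Graph(wanted, edges, labels)


def edge_set_difference(g1: Graph, g2: Graph) -> FrozenSet[Edge]:
    """Edges of ``g1`` absent from ``g2`` (as canonical unordered pairs)."""
    return frozenset(g1.edges - g2.edges)


def simple_paths(g: Graph, x: NodeId, y: NodeId,
                 max_length: Optional[int] = None,
                 max_paths: int = 10 ** 6) -> List[NodePath]:
    """All simple paths between ``x`` and ``y``.

    Paths are canonically oriented and sorted by length then
    lexicographic node sequence; the direct edge, when present, is the
    unique length-2 path.  Enumeration is exponential in the worst case,
    so ``max_paths`` (default 10^6) bounds the work; exceeding it raises
    :class:`PathEnumerationOverflow` rather than returning a truncated
    list.
    """
    if x == y:
        raise ValueError("path endpoints must differ")
    node_set = set(g.nodes)
    if x not in node_set or y not in node_set:
        missing = [n for n in (x, y) if n not in node_set]
        raise ValueError(f"unknown node id(s): {missing!r}")
    cutoff = (len(g.nodes) - 1) if max_length is None else (max_length - 1)
    out: List[NodePath] = []
    for seq in nx.all_simple_paths(g.to_networkx(), x, y, cutoff=cutoff):
        out.append(NodePath(seq))
        if len(out) > max_paths:
            raise PathEnumerationOverflow(
                f"more than {max_paths} simple paths between {x!r} and {y!r}")
    out.sort(key=lambda p: (p.t, tuple(_key(n) for n in p.sequence)))
    return out


def classify_pair_cases(g1: Graph, g2: Graph) -> Dict[Edge, int]:
    """Classify every unordered node pair by reachability in two graphs.

    With ``g1`` in the reference (control) slot:

    * case 1 -- reachable in g1 only (disconnection in g2),
    * case 2 -- reachable in g2 only (abnormal integration in g2),
    * case 3 -- reachable in both,
    * case 4 -- reachable in neither.
    """
    if g1.node_set != g2.node_set:
        diff = sorted(g1.node_set ^ g2.node_set, key=_key)
        raise ValueError(f"graphs must share a node set; symmetric difference: {diff!r}")
    part1 = connected_components(g1)
    part2 = connected_components(g2)
    cases: Dict[Edge, int] = {}
    nodes = g1.nodes
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            in1 = part1.same_block(u, v)
            in2 = part2.same_block(u, v)
            if in1 and in2:
                case = 3
            elif in1:
                case = 1
            elif in2:
                case = 2
            else:
                case = 4
            cases[canonical_edge(u, v)] = case
    return cases
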