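"""Disconnector / connector detection between two group graphs.

Given a reference graph (typically the control group) and a comparison
graph (typically the patient group) over the same nodes, an edge of the
reference that is missing from the comparison is a *disconnector* when
its absence actually severs multistep paths -- i.e. its endpoints land
in two different connected components of the comparison graph.  The
symmetric notion, obtained by swapping the inputs, is a *connector*: a
new edge that welds previously separate components together (abnormal
integration).  Missing or new edges whose endpoints remain mutually
reachable are merely "simple" differences; they change no reachability.

``find_transition_edges`` implements the component-walking algorithm
(iterate components of Graph1, detect those spread over >= 2 components
of Graph2, and sieve the induced-subgraph edge differences);
``transition_edges_oracle`` is an independent one-line characterisation
used to verify it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, List, Tuple

from .graphs import (
    ComponentPartition,
    Edge,
    Graph,
    canonical_edge,
    classify_pair_cases,
    connected_components,
    edge_set_difference,
    induced_subgraph,
)


def _check_same_nodes(g1: Graph, g2: Graph) -> None:
    if g1.node_set != g2.node_set:
        diff = sorted(g1.node_set ^ g2.node_set, key=lambda x: (isinstance(x, str), x))
        raise ValueError(f"graphs must share a node set; symmetric difference: {diff!r}")


def find_transition_edges(graph1: Graph, graph2: Graph) -> FrozenSet[Edge]:
    """Edges of ``graph1`` whose loss in ``graph2`` breaks reachability.

    For each connected component c1 of ``graph1``, collect the
    components of ``graph2`` intersecting c1 (the "container").  When
    the container holds at least two components, the nodes of c1 were
    separated in ``graph2``; for every 2-combination (a, b) of container
    components the edge differences of the subgraphs induced on
    nodes(a) | nodes(b) are screened, keeping edges whose endpoints lie
    in two distinct ``graph2`` components and inside c1.  A component
    pair separated only indirectly (empty difference) contributes
    nothing.
    """
    _check_same_nodes(graph1, graph2)
    part1 = connected_components(graph1)
    part2 = connected_components(graph2)
    found: set = set()
    for c1 in part1.blocks:
        container_ids = sorted({part2.index[n] for n in c1})
        if len(container_ids) < 2:
            continue
        for ia, ib in combinations(container_ids, 2):
            n_union = set(part2.blocks[ia]) | set(part2.blocks[ib])
            sub1 = induced_subgraph(graph1, n_union)
            sub2 = induced_subgraph(graph2, n_union)
            for (u, v) in edge_set_difference(sub1, sub2):
                if part2.index[u] != part2.index[v] and u in c1 and v in c1:
                    found.add(canonical_edge(u, v))
    return frozenset(found)


def transition_edges_oracle(graph1: Graph, graph2: Graph) -> FrozenSet[Edge]:
    """Direct characterisation of the transition-edge set.

    An edge of ``graph1`` missing from ``graph2`` breaks paths exactly
    when its endpoints are mutually unreachable in ``graph2``, i.e. lie
    in different connected components there.  Used as an independent
    check of :func:`find_transition_edges`.
    """
    _check_same_nodes(graph1, graph2)
    part2 = connected_components(graph2)
    return frozenset(
        e for e in edge_set_difference(graph1, graph2)
        if part2.index[e[0]] != part2.index[e[1]]
    )


@dataclass(frozen=True)
class DifferentialReport:
    """Four-way split of the edge differences between two group graphs.

    ``disconnectors`` break paths in the patient graph, ``connectors``
    create new ones; ``simple_missing`` / ``simple_additional`` are the
    remaining differences that alter no reachability.  ``pair_cases``
    classifies every node pair: 1 = reachable in control only, 2 =
    patient only, 3 = both, 4 = neither.
    """

    disconnectors: FrozenSet[Edge]
    connectors: FrozenSet[Edge]
    simple_missing: FrozenSet[Edge]
    simple_additional: FrozenSet[Edge]
    pair_cases: Dict[Edge, int]

    def sorted(self, which: str) -> List[Edge]:
        edges: FrozenSet[Edge] = getattr(self, which)
        return sorted(edges, key=lambda e: ((isinstance(e[0], str), e[0]),
                                            (isinstance(e[1], str), e[1])))

    def pairs_in_case(self, case: int) -> List[Edge]:
        return sorted((p for p, c in self.pair_cases.items() if c == case),
                      key=lambda e: ((isinstance(e[0], str), e[0]),
                                     (isinstance(e[1], str), e[1])))


def differential_report(control: Graph, patient: Graph) -> DifferentialReport:
    """Full path-based comparison of a control and a patient graph.

    Disconnectors come from the algorithm run as (control, patient),
    connectors from the swapped run; the remaining edge-set differences
    are reported as simple missing / simple additional edges.
    """
    _check_same_nodes(control, patient)
    disconnectors = find_transition_edges(control, patient)
    connectors = find_transition_edges(patient, control)
    simple_missing = frozenset(edge_set_difference(control, patient) - disconnectors)
    simple_additional = frozenset(edge_set_difference(patient, control) - connectors)
    cases = classify_pair_cases(control, patient)
    return DifferentialReport(disconnectors, connectors,
                              simple_missing, simple_additional, cases)
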