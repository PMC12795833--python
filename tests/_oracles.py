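"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms: template matching
is checked against exhaustive tuple enumeration, betweenness against
explicit enumeration of all shortest paths, and the hypergeometric tail
against scipy's survival function.
"""

from __future__ import annotations

from itertools import permutations, product

import networkx as nx

from cytoreg.graph import KnowledgeGraph
from cytoreg.templates import Match, PathTemplate


def brute_force_matches(
    graph: KnowledgeGraph, template: PathTemplate
) -> list[Match]:
    """Filter all ordered node tuples of slot length by the constraints.

    Every combination of satisfying edges yields its own match, mirroring
    the path-instance semantics of the matcher.
    """
    node_ids = sorted(graph.nodes)
    k = len(template.slots)
    matches = []
    for tup in permutations(node_ids, k):
        if not all(
            slot.matches(graph.node(nid))
            for slot, nid in zip(template.slots, tup)
        ):
            continue
        step_edges = []
        ok = True
        for i, allowed in enumerate(template.edge_constraints):
            present = [
                (tup[i], tup[i + 1], itype)
                for itype in sorted(allowed)
                if graph.has_edge(tup[i], tup[i + 1], itype)
            ]
            if not present:
                ok = False
                break
            step_edges.append(present)
        if ok:
            for combo in product(*step_edges):
                matches.append(Match(template.name, tup, tuple(combo)))
    matches.sort(key=lambda m: (m.node_ids, m.edges))
    return matches


def brute_force_betweenness(graph: nx.Graph) -> dict:
    """Unnormalized betweenness by enumerating every shortest path."""
    bc = {v: 0.0 for v in graph}
    nodes = sorted(graph)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if not nx.has_path(graph, s, t):
                continue
            paths = list(nx.all_shortest_paths(graph, s, t))
            sigma = len(paths)
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / sigma
    return bc
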