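"""Shared fixtures: small hand-built graphs and random type-valid graphs."""

from __future__ import annotations

import numpy as np
import pytest

from cytoreg.graph import EDGE_TARGET_KIND, KnowledgeGraph, Node

KIND_CHOICES = ["gene", "protein"]
CATEGORY_CHOICES = [
    "cytokine",
    "cytokine_receptor",
    "asd_associated",
    "mediator",
    "other",
]
ITYPE_CHOICES = sorted(EDGE_TARGET_KIND)


def make_node(node_id, symbol=None, kind="protein", categories=("other",)):
    return Node(node_id, symbol or node_id.split(":")[0], kind, frozenset(categories))


def pair_graph(symbol_specs):
    """Graph with a gene+protein pair (plus expression edge) per
    (symbol, category) spec."""
    g = KnowledgeGraph()
    for symbol, category in symbol_specs:
        g.add_node(make_node(f"{symbol}:gene", symbol, "gene", (category,)))
        g.add_node(make_node(f"{symbol}:protein", symbol, "protein", (category,)))
        g.add_edge(f"{symbol}:gene", f"{symbol}:protein", "expression")
    return g


def random_typed_graph(
    rng: np.random.Generator, max_nodes: int = 12, max_edges: int = 30
) -> KnowledgeGraph:
    """Random graph whose every edge satisfies the direction-typing rules.

    Node kinds and categories are sampled uniformly, so all five templates
    have candidate slots with reasonable probability.
    """
    g = KnowledgeGraph()
    n_nodes = int(rng.integers(2, max_nodes + 1))
    for i in range(n_nodes):
        kind = KIND_CHOICES[int(rng.integers(2))]
        n_cats = int(rng.integers(1, 3))
        cats = {
            CATEGORY_CHOICES[int(rng.integers(len(CATEGORY_CHOICES)))]
            for _ in range(n_cats)
        }
        g.add_node(Node(f"N{i:02d}", f"S{i:02d}", kind, frozenset(cats)))
    genes = [n.id for n in g.nodes_with(kind="gene")]
    proteins = [n.id for n in g.nodes_with(kind="protein")]
    all_ids = sorted(g.nodes)
    n_edges = int(rng.integers(0, max_edges + 1))
    for _ in range(n_edges):
        itype = ITYPE_CHOICES[int(rng.integers(len(ITYPE_CHOICES)))]
        if itype == "expression":
            if not genes or not proteins:
                continue
            source = genes[int(rng.integers(len(genes)))]
            target = proteins[int(rng.integers(len(proteins)))]
        else:
            pool = genes if EDGE_TARGET_KIND[itype] == "gene" else proteins
            if not pool:
                continue
            source = all_ids[int(rng.integers(len(all_ids)))]
            target = pool[int(rng.integers(len(pool)))]
        if source != target:
            g.add_edge(source, target, itype)
    return g


@pytest.fixture
def planted_t1_graph():
    """One cytokine directly regulating one ASD protein (a single T1 path)."""
    g = pair_graph([("IL6", "cytokine"), ("SHANK3", "asd_associated")])
    g.add_edge("IL6:protein", "SHANK3:protein", "activity_regulation")
    return g
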