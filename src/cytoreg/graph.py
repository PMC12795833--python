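"""Typed molecular knowledge graph: data model and file formats.

The pipeline operates on a directed multigraph with two node kinds (``gene``
and ``protein``) and five regulatory interaction types.  Interaction types
carry direction-typing rules — an ``expression`` edge always runs from a gene
to its protein product, ``expression_regulation`` always targets a gene node,
and the three protein-level regulation types (activity, transport,
degradation) always target a protein node.  These rules are enforced at load
time so that no stored graph can violate them.

Node roles (cytokine, cytokine receptor, ASD-associated, mediator) are plain
categories attached to nodes; they drive both the path-template matching and
the downstream prioritization.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "KINDS",
    "CATEGORIES",
    "INTERACTION_TYPES",
    "EDGE_TARGET_KIND",
    "GraphError",
    "Node",
    "Edge",
    "KnowledgeGraph",
    "GeneSet",
    "AnnotationTable",
    "read_nodes",
    "read_edges",
    "read_graph",
    "write_graph",
    "write_nodes_tsv",
    "write_edges_tsv",
    "read_gene_sets",
    "read_annotations",
]

KINDS = frozenset({"gene", "protein"})

CATEGORIES = frozenset(
    {"cytokine", "cytokine_receptor", "asd_associated", "mediator", "other"}
)

#: The five interaction types of the regulatory model.
INTERACTION_TYPES = frozenset(
    {
        "expression_regulation",
        "expression",
        "activity_regulation",
        "transport_regulation",
        "degradation_regulation",
    }
)

#: Required kind of the *target* node, per interaction type.
EDGE_TARGET_KIND: Mapping[str, str] = {
    "expression": "protein",
    "expression_regulation": "gene",
    "activity_regulation": "protein",
    "transport_regulation": "protein",
    "degradation_regulation": "protein",
}

#: Required kind of the *source* node, where constrained.
EDGE_SOURCE_KIND: Mapping[str, str] = {"expression": "gene"}


class GraphError(ValueError):
    """Raised on any violation of the knowledge-graph invariants."""


@dataclass(frozen=True)
class Node:
    """A gene or protein node.

    ``id`` is opaque and unique within a graph; by convention the generators
    in this package use ``SYMBOL:gene`` / ``SYMBOL:protein``.  ``categories``
    holds functional roles; an empty set is normalized to ``{"other"}``.
    """

    id: str
    symbol: str
    kind: str
    categories: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise GraphError(f"unknown node kind {self.kind!r} for node {self.id!r}")
        cats = frozenset(self.categories) or frozenset({"other"})
        unknown = cats - CATEGORIES
        if unknown:
            raise GraphError(
                f"unknown categories {sorted(unknown)} for node {self.id!r}"
            )
        object.__setattr__(self, "categories", cats)
        object.__setattr__(self, "symbol", self.symbol.upper())


@dataclass
class Edge:
    """A typed directed interaction.

    ``provenance`` records which path templates (or other sources) produced
    the edge; it is empty for raw input graphs and non-empty in consolidated
    networks.
    """

    source: str
    target: str
    interaction_type: str
    provenance: set = field(default_factory=set)

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.interaction_type)


class KnowledgeGraph:
    """Directed multigraph keyed by (source, target, interaction_type).

    At most one edge exists per triple; re-adding a triple unions the
    provenance sets.  All direction-typing rules are checked in
    :meth:`add_edge`.
    """

    def __init__(self) -> None:
        self._nodes: dict[str, Node] = {}
        self._edges: dict[tuple[str, str, str], Edge] = {}
        self._out: dict[str, list[Edge]] = defaultdict(list)
        self._in: dict[str, list[Edge]] = defaultdict(list)

    # -- construction ------------------------------------------------------

    def add_node(self, node: Node) -> None:
        existing = self._nodes.get(node.id)
        if existing is not None:
            if existing != node:
                raise GraphError(
                    f"conflicting records for node id {node.id!r}: "
                    f"{existing} vs {node}"
                )
            return
        self._nodes[node.id] = node

    def add_edge(
        self,
        source: str,
        target: str,
        interaction_type: str,
        provenance: Iterable[str] = (),
    ) -> Edge:
        if interaction_type not in INTERACTION_TYPES:
            raise GraphError(f"unknown interaction type {interaction_type!r}")
        for nid in (source, target):
            if nid not in self._nodes:
                raise GraphError(f"edge references unknown node id {nid!r}")
        tgt_kind = EDGE_TARGET_KIND[interaction_type]
        if self._nodes[target].kind != tgt_kind:
            raise GraphError(
                f"{interaction_type} edge {source!r}->{target!r} must target a "
                f"{tgt_kind} node, not {self._nodes[target].kind}"
            )
        src_kind = EDGE_SOURCE_KIND.get(interaction_type)
        if src_kind is not None and self._nodes[source].kind != src_kind:
            raise GraphError(
                f"{interaction_type} edge {source!r}->{target!r} must originate "
                f"from a {src_kind} node, not {self._nodes[source].kind}"
            )
        key = (source, target, interaction_type)
        edge = self._edges.get(key)
        if edge is None:
            edge = Edge(source, target, interaction_type, set(provenance))
            self._edges[key] = edge
            self._out[source].append(edge)
            self._in[target].append(edge)
        else:
            edge.provenance.update(provenance)
        return edge

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> dict[str, Node]:
        return self._nodes

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges.values())

    def node(self, node_id: str) -> Node:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise GraphError(f"unknown node id {node_id!r}") from None

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def has_edge(self, source: str, target: str, interaction_type: str) -> bool:
        return (source, target, interaction_type) in self._edges

    def out_edges(self, node_id: str) -> list[Edge]:
        return self._out.get(node_id, [])

    def in_edges(self, node_id: str) -> list[Edge]:
        return self._in.get(node_id, [])

    def degree(self, node_id: str) -> int:
        """Typed multigraph degree: incident edges, both directions."""
        self.node(node_id)
        return len(self._out.get(node_id, [])) + len(self._in.get(node_id, []))

    def nodes_with(self, kind: str | None = None, category: str | None = None):
        for node in self._nodes.values():
            if kind is not None and node.kind != kind:
                continue
            if category is not None and category not in node.categories:
                continue
            yield node

    def edge_triples(self) -> set[tuple[str, str, str]]:
        return set(self._edges)

    def node_records(self) -> set[tuple[str, str, str, frozenset]]:
        return {
            (n.id, n.symbol, n.kind, n.categories) for n in self._nodes.values()
        }

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[Node]:
        return iter(self._nodes.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        if self.node_records() != other.node_records():
            return False
        if set(self._edges) != set(other._edges):
            return False
        return all(
            self._edges[k].provenance == other._edges[k].provenance
            for k in self._edges
        )

    def copy(self) -> "KnowledgeGraph":
        g = KnowledgeGraph()
        for node in self._nodes.values():
            g.add_node(node)
        for edge in self._edges.values():
            g.add_edge(*edge.triple, provenance=edge.provenance)
        return g

    # -- conversions -------------------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for node in self._nodes.values():
            g.add_node(
                node.id,
                symbol=node.symbol,
                kind=node.kind,
                categories=";".join(sorted(node.categories)),
            )
        for edge in self._edges.values():
            g.add_edge(
                edge.source,
                edge.target,
                key=edge.interaction_type,
                interaction_type=edge.interaction_type,
                provenance=";".join(sorted(edge.provenance)),
            )
        return g

    def undirected_projection(self) -> nx.Graph:
        """Simple undirected graph: one unweighted edge per connected pair."""
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        for source, target, _ in self._edges:
            if source != target:
                g.add_edge(source, target)
        return g


@dataclass(frozen=True)
class GeneSet:
    """A named set of (upper-cased) gene symbols."""

    name: str
    symbols: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "symbols", frozenset(s.upper() for s in self.symbols)
        )

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class AnnotationTable:
    """Flat term -> gene-set annotations with an explicit background.

    ``terms`` maps a term id to ``(term_name, frozenset of symbols)``.  Every
    annotated symbol must be in ``background``; term gene sets are non-empty.
    No ontology-graph propagation is performed — annotations are taken as
    given.
    """

    terms: dict[str, tuple[str, frozenset]]
    background: frozenset

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise GraphError(f"term {term_id!r} has an empty gene set")
            stray = genes - self.background
            if stray:
                raise GraphError(
                    f"term {term_id!r} annotates symbols outside the "
                    f"background: {sorted(stray)[:5]}"
                )

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def genes(self, term_id: str) -> frozenset:
        return self.terms[term_id][1]

    def term_name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def terms_annotating(self, symbol: str) -> set[str]:
        symbol = symbol.upper()
        return {t for t, (_, genes) in self.terms.items() if symbol in genes}

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term_id in sorted(self.terms):
                name, genes = self.terms[term_id]
                fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _tsv_rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) skipping blank and '#' lines."""
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            yield lineno, row


def read_nodes(path: str | Path) -> list[Node]:
    """Read a node table (columns: id, symbol, kind, categories)."""
    rows = _tsv_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise GraphError(f"{path}: empty node table (header required)") from None
    required = ["id", "symbol", "kind", "categories"]
    if [h.strip() for h in header[:4]] != required:
        raise GraphError(f"{path}: node table header must be {required}")
    nodes: list[Node] = []
    seen: set[str] = set()
    for lineno, row in rows:
        if len(row) < 3:
            raise GraphError(f"{path}:{lineno}: expected >= 3 columns")
        node_id, symbol, kind = row[0], row[1], row[2]
        cats = row[3] if len(row) > 3 else ""
        if node_id in seen:
            raise GraphError(f"{path}:{lineno}: duplicate node id {node_id!r}")
        seen.add(node_id)
        categories = frozenset(c for c in cats.split(";") if c)
        try:
            nodes.append(Node(node_id, symbol, kind, categories))
        except GraphError as exc:
            raise GraphError(f"{path}:{lineno}: {exc}") from None
    return nodes


def read_edges(path: str | Path, nodes: Iterable[Node]) -> KnowledgeGraph:
    """Read an edge table into a graph over the given nodes.

    Columns: source, target, interaction_type and optionally provenance
    (semicolon-separated).  Duplicate triples collapse with provenance
    unioned; direction-typing violations are rejected with the line number.
    """
    graph = KnowledgeGraph()
    for node in nodes:
        graph.add_node(node)
    rows = _tsv_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise GraphError(f"{path}: empty edge table (header required)") from None
    required = ["source", "target", "interaction_type"]
    if [h.strip() for h in header[:3]] != required:
        raise GraphError(f"{path}: edge table header must start with {required}")
    for lineno, row in rows:
        if len(row) < 3:
            raise GraphError(f"{path}:{lineno}: expected >= 3 columns")
        provenance = (
            [p for p in row[3].split(";") if p] if len(row) > 3 else []
        )
        try:
            graph.add_edge(row[0], row[1], row[2], provenance)
        except GraphError as exc:
            raise GraphError(f"{path}:{lineno}: {exc}") from None
    return graph


def _nodes_companion(path: Path) -> Path:
    if path.suffix == ".tsv":
        return path.with_suffix(".nodes.tsv")
    return path.with_name(path.name + ".nodes.tsv")


def write_nodes_tsv(graph: KnowledgeGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tsymbol\tkind\tcategories\n")
        for node in sorted(graph, key=lambda n: n.id):
            fh.write(
                f"{node.id}\t{node.symbol}\t{node.kind}\t"
                f"{';'.join(sorted(node.categories))}\n"
            )


def write_edges_tsv(graph: KnowledgeGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tinteraction_type\tprovenance\n")
        for key in sorted(graph.edge_triples()):
            prov = ";".join(sorted(graph._edges[key].provenance))
            fh.write("\t".join([*key, prov]) + "\n")


def write_graph(
    graph: KnowledgeGraph, path: str | Path, format: str = "tsv"
) -> None:
    """Write a graph as TSV (edge table + node companion), GraphML, or SIF.

    TSV writes the edge table at ``path`` and the node table beside it (same
    stem, ``.nodes.tsv`` suffix).  SIF is a lossy export (ids and types only);
    GraphML and TSV round-trip exactly.
    """
    path = Path(path)
    if format == "tsv":
        write_nodes_tsv(graph, _nodes_companion(path))
        write_edges_tsv(graph, path)
    elif format == "graphml":
        nx.write_graphml(graph.to_networkx(), path)
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            connected = set()
            for source, target, itype in sorted(graph.edge_triples()):
                fh.write(f"{source}\t{itype}\t{target}\n")
                connected.update((source, target))
            for node_id in sorted(set(graph.nodes) - connected):
                fh.write(f"{node_id}\n")
    else:
        raise GraphError(f"unsupported graph format {format!r}")


def read_graph(
    path: str | Path,
    format: str = "tsv",
    nodes: Iterable[Node] | None = None,
) -> KnowledgeGraph:
    """Read a graph written by :func:`write_graph`.

    SIF carries no node metadata, so ``nodes`` must be supplied for it.
    """
    path = Path(path)
    if format == "tsv":
        if nodes is None:
            nodes = read_nodes(_nodes_companion(path))
        return read_edges(path, nodes)
    if format == "graphml":
        nxg = nx.read_graphml(path, force_multigraph=True)
        graph = KnowledgeGraph()
        for node_id, data in nxg.nodes(data=True):
            categories = frozenset(
                c for c in data.get("categories", "").split(";") if c
            )
            graph.add_node(
                Node(node_id, data["symbol"], data["kind"], categories)
            )
        for source, target, data in nxg.edges(data=True):
            provenance = [
                p for p in data.get("provenance", "").split(";") if p
            ]
            graph.add_edge(source, target, data["interaction_type"], provenance)
        return graph
    if format == "sif":
        if nodes is None:
            raise GraphError("reading SIF requires a node table")
        graph = KnowledgeGraph()
        for node in nodes:
            graph.add_node(node)
        for lineno, row in _tsv_rows(path):
            if len(row) == 1:
                graph.node(row[0])  # isolated node; must exist
                continue
            if len(row) != 3:
                raise GraphError(f"{path}:{lineno}: malformed SIF line")
            source, itype, target = row
            graph.add_edge(source, target, itype)
        return graph
    raise GraphError(f"unsupported graph format {format!r}")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (one set per row) or a plain symbol list.

    A ``.gmt`` extension selects GMT parsing; anything else is treated as one
    symbol per line, producing a single set named after the file stem.
    """
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        sets: list[GeneSet] = []
        for lineno, row in _tsv_rows(path):
            if len(row) < 3 or not any(s.strip() for s in row[2:]):
                raise GraphError(
                    f"{path}:{lineno}: GMT row {row[0]!r} has no symbols"
                )
            sets.append(
                GeneSet(row[0], frozenset(s for s in row[2:] if s.strip()))
            )
        return sets
    symbols = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(line)
    if not symbols:
        raise GraphError(f"{path}: empty gene list")
    return [GeneSet(path.stem, frozenset(symbols))]


def read_annotations(
    path: str | Path, background: Iterable[str] | None = None
) -> AnnotationTable:
    """Read term annotations from GMT or a term-gene TSV.

    GMT rows are ``term_id <tab> term_name <tab> symbols...``; the TSV form
    has columns term_id, term_name, symbol (one gene per row).  The background
    defaults to the union of all annotated symbols and can be widened by
    passing ``background`` explicitly.
    """
    path = Path(path)
    terms: dict[str, tuple[str, set]] = {}
    if path.suffix.lower() == ".gmt":
        for lineno, row in _tsv_rows(path):
            if len(row) < 3:
                raise GraphError(f"{path}:{lineno}: GMT row needs >= 3 fields")
            name, genes = terms.setdefault(row[0], (row[1], set()))
            genes.update(s.upper() for s in row[2:] if s.strip())
    else:
        rows = _tsv_rows(path)
        _, header = next(rows, (0, []))
        if [h.strip() for h in header[:3]] != ["term_id", "term_name", "symbol"]:
            raise GraphError(
                f"{path}: annotation TSV header must be term_id, term_name, symbol"
            )
        for lineno, row in rows:
            if len(row) < 3:
                raise GraphError(f"{path}:{lineno}: expected 3 columns")
            name, genes = terms.setdefault(row[0], (row[1], set()))
            genes.add(row[2].upper())
    frozen = {t: (name, frozenset(genes)) for t, (name, genes) in terms.items()}
    if background is None:
        bg = frozenset().union(*(g for _, g in frozen.values())) if frozen else frozenset()
    else:
        bg = frozenset(s.upper() for s in background)
        bg = bg.union(*(g for _, g in frozen.values())) if frozen else bg
    return AnnotationTable(frozen, bg)
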