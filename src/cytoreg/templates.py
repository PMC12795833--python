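"""Path-template matching and subnetwork consolidation.

A path template is a declarative chain of node constraints (kind plus
required categories, each slot labelled with a role) joined by sets of
allowed interaction types.  Matching a template against the knowledge graph
enumerates every injective assignment of graph nodes to slots such that each
consecutive pair is connected by an edge of an allowed type.  The matched
subnetworks — one per template — are merged into a consolidated regulatory
network whose edges remember which templates produced them.

Five default templates cover the regulatory routes from a cytokine protein
to an ASD-associated target: direct protein-level regulation, protein-level
regulation through an expressed mediator, direct transcriptional regulation,
and transcriptional regulation relayed through a mediator or receptor
protein.  All five can be overridden from a YAML config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .graph import (
    CATEGORIES,
    EDGE_SOURCE_KIND,
    EDGE_TARGET_KIND,
    INTERACTION_TYPES,
    GraphError,
    KnowledgeGraph,
    Node,
)

__all__ = [
    "ROLES",
    "TemplateError",
    "SlotConstraint",
    "PathTemplate",
    "Match",
    "Subnetwork",
    "ConsolidatedNetwork",
    "NetworkSummary",
    "default_templates",
    "parse_templates",
    "match_template",
    "subnetwork_from_matches",
    "merge_subnetworks",
    "summarize_network",
    "reconstruct",
]

ROLES = frozenset({"source_cytokine", "mediator", "asd_target"})

PROTEIN_REGULATION = frozenset(
    {"activity_regulation", "transport_regulation", "degradation_regulation"}
)


class TemplateError(ValueError):
    """Raised for malformed template definitions."""


@dataclass(frozen=True)
class SlotConstraint:
    kind: str
    categories: frozenset
    role: str

    def matches(self, node: Node) -> bool:
        return node.kind == self.kind and self.categories <= node.categories


@dataclass(frozen=True)
class PathTemplate:
    """One reconstruction query: slots plus per-step allowed edge types."""

    name: str
    slots: tuple[SlotConstraint, ...]
    edge_constraints: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if len(self.slots) < 2:
            raise TemplateError(f"template {self.name!r}: needs >= 2 slots")
        if len(self.edge_constraints) != len(self.slots) - 1:
            raise TemplateError(
                f"template {self.name!r}: {len(self.slots)} slots require "
                f"{len(self.slots) - 1} edge constraints"
            )
        if self.slots[0].role != "source_cytokine":
            raise TemplateError(
                f"template {self.name!r}: first slot must be the source_cytokine"
            )
        if self.slots[-1].role != "asd_target":
            raise TemplateError(
                f"template {self.name!r}: last slot must be the asd_target"
            )
        roles = [s.role for s in self.slots]
        if roles.count("source_cytokine") != 1 or roles.count("asd_target") != 1:
            raise TemplateError(
                f"template {self.name!r}: exactly one source_cytokine and one "
                "asd_target slot allowed"
            )
        for slot in self.slots:
            if slot.kind not in {"gene", "protein"}:
                raise TemplateError(
                    f"template {self.name!r}: unknown slot kind {slot.kind!r}"
                )
            if slot.role not in ROLES:
                raise TemplateError(
                    f"template {self.name!r}: unknown role {slot.role!r}"
                )
            unknown = slot.categories - CATEGORIES
            if unknown:
                raise TemplateError(
                    f"template {self.name!r}: unknown categories {sorted(unknown)}"
                )
        for i, allowed in enumerate(self.edge_constraints):
            if not allowed:
                raise TemplateError(
                    f"template {self.name!r}: empty edge constraint at step {i}"
                )
            unknown = allowed - INTERACTION_TYPES
            if unknown:
                raise TemplateError(
                    f"template {self.name!r}: unknown interaction types "
                    f"{sorted(unknown)}"
                )
            for itype in allowed:
                if EDGE_TARGET_KIND[itype] != self.slots[i + 1].kind:
                    raise TemplateError(
                        f"template {self.name!r}: {itype} cannot target a "
                        f"{self.slots[i + 1].kind} slot (step {i})"
                    )
                src_kind = EDGE_SOURCE_KIND.get(itype)
                if src_kind is not None and src_kind != self.slots[i].kind:
                    raise TemplateError(
                        f"template {self.name!r}: {itype} cannot originate from "
                        f"a {self.slots[i].kind} slot (step {i})"
                    )


@dataclass(frozen=True)
class Match:
    """One injective slot assignment, with the matched edge triples."""

    template: str
    node_ids: tuple[str, ...]
    edges: tuple[tuple[str, str, str], ...]


@dataclass
class Subnetwork:
    """A template's matched subgraph plus the role of every matched node."""

    graph: KnowledgeGraph
    roles: dict[str, set] = field(default_factory=dict)


#: A merged subnetwork; structurally identical to Subnetwork but every edge
#: carries non-empty provenance and the role index covers all nodes.
ConsolidatedNetwork = Subnetwork


@dataclass
class NetworkSummary:
    n_nodes_by_kind: dict[str, int]
    n_edges_by_type: dict[str, int]
    n_regulator_cytokines: int
    n_regulated_asd_proteins: int
    n_regulated_asd_genes: int

    @property
    def n_nodes(self) -> int:
        return sum(self.n_nodes_by_kind.values())

    @property
    def n_edges(self) -> int:
        return sum(self.n_edges_by_type.values())

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_nodes_by_kind": dict(sorted(self.n_nodes_by_kind.items())),
            "n_edges_by_type": dict(sorted(self.n_edges_by_type.items())),
            "n_regulator_cytokines": self.n_regulator_cytokines,
            "n_regulated_asd_proteins": self.n_regulated_asd_proteins,
            "n_regulated_asd_genes": self.n_regulated_asd_genes,
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# default templates
# ---------------------------------------------------------------------------


def _slot(kind: str, categories: Iterable[str], role: str) -> SlotConstraint:
    return SlotConstraint(kind, frozenset(categories), role)


def default_templates() -> list[PathTemplate]:
    """The five built-in reconstruction queries (T1-T5).

    T1: cytokine protein --(activity|transport|degradation regulation)--> ASD protein
    T2: cytokine protein --expression_regulation--> mediator gene
        --expression--> mediator protein
        --(activity|transport|degradation regulation)--> ASD protein
    T3: cytokine protein --expression_regulation--> ASD gene
    T4: cytokine protein --activity_regulation--> mediator protein
        --expression_regulation--> ASD gene
    T5: cytokine protein --activity_regulation--> receptor protein
        --expression_regulation--> ASD gene
    """
    cyt = _slot("protein", {"cytokine"}, "source_cytokine")
    asd_protein = _slot("protein", {"asd_associated"}, "asd_target")
    asd_gene = _slot("gene", {"asd_associated"}, "asd_target")
    return [
        PathTemplate("T1", (cyt, asd_protein), (PROTEIN_REGULATION,)),
        PathTemplate(
            "T2",
            (
                cyt,
                _slot("gene", {"mediator"}, "mediator"),
                _slot("protein", {"mediator"}, "mediator"),
                asd_protein,
            ),
            (
                frozenset({"expression_regulation"}),
                frozenset({"expression"}),
                PROTEIN_REGULATION,
            ),
        ),
        PathTemplate(
            "T3", (cyt, asd_gene), (frozenset({"expression_regulation"}),)
        ),
        PathTemplate(
            "T4",
            (cyt, _slot("protein", {"mediator"}, "mediator"), asd_gene),
            (
                frozenset({"activity_regulation"}),
                frozenset({"expression_regulation"}),
            ),
        ),
        PathTemplate(
            "T5",
            (
                cyt,
                _slot("protein", {"cytokine_receptor"}, "mediator"),
                asd_gene,
            ),
            (
                frozenset({"activity_regulation"}),
                frozenset({"expression_regulation"}),
            ),
        ),
    ]


def parse_templates(source: str | Path | dict) -> list[PathTemplate]:
    """Parse templates from a YAML file (or an already-loaded mapping).

    Expected structure::

        templates:
          - name: T1
            slots:
              - {kind: protein, categories: [cytokine], role: source_cytokine}
              - {kind: protein, categories: [asd_associated], role: asd_target}
            edges:
              - [activity_regulation, transport_regulation]
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        data = source
    if not isinstance(data, dict) or "templates" not in data:
        raise TemplateError("template config must contain a 'templates' list")
    templates = []
    for spec in data["templates"]:
        name = spec.get("name", "<unnamed>")
        try:
            slots = tuple(
                _slot(s["kind"], s.get("categories", []), s["role"])
                for s in spec["slots"]
            )
            edges = tuple(frozenset(e) for e in spec["edges"])
        except (KeyError, TypeError) as exc:
            raise TemplateError(f"template {name!r}: malformed entry ({exc})")
        templates.append(PathTemplate(name, slots, edges))
    names = [t.name for t in templates]
    if len(set(names)) != len(names):
        raise TemplateError("duplicate template names in config")
    return templates


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def match_template(graph: KnowledgeGraph, template: PathTemplate) -> list[Match]:
    """Enumerate all injective matches of ``template`` in ``graph``.

    Depth-first extension from the candidate set of the first slot; results
    are returned sorted by their node-id tuple so the output order is
    deterministic regardless of graph construction order.
    """
    slots = template.slots
    matches: list[Match] = []

    def extend(nodes: list[str], edges: list[tuple[str, str, str]]) -> None:
        depth = len(nodes)
        if depth == len(slots):
            matches.append(Match(template.name, tuple(nodes), tuple(edges)))
            return
        allowed = template.edge_constraints[depth - 1]
        slot = slots[depth]
        used = set(nodes)
        for edge in graph.out_edges(nodes[-1]):
            if edge.interaction_type not in allowed:
                continue
            if edge.target in used:
                continue
            if not slot.matches(graph.node(edge.target)):
                continue
            nodes.append(edge.target)
            edges.append(edge.triple)
            extend(nodes, edges)
            nodes.pop()
            edges.pop()

    for node in graph:
        if slots[0].matches(node):
            extend([node.id], [])
    matches.sort(key=lambda m: (m.node_ids, m.edges))
    return matches


def subnetwork_from_matches(
    graph: KnowledgeGraph, matches: Sequence[Match]
) -> Subnetwork:
    """Union of all matched nodes and edges from one template.

    Each edge's provenance is the template name; the role index records the
    slot role(s) each node occupied across matches.
    """
    templates = {m.template for m in matches}
    if len(templates) > 1:
        raise TemplateError(
            f"matches from multiple templates: {sorted(templates)}"
        )
    sub = KnowledgeGraph()
    roles: dict[str, set] = {}
    for match in matches:
        n = len(match.node_ids)
        for i, node_id in enumerate(match.node_ids):
            sub.add_node(graph.node(node_id))
            if i == 0:
                role = "source_cytokine"
            elif i == n - 1:
                role = "asd_target"
            else:
                role = "mediator"
            roles.setdefault(node_id, set()).add(role)
        for triple in match.edges:
            sub.add_edge(*triple, provenance={match.template})
    return Subnetwork(sub, roles)


def merge_subnetworks(
    subnets: Iterable[Subnetwork | KnowledgeGraph],
) -> ConsolidatedNetwork:
    """Merge subnetworks: node/edge union with provenance and roles unioned.

    The operation is commutative, associative and idempotent.  Conflicting
    node records under one id (e.g. differing kind) raise ``GraphError``.
    """
    merged = KnowledgeGraph()
    roles: dict[str, set] = {}
    for subnet in subnets:
        if isinstance(subnet, KnowledgeGraph):
            subnet = Subnetwork(subnet, {})
        for node in subnet.graph:
            merged.add_node(node)
        for edge in subnet.graph.edges:
            merged.add_edge(*edge.triple, provenance=edge.provenance)
        for node_id, node_roles in subnet.roles.items():
            roles.setdefault(node_id, set()).update(node_roles)
    return ConsolidatedNetwork(merged, roles)


def summarize_network(net: ConsolidatedNetwork) -> NetworkSummary:
    """Headline counts of a consolidated network.

    Regulator cytokines are distinct nodes that occupied a source-cytokine
    slot in at least one match; regulated ASD proteins/genes are distinct
    target-slot nodes split by kind.
    """
    graph = net.graph
    by_kind: dict[str, int] = {"gene": 0, "protein": 0}
    for node in graph:
        by_kind[node.kind] = by_kind.get(node.kind, 0) + 1
    by_type: dict[str, int] = {}
    for edge in graph.edges:
        by_type[edge.interaction_type] = by_type.get(edge.interaction_type, 0) + 1
    regulators = {
        nid for nid, r in net.roles.items() if "source_cytokine" in r
    }
    targets = {nid for nid, r in net.roles.items() if "asd_target" in r}
    target_proteins = {
        nid for nid in targets if graph.node(nid).kind == "protein"
    }
    target_genes = {nid for nid in targets if graph.node(nid).kind == "gene"}
    return NetworkSummary(
        n_nodes_by_kind=by_kind,
        n_edges_by_type=by_type,
        n_regulator_cytokines=len(regulators),
        n_regulated_asd_proteins=len(target_proteins),
        n_regulated_asd_genes=len(target_genes),
    )


def reconstruct(
    graph: KnowledgeGraph,
    templates: Sequence[PathTemplate] | None = None,
    blacklist: Iterable[tuple[str, str, str]] = (),
) -> tuple[ConsolidatedNetwork, dict[str, list[Match]]]:
    """Run all templates against a graph and merge the matched subnetworks.

    ``blacklist`` removes specific edge triples before matching; it stands in
    for manual curation of automatically extracted interactions.
    """
    if templates is None:
        templates = default_templates()
    blacklist = set(blacklist)
    if blacklist:
        pruned = KnowledgeGraph()
        for node in graph:
            pruned.add_node(node)
        for edge in graph.edges:
            if edge.triple not in blacklist:
                pruned.add_edge(*edge.triple, provenance=edge.provenance)
        graph = pruned
    matches = {t.name: match_template(graph, t) for t in templates}
    subnets = [
        subnetwork_from_matches(graph, m) for m in matches.values() if m
    ]
    return merge_subnetworks(subnets), matches
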