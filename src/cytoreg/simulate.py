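"""Synthetic knowledge-graph generator with planted regulatory structure.

The generator emulates the statistical shape of the curated molecular
knowledge base the pipeline was designed around, so that every downstream
stage can be exercised and validated without any external download:

* a bipartite gene/protein node population — every symbol contributes one
  gene node and one protein node joined by an ``expression`` edge — split
  into cytokines, cytokine receptors, ASD-associated genes, mediators and
  background symbols;
* planted regulatory paths from cytokine proteins to ASD-associated nodes,
  each path instantiating one of the five default reconstruction templates;
  a small set of "hub" cytokines receives many paths (Poisson with mean
  ``paths_per_hub``) while the rest receive few (``paths_per_nonhub``),
  giving a known ground truth for the prioritization stage;
* uniformly sampled type-valid noise edges;
* flat GO-style annotations in which a subset of "disease-like" terms is
  enriched on the targeted ASD genes (and on the cytokines that regulate
  them) against a low background annotation rate;
* a drug-target table covering a configurable fraction of the cytokines
  with approved entries.

Default sizes follow the study conditions of the real analysis: 186
cytokines, 114 receptors and 234 high-confidence ASD genes.  Everything is
driven by one integer seed; identical configs produce byte-identical
fixture bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graph import (
    AnnotationTable,
    GraphError,
    KnowledgeGraph,
    Node,
    read_annotations,
    read_edges,
    read_nodes,
    write_edges_tsv,
    write_nodes_tsv,
)

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_kg",
    "generate_annotations",
    "generate_drug_table",
    "generate_all",
    "write_fixture_bundle",
    "load_fixture_bundle",
]

PROTEIN_REG_TYPES = (
    "activity_regulation",
    "transport_regulation",
    "degradation_regulation",
)


@dataclass
class SynthConfig:
    """Generator parameters; defaults mirror the real input list sizes."""

    n_cytokines: int = 186
    n_receptors: int = 114
    n_asd_genes: int = 234
    n_mediators: int = 100
    n_other: int = 50
    n_hubs: int = 8
    paths_per_hub: float = 20.0
    paths_per_nonhub: float = 1.0
    noise_edges: int = 100
    n_go_terms: int = 150
    n_asd_terms: int = 30
    annotation_enrichment: float = 0.9
    background_annotation: float = 0.05
    regulator_annotation: float = 0.9
    drug_coverage: float = 8 / 21
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_cytokines": self.n_cytokines,
            "n_receptors": self.n_receptors,
            "n_asd_genes": self.n_asd_genes,
            "n_mediators": self.n_mediators,
            "n_other": self.n_other,
            "n_hubs": self.n_hubs,
            "noise_edges": self.noise_edges,
            "n_go_terms": self.n_go_terms,
            "n_asd_terms": self.n_asd_terms,
        }
        for name, value in counts.items():
            if value < 0:
                raise GraphError(f"{name} must be non-negative, got {value}")
        if self.n_hubs > self.n_cytokines:
            raise GraphError(
                f"n_hubs ({self.n_hubs}) cannot exceed n_cytokines "
                f"({self.n_cytokines})"
            )
        if self.n_asd_terms > self.n_go_terms:
            raise GraphError("n_asd_terms cannot exceed n_go_terms")
        for name in (
            "annotation_enrichment",
            "background_annotation",
            "regulator_annotation",
            "drug_coverage",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise GraphError(f"{name} must lie in [0, 1], got {value}")
        if self.paths_per_hub < 0 or self.paths_per_nonhub < 0:
            raise GraphError("path intensities must be non-negative")


@dataclass
class SynthTruth:
    """Ground-truth record of the planted structure."""

    hub_ids: set = field(default_factory=set)
    hub_symbols: set = field(default_factory=set)
    cytokine_symbols: list = field(default_factory=list)
    asd_targeted_genes: set = field(default_factory=set)
    asd_targeted_proteins: set = field(default_factory=set)
    asd_like_terms: set = field(default_factory=set)
    drugged_cytokines: set = field(default_factory=set)
    cytokine_targets: dict = field(default_factory=dict)

    @property
    def targeted_symbols(self) -> set:
        return self.asd_targeted_genes | self.asd_targeted_proteins

    def to_json(self, path: str | Path) -> None:
        data = {
            "hub_ids": sorted(self.hub_ids),
            "hub_symbols": sorted(self.hub_symbols),
            "cytokine_symbols": list(self.cytokine_symbols),
            "asd_targeted_genes": sorted(self.asd_targeted_genes),
            "asd_targeted_proteins": sorted(self.asd_targeted_proteins),
            "asd_like_terms": sorted(self.asd_like_terms),
            "drugged_cytokines": sorted(self.drugged_cytokines),
            "cytokine_targets": {
                c: sorted(t) for c, t in sorted(self.cytokine_targets.items())
            },
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            hub_ids=set(data["hub_ids"]),
            hub_symbols=set(data["hub_symbols"]),
            cytokine_symbols=list(data["cytokine_symbols"]),
            asd_targeted_genes=set(data["asd_targeted_genes"]),
            asd_targeted_proteins=set(data["asd_targeted_proteins"]),
            asd_like_terms=set(data["asd_like_terms"]),
            drugged_cytokines=set(data["drugged_cytokines"]),
            cytokine_targets={
                c: set(t) for c, t in data["cytokine_targets"].items()
            },
        )


def _symbols(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def _add_symbol_pair(graph: KnowledgeGraph, symbol: str, category: str) -> None:
    cats = frozenset({category})
    graph.add_node(Node(f"{symbol}:gene", symbol, "gene", cats))
    graph.add_node(Node(f"{symbol}:protein", symbol, "protein", cats))
    graph.add_edge(f"{symbol}:gene", f"{symbol}:protein", "expression")


def generate_kg(config: SynthConfig) -> tuple[KnowledgeGraph, SynthTruth]:
    """Generate the typed graph with planted cytokine-to-ASD paths.

    Every planted path instantiates one of the five default templates; the
    choice among the feasible templates is uniform per path.  Path counts per
    cytokine are Poisson with mean ``paths_per_hub`` for the ``n_hubs``
    randomly chosen hubs and ``paths_per_nonhub`` otherwise.  Noise edges are
    sampled uniformly among type-valid (source, target, type) triples not
    already present.
    """
    rng = np.random.default_rng(config.seed)
    graph = KnowledgeGraph()
    truth = SynthTruth()

    cytokines = _symbols("CYT", config.n_cytokines)
    receptors = _symbols("REC", config.n_receptors)
    asd = _symbols("ASD", config.n_asd_genes)
    mediators = _symbols("MED", config.n_mediators)
    others = _symbols("OTH", config.n_other)
    for symbol in cytokines:
        _add_symbol_pair(graph, symbol, "cytokine")
    for symbol in receptors:
        _add_symbol_pair(graph, symbol, "cytokine_receptor")
    for symbol in asd:
        _add_symbol_pair(graph, symbol, "asd_associated")
    for symbol in mediators:
        _add_symbol_pair(graph, symbol, "mediator")
    for symbol in others:
        _add_symbol_pair(graph, symbol, "other")

    truth.cytokine_symbols = list(cytokines)
    if config.n_hubs and cytokines:
        hub_idx = rng.choice(len(cytokines), size=config.n_hubs, replace=False)
        hubs = {cytokines[i] for i in hub_idx}
    else:
        hubs = set()
    truth.hub_symbols = set(hubs)
    truth.hub_ids = {f"{s}:protein" for s in hubs}

    feasible = []
    if asd:
        feasible.extend(["T1", "T3"])
        if mediators:
            feasible.extend(["T2", "T4"])
        if receptors:
            feasible.append("T5")

    def plant_path(cyt: str) -> None:
        template = feasible[rng.integers(len(feasible))]
        src = f"{cyt}:protein"
        target = asd[rng.integers(len(asd))]
        if template == "T1":
            reg = PROTEIN_REG_TYPES[rng.integers(3)]
            graph.add_edge(src, f"{target}:protein", reg)
            truth.asd_targeted_proteins.add(target)
        elif template == "T2":
            med = mediators[rng.integers(len(mediators))]
            reg = PROTEIN_REG_TYPES[rng.integers(3)]
            graph.add_edge(src, f"{med}:gene", "expression_regulation")
            graph.add_edge(f"{med}:protein", f"{target}:protein", reg)
            truth.asd_targeted_proteins.add(target)
        elif template == "T3":
            graph.add_edge(src, f"{target}:gene", "expression_regulation")
            truth.asd_targeted_genes.add(target)
        elif template == "T4":
            med = mediators[rng.integers(len(mediators))]
            graph.add_edge(src, f"{med}:protein", "activity_regulation")
            graph.add_edge(
                f"{med}:protein", f"{target}:gene", "expression_regulation"
            )
            truth.asd_targeted_genes.add(target)
        else:  # T5
            rec = receptors[rng.integers(len(receptors))]
            graph.add_edge(src, f"{rec}:protein", "activity_regulation")
            graph.add_edge(
                f"{rec}:protein", f"{target}:gene", "expression_regulation"
            )
            truth.asd_targeted_genes.add(target)
        truth.cytokine_targets.setdefault(cyt, set()).add(target)

    if feasible:
        for cyt in cytokines:
            mean = (
                config.paths_per_hub if cyt in hubs else config.paths_per_nonhub
            )
            for _ in range(int(rng.poisson(mean))):
                plant_path(cyt)

    _plant_noise(graph, config, rng)
    return graph, truth


def _plant_noise(
    graph: KnowledgeGraph, config: SynthConfig, rng: np.random.Generator
) -> None:
    if config.noise_edges == 0:
        return
    genes = sorted(n.id for n in graph.nodes_with(kind="gene"))
    proteins = sorted(n.id for n in graph.nodes_with(kind="protein"))
    all_nodes = genes + proteins
    if not genes or not proteins:
        return
    itypes = sorted(
        {"expression_regulation", "expression", *PROTEIN_REG_TYPES}
    )
    added = 0
    attempts = 0
    max_attempts = config.noise_edges * 50 + 100
    while added < config.noise_edges and attempts < max_attempts:
        attempts += 1
        itype = itypes[rng.integers(len(itypes))]
        if itype == "expression":
            source = genes[rng.integers(len(genes))]
            target = proteins[rng.integers(len(proteins))]
        elif itype == "expression_regulation":
            source = all_nodes[rng.integers(len(all_nodes))]
            target = genes[rng.integers(len(genes))]
        else:
            source = all_nodes[rng.integers(len(all_nodes))]
            target = proteins[rng.integers(len(proteins))]
        if source == target or graph.has_edge(source, target, itype):
            continue
        graph.add_edge(source, target, itype)
        added += 1


def generate_annotations(
    config: SynthConfig, truth: SynthTruth
) -> AnnotationTable:
    """Flat annotations with disease-like terms enriched on planted targets.

    The first ``n_asd_terms`` terms are the disease-like terms (recorded in
    ``truth.asd_like_terms``).  Each annotates every targeted ASD symbol with
    probability ``annotation_enrichment`` and every other symbol with
    ``background_annotation``; a cytokine whose planted targets intersect the
    term's gene set is annotated with probability ``regulator_annotation``
    (regulators participate in the processes they regulate).  The remaining
    terms annotate all symbols at the background rate.  The background is
    every gene symbol in the graph.
    """
    rng = np.random.default_rng([config.seed, 1])
    all_symbols = sorted(
        set(truth.cytokine_symbols)
        | {
            s
            for pool, n in (
                ("REC", config.n_receptors),
                ("ASD", config.n_asd_genes),
                ("MED", config.n_mediators),
                ("OTH", config.n_other),
            )
            for s in _symbols(pool, n)
        }
    )
    background = frozenset(all_symbols)
    cytokine_set = set(truth.cytokine_symbols)
    targeted = sorted(truth.targeted_symbols)
    non_special = [
        s for s in all_symbols
        if s not in cytokine_set and s not in truth.targeted_symbols
    ]

    terms: dict[str, tuple[str, frozenset]] = {}
    for i in range(config.n_go_terms):
        term_id = f"GO:SYN{i + 1:05d}"
        is_asd = i < config.n_asd_terms
        genes: set = set()
        if is_asd:
            truth.asd_like_terms.add(term_id)
            for symbol in targeted:
                if rng.random() < config.annotation_enrichment:
                    genes.add(symbol)
            for symbol in non_special:
                if rng.random() < config.background_annotation:
                    genes.add(symbol)
            for symbol in sorted(cytokine_set):
                prob = (
                    config.regulator_annotation
                    if truth.cytokine_targets.get(symbol, set()) & genes
                    else config.background_annotation
                )
                if rng.random() < prob:
                    genes.add(symbol)
            name = f"synthetic disease-associated process {i + 1}"
        else:
            for symbol in all_symbols:
                if rng.random() < config.background_annotation:
                    genes.add(symbol)
            name = f"synthetic background process {i + 1}"
        if not genes and all_symbols:
            genes.add(all_symbols[int(rng.integers(len(all_symbols)))])
        terms[term_id] = (name, frozenset(genes))
    return AnnotationTable(terms, background)


def generate_drug_table(config: SynthConfig, truth: SynthTruth) -> pd.DataFrame:
    """Drug-target rows for a ``drug_coverage`` fraction of the cytokines.

    Covered cytokines each receive one approved record; the chosen set is
    recorded in ``truth.drugged_cytokines``.
    """
    rng = np.random.default_rng([config.seed, 2])
    cytokines = sorted(truth.cytokine_symbols)
    n_drugged = int(round(config.drug_coverage * len(cytokines)))
    if n_drugged and cytokines:
        idx = sorted(rng.choice(len(cytokines), size=n_drugged, replace=False))
        chosen = [cytokines[i] for i in idx]
    else:
        chosen = []
    truth.drugged_cytokines = set(chosen)
    rows = [
        {
            "target_symbol": symbol,
            "drug_id": f"DSYN{i + 1:04d}",
            "drug_name": f"synthetic-{symbol.lower()}-inhibitor",
            "status": "approved",
        }
        for i, symbol in enumerate(chosen)
    ]
    return pd.DataFrame(
        rows, columns=["target_symbol", "drug_id", "drug_name", "status"]
    )


def generate_all(
    config: SynthConfig,
) -> tuple[KnowledgeGraph, SynthTruth, AnnotationTable, pd.DataFrame]:
    graph, truth = generate_kg(config)
    annotations = generate_annotations(config, truth)
    drug_table = generate_drug_table(config, truth)
    return graph, truth, annotations, drug_table


def write_fixture_bundle(
    directory: str | Path,
    graph: KnowledgeGraph,
    truth: SynthTruth,
    annotations: AnnotationTable,
    drug_table: pd.DataFrame,
    config: SynthConfig,
) -> None:
    """Write nodes.tsv, edges.tsv, annotations.gmt, drugs.tsv, truth.json and
    a config echo into ``directory`` (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_nodes_tsv(graph, directory / "nodes.tsv")
    write_edges_tsv(graph, directory / "edges.tsv")
    annotations.write_gmt(directory / "annotations.gmt")
    drug_table.to_csv(directory / "drugs.tsv", sep="\t", index=False)
    truth.to_json(directory / "truth.json")
    with open(directory / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def load_fixture_bundle(directory: str | Path):
    """Reload a bundle: (graph, truth, annotations, drug table)."""
    directory = Path(directory)
    nodes = read_nodes(directory / "nodes.tsv")
    graph = read_edges(directory / "edges.tsv", nodes)
    truth = SynthTruth.from_json(directory / "truth.json")
    annotations = read_annotations(
        directory / "annotations.gmt",
        background=[n.symbol for n in nodes if n.kind == "gene"],
    )
    drug_table = pd.read_csv(directory / "drugs.tsv", sep="\t")
    return graph, truth, annotations, drug_table
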