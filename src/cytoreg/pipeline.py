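"""End-to-end pipeline: reconstruction, enrichment, prioritization,
drug cross-reference, and the machine-readable run report.

``run_pipeline`` executes the three analysis stages in order on file inputs
described by a :class:`PipelineConfig` and writes every stage artifact plus
``report.json`` into the output directory.  Re-running on identical inputs
produces byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .drugs import load_drug_table, write_xref_tsv, xref_candidates, xref_counts
from .enrichment import enrich_gene_set, write_enrichment_tsv
from .graph import (
    GeneSet,
    GraphError,
    read_annotations,
    read_edges,
    read_nodes,
    write_edges_tsv,
    write_nodes_tsv,
    _tsv_rows,
)
from .prioritize import (
    cytokine_centralities,
    process_representation,
    rank_and_select,
)
from .templates import parse_templates, reconstruct, summarize_network

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """File inputs and thresholds for one pipeline run."""

    nodes: Path
    edges: Path
    annotations: Path
    drugs: Path
    outdir: Path
    templates: Path | None = None
    blacklist: Path | None = None
    alpha_enrichment: float = 0.05
    alpha_process: float = 0.05
    k_degree: int = 15
    k_betweenness: int = 15
    process_top_k: int | None = None

    def __post_init__(self) -> None:
        for name in ("nodes", "edges", "annotations", "drugs", "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        for name in ("templates", "blacklist"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        for name in ("alpha_enrichment", "alpha_process"):
            alpha = getattr(self, name)
            if not 0.0 < alpha < 1.0:
                raise GraphError(f"{name} must lie in (0, 1), got {alpha}")
        if self.k_degree <= 0 or self.k_betweenness <= 0:
            raise GraphError("top-list sizes must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise GraphError(f"{path}: unknown config keys {sorted(unknown)}")
        base = path.parent
        for key in ("nodes", "edges", "annotations", "drugs", "outdir",
                    "templates", "blacklist"):
            if data.get(key) is not None:
                data[key] = base / data[key]
        return cls(**data)

    def echo(self) -> dict[str, Any]:
        data = dataclasses.asdict(self)
        return {
            k: (str(v) if isinstance(v, Path) else v) for k, v in data.items()
        }


@dataclass
class RunReport:
    config: dict[str, Any]
    network_summary: dict[str, Any]
    enrichment: dict[str, int]
    ranking: dict[str, int]
    xref: dict[str, int]
    version: str = __version__
    schema_version: int = REPORT_SCHEMA_VERSION
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _read_blacklist(path: Path) -> set[tuple[str, str, str]]:
    triples = set()
    rows = _tsv_rows(path)
    for lineno, row in rows:
        if row[:3] == ["source", "target", "interaction_type"]:
            continue  # optional header
        if len(row) < 3:
            raise GraphError(f"{path}:{lineno}: blacklist rows need 3 columns")
        triples.add((row[0], row[1], row[2]))
    return triples


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute reconstruction -> enrichment -> prioritization -> xref.

    Stage artifacts written to ``config.outdir``: consolidated edge/node
    tables, ``summary.json``, ``enrichment.tsv``, ``ranking.tsv``,
    ``xref.tsv`` and ``report.json``.  Degenerate inputs (e.g. a graph with
    no template matches) complete with zero counts rather than failing.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: reconstruction -----------------------------------------
    try:
        nodes = read_nodes(config.nodes)
        graph = read_edges(config.edges, nodes)
        templates = (
            parse_templates(config.templates)
            if config.templates is not None
            else None
        )
        blacklist = (
            _read_blacklist(config.blacklist)
            if config.blacklist is not None
            else ()
        )
        net, matches = reconstruct(graph, templates, blacklist)
    except Exception as exc:
        raise GraphError(f"reconstruction: {exc}") from exc
    summary = summarize_network(net)
    write_nodes_tsv(net.graph, outdir / "consolidated.nodes.tsv")
    write_edges_tsv(net.graph, outdir / "consolidated.tsv")
    summary.write_json(outdir / "summary.json")
    log.info(
        "reconstruction: %d matches over %d templates; %d nodes, %d edges",
        sum(len(m) for m in matches.values()),
        len(matches),
        summary.n_nodes,
        summary.n_edges,
    )

    # --- stage 2a: GO over-representation of regulated ASD genes ----------
    try:
        annotations = read_annotations(
            config.annotations,
            background=[n.symbol for n in nodes if n.kind == "gene"],
        )
        # annotation is symbol-level, so regulated proteins map to their genes
        regulated_symbols = frozenset(
            net.graph.node(nid).symbol
            for nid, roles in net.roles.items()
            if "asd_target" in roles
        )
        if regulated_symbols:
            enrichment = enrich_gene_set(
                GeneSet("cytokine_regulated_asd_genes", regulated_symbols),
                annotations,
                alpha=config.alpha_enrichment,
            )
        else:
            log.warning("enrichment: no regulated ASD genes; stage skipped")
            enrichment = []
    except Exception as exc:
        raise GraphError(f"enrichment: {exc}") from exc
    write_enrichment_tsv(enrichment, outdir / "enrichment.tsv")
    asd_terms = {r.term_id for r in enrichment if r.significant}

    # --- stage 2b: prioritization -----------------------------------------
    try:
        scores = cytokine_centralities(net)
        cytokine_symbols = frozenset(scores.degree)
        if cytokine_symbols:
            reps = process_representation(
                GeneSet("regulator_cytokines", cytokine_symbols),
                asd_terms,
                annotations,
                alpha=config.alpha_process,
            )
            ranking = rank_and_select(
                scores,
                reps,
                k_degree=config.k_degree,
                k_betweenness=config.k_betweenness,
                process_top_k=config.process_top_k,
            )
        else:
            log.warning("prioritization: no regulator cytokines; stage skipped")
            ranking = rank_and_select(scores, [], 1, 1)
    except Exception as exc:
        raise GraphError(f"prioritization: {exc}") from exc
    ranking.write_tsv(outdir / "ranking.tsv")

    # --- stage 3: drug-target cross-reference -----------------------------
    try:
        table = load_drug_table(config.drugs)
        if ranking.candidates:
            results = xref_candidates(
                GeneSet("candidates", frozenset(ranking.candidates)), table
            )
        else:
            results = []
    except Exception as exc:
        raise GraphError(f"xref: {exc}") from exc
    write_xref_tsv(results, outdir / "xref.tsv")
    counts = xref_counts(results)

    report = RunReport(
        config=config.echo(),
        network_summary=summary.to_dict(),
        enrichment={
            "n_terms_tested": len(enrichment),
            "n_significant": len(asd_terms),
        },
        ranking={
            "n_cytokines": len(scores.degree),
            "top_degree_size": len(ranking.top_degree),
            "top_betweenness_size": len(ranking.top_betweenness),
            "process_list_size": len(ranking.process_list),
            "candidate_count": len(ranking.candidates),
            "consensus_count": len(ranking.consensus),
        },
        xref={"n_candidates_xrefed": len(results), **counts},
    )
    report.write_json(outdir / "report.json")
    return report
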