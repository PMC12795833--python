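"""Cytokine prioritization: centrality metrics, process representation,
top-list union and consensus.

Three independent rankings are produced for the regulator cytokines of a
consolidated network:

* **degree** — typed multigraph degree (incident edges, both directions);
  a cytokine regulating a target through two interaction types counts both.
* **betweenness** — unnormalized Freeman betweenness on the undirected
  simple projection of the network (unit weights, unordered pairs,
  endpoints excluded), via Brandes' algorithm.
* **process representation** — for each cytokine, a term-space
  hypergeometric test of its annotation overlap with the disease-associated
  biological processes: among the N terms of the annotation table, K are
  disease-associated and the cytokine is annotated to n of all terms, k of
  them disease-associated; significance is assessed at FDR < alpha across
  the cytokines tested.

The candidate set is the union of the three top lists and the consensus set
their intersection.  Ties break by descending score then ascending symbol,
so every output is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .enrichment import ContingencyCounts, bh_fdr, bonferroni_adjust, hypergeom_tail
from .graph import AnnotationTable, GeneSet
from .templates import ConsolidatedNetwork

__all__ = [
    "CentralityScores",
    "ProcessRepresentation",
    "RankedCytokine",
    "CytokineRanking",
    "degree_centrality",
    "betweenness_centrality",
    "process_representation",
    "rank_and_select",
    "cytokine_centralities",
]

log = logging.getLogger(__name__)


@dataclass
class CentralityScores:
    """Per-key degree and betweenness (keys are node ids or symbols)."""

    degree: dict[str, int] = field(default_factory=dict)
    betweenness: dict[str, float] = field(default_factory=dict)


def degree_centrality(
    net: ConsolidatedNetwork, node_ids: Iterable[str]
) -> CentralityScores:
    """Typed degree of each requested node; unknown ids raise."""
    scores = CentralityScores()
    for node_id in node_ids:
        scores.degree[node_id] = net.graph.degree(node_id)
    return scores


def betweenness_centrality(net: ConsolidatedNetwork) -> CentralityScores:
    """Unnormalized betweenness of every node, undirected simple projection.

    Disconnected pairs contribute nothing; endpoint nodes of a path receive
    zero.  Equivalent to summing sigma_st(v)/sigma_st over unordered pairs
    {s, t} with s != v != t.
    """
    projection = net.graph.undirected_projection()
    bc = nx.betweenness_centrality(projection, normalized=False)
    return CentralityScores(betweenness=dict(bc))


def cytokine_centralities(net: ConsolidatedNetwork) -> CentralityScores:
    """Degree and betweenness per regulator-cytokine *symbol*.

    Scores of the (rare) case of several regulator nodes sharing a symbol
    are summed, so each cytokine appears once in the ranking.
    """
    regulator_ids = sorted(
        nid for nid, roles in net.roles.items() if "source_cytokine" in roles
    )
    deg = degree_centrality(net, regulator_ids).degree
    betw = betweenness_centrality(net).betweenness
    scores = CentralityScores()
    for nid in regulator_ids:
        symbol = net.graph.node(nid).symbol
        scores.degree[symbol] = scores.degree.get(symbol, 0) + deg[nid]
        scores.betweenness[symbol] = scores.betweenness.get(symbol, 0.0) + betw.get(
            nid, 0.0
        )
    return scores


@dataclass
class ProcessRepresentation:
    """One cytokine's overlap with the disease-associated process terms."""

    symbol: str
    n_asd_processes: int
    counts: ContingencyCounts
    p_value: float
    p_bonferroni: float
    fdr: float
    significant: bool


def process_representation(
    cytokines: GeneSet,
    asd_terms: Iterable[str],
    annotations: AnnotationTable,
    alpha: float = 0.05,
) -> list[ProcessRepresentation]:
    """Term-space over-representation of each cytokine in the disease terms.

    Cytokine symbols absent from the annotation background are dropped with
    a warning.  A cytokine annotated to no terms at all is kept with k = 0,
    p = 1.  Corrections (Bonferroni and BH) run across the cytokines tested.
    """
    asd_terms = set(asd_terms)
    unknown = asd_terms - set(annotations.terms)
    if unknown:
        raise ValueError(
            f"disease terms not in the annotation table: {sorted(unknown)[:5]}"
        )
    N = annotations.n_terms
    K = len(asd_terms)
    symbols = []
    for symbol in sorted(cytokines.symbols):
        if symbol not in annotations.background:
            log.warning(
                "process_representation: %s absent from annotation background; "
                "dropped",
                symbol,
            )
            continue
        symbols.append(symbol)
    rows = []
    p_values = []
    for symbol in symbols:
        annotated = annotations.terms_annotating(symbol)
        n = len(annotated)
        k = len(annotated & asd_terms)
        counts = ContingencyCounts(N=N, K=K, n=n, k=k)
        p_values.append(hypergeom_tail(counts))
        rows.append((symbol, k, counts))
    bonf = bonferroni_adjust(p_values)
    fdr = bh_fdr(p_values)
    return [
        ProcessRepresentation(
            symbol=symbol,
            n_asd_processes=k,
            counts=counts,
            p_value=p,
            p_bonferroni=pb,
            fdr=q,
            significant=q < alpha,
        )
        for (symbol, k, counts), p, pb, q in zip(rows, p_values, bonf, fdr)
    ]


@dataclass
class RankedCytokine:
    symbol: str
    degree: int
    degree_rank: int
    betweenness: float
    betweenness_rank: int
    n_asd_processes: int
    p_value: float
    p_bonferroni: float
    fdr: float
    process_rank: int
    in_top_degree: bool
    in_top_betweenness: bool
    in_process_list: bool
    candidate: bool
    consensus: bool


@dataclass
class CytokineRanking:
    rows: list[RankedCytokine]
    top_degree: set
    top_betweenness: set
    process_list: set
    candidates: set
    consensus: set

    def write_tsv(self, path) -> None:
        header = (
            "symbol\tdegree\tdegree_rank\tbetweenness\tbetweenness_rank\t"
            "n_asd_processes\tp_value\tp_bonferroni\tfdr\tprocess_rank\t"
            "in_top_degree\tin_top_betweenness\tin_process_list\tcandidate\t"
            "consensus\n"
        )
        with open(Path(path), "w", encoding="utf-8") as fh:
            fh.write(header)
            for r in self.rows:
                fh.write(
                    f"{r.symbol}\t{r.degree}\t{r.degree_rank}\t"
                    f"{r.betweenness:.6g}\t{r.betweenness_rank}\t"
                    f"{r.n_asd_processes}\t{r.p_value:.6g}\t"
                    f"{r.p_bonferroni:.6g}\t{r.fdr:.6g}\t{r.process_rank}\t"
                    f"{str(r.in_top_degree).lower()}\t"
                    f"{str(r.in_top_betweenness).lower()}\t"
                    f"{str(r.in_process_list).lower()}\t"
                    f"{str(r.candidate).lower()}\t{str(r.consensus).lower()}\n"
                )


def _dense_ranks(items: Sequence[str], score: Mapping[str, float]) -> dict[str, int]:
    """1-based dense ranks on descending score; tied scores share a rank."""
    ordered = sorted(items, key=lambda s: (-score[s], s))
    ranks: dict[str, int] = {}
    rank = 0
    previous = None
    for symbol in ordered:
        if previous is None or score[symbol] != previous:
            rank += 1
            previous = score[symbol]
        ranks[symbol] = rank
    return ranks


def _top_k(items: Sequence[str], score: Mapping[str, float], k: int) -> set:
    ordered = sorted(items, key=lambda s: (-score[s], s))
    return set(ordered[:k])


def rank_and_select(
    scores: CentralityScores,
    reps: Sequence[ProcessRepresentation],
    k_degree: int = 15,
    k_betweenness: int = 15,
    process_top_k: int | None = None,
) -> CytokineRanking:
    """Build the per-metric top lists, their union and their intersection.

    Top lists take the ``k`` highest-scoring cytokines per centrality metric
    (k capped at the cytokine count, with a warning).  The process list
    contains every cytokine whose representation test is significant, unless
    ``process_top_k`` overrides it with a fixed-size list ordered by FDR then
    overlap count.  Candidates are the union of the three lists, the
    consensus their intersection.
    """
    symbols = sorted(scores.degree)
    if set(scores.betweenness) != set(symbols):
        missing = set(symbols) ^ set(scores.betweenness)
        raise ValueError(f"degree/betweenness cover different cytokines: {missing}")
    rep_by_symbol = {r.symbol: r for r in reps}
    n = len(symbols)
    if k_degree > n or k_betweenness > n:
        log.warning(
            "rank_and_select: top-list size capped at the %d cytokines scored", n
        )
        k_degree = min(k_degree, n)
        k_betweenness = min(k_betweenness, n)

    degree_ranks = _dense_ranks(symbols, scores.degree)
    betw_ranks = _dense_ranks(symbols, scores.betweenness)
    top_degree = _top_k(symbols, scores.degree, k_degree)
    top_betweenness = _top_k(symbols, scores.betweenness, k_betweenness)

    # process ranking: ascending fdr, then descending overlap, then symbol
    def process_key(s: str):
        r = rep_by_symbol.get(s)
        if r is None:
            return (1.0, 0)
        return (r.fdr, -r.n_asd_processes)

    proc_ordered = sorted(symbols, key=lambda s: (*process_key(s), s))
    proc_score = {s: (-process_key(s)[0], -process_key(s)[1]) for s in symbols}
    proc_ranks: dict[str, int] = {}
    rank = 0
    previous = None
    for symbol in proc_ordered:
        if previous is None or proc_score[symbol] != previous:
            rank += 1
            previous = proc_score[symbol]
        proc_ranks[symbol] = rank
    if process_top_k is not None:
        process_list = set(proc_ordered[: min(process_top_k, n)])
    else:
        process_list = {
            s for s in symbols
            if s in rep_by_symbol and rep_by_symbol[s].significant
        }

    candidates = top_degree | top_betweenness | process_list
    consensus = top_degree & top_betweenness & process_list

    rows = []
    for symbol in symbols:
        rep = rep_by_symbol.get(symbol)
        rows.append(
            RankedCytokine(
                symbol=symbol,
                degree=scores.degree[symbol],
                degree_rank=degree_ranks[symbol],
                betweenness=scores.betweenness[symbol],
                betweenness_rank=betw_ranks[symbol],
                n_asd_processes=rep.n_asd_processes if rep else 0,
                p_value=rep.p_value if rep else 1.0,
                p_bonferroni=rep.p_bonferroni if rep else 1.0,
                fdr=rep.fdr if rep else 1.0,
                process_rank=proc_ranks[symbol],
                in_top_degree=symbol in top_degree,
                in_top_betweenness=symbol in top_betweenness,
                in_process_list=symbol in process_list,
                candidate=symbol in candidates,
                consensus=symbol in consensus,
            )
        )
    rows.sort(key=lambda r: (r.degree_rank + r.betweenness_rank + r.process_rank, r.symbol))
    return CytokineRanking(
        rows=rows,
        top_degree=top_degree,
        top_betweenness=top_betweenness,
        process_list=process_list,
        candidates=candidates,
        consensus=consensus,
    )
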