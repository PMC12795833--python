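"""Over-representation statistics: exact hypergeometric test with
Bonferroni and Benjamini-Hochberg adjustment.

The enrichment question asked of every annotation term is the classic ORA
null: given a background of ``N`` genes of which ``K`` carry the term, does a
query set of ``n`` genes contain ``k`` or more term genes more often than
chance?  The upper-tail probability ``P(X >= k)`` for
``X ~ Hypergeometric(N, K, n)`` is evaluated with exact integer
combinatorics (arbitrary-precision binomials), so results are correct to
floating-point rounding at any count size the pipeline encounters.

Both Bonferroni and Benjamini-Hochberg (step-up FDR) adjusted values are
reported for every analysis; term selection defaults to FDR < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np

from .graph import AnnotationTable, GeneSet

__all__ = [
    "ContingencyCounts",
    "EnrichmentResult",
    "hypergeom_tail",
    "bonferroni_adjust",
    "bh_fdr",
    "enrich_gene_set",
    "write_enrichment_tsv",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyCounts:
    """Hypergeometric counts: background N, term size K, query size n,
    overlap k."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid counts: K, n must lie in [0, N]: {self}")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"invalid overlap k: {self}")


def hypergeom_tail(counts: ContingencyCounts) -> float:
    """Exact upper-tail probability P(X >= k), X ~ Hypergeom(N, K, n).

    Computed as a rational number and converted to float at the end, so the
    result is the correctly rounded double of the exact probability.
    """
    N, K, n, k = counts.N, counts.K, counts.n, counts.k
    if k == 0:
        return 1.0
    numerator = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return float(Fraction(numerator, comb(N, n)))


def bonferroni_adjust(p_values: Sequence[float]) -> list[float]:
    """Bonferroni family-wise correction: p * m, clamped at 1."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending ordering, clamped
    at 1.  Adjusted values dominate the raw ones elementwise and are monotone
    non-decreasing along the sorted order.
    """
    m = len(p_values)
    if m == 0:
        return []
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    counts: ContingencyCounts
    p_value: float
    p_bonferroni: float
    fdr: float
    significant: bool


def enrich_gene_set(
    query: GeneSet,
    annotations: AnnotationTable,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in every term.

    Query symbols outside the annotation background are dropped with a
    warning; an empty effective query is an error.  One result is produced
    per term (terms have K >= 1 by construction); corrections run over all
    tested terms and ``significant`` applies FDR < alpha.  Results are sorted
    by p-value, ties broken by term id.
    """
    background = annotations.background
    effective = query.symbols & background
    dropped = query.symbols - background
    if dropped:
        log.warning(
            "enrich_gene_set: dropped %d query symbols outside the background "
            "(e.g. %s)",
            len(dropped),
            sorted(dropped)[:3],
        )
    if not effective:
        raise ValueError(
            f"query {query.name!r} has no symbols in the annotation background"
        )
    N = len(background)
    n = len(effective)
    term_ids = sorted(annotations.terms)
    results = []
    p_values = []
    for term_id in term_ids:
        term_genes = annotations.genes(term_id)
        counts = ContingencyCounts(
            N=N, K=len(term_genes), n=n, k=len(effective & term_genes)
        )
        p_values.append(hypergeom_tail(counts))
        results.append((term_id, counts))
    bonf = bonferroni_adjust(p_values)
    fdr = bh_fdr(p_values)
    out = [
        EnrichmentResult(
            term_id=term_id,
            term_name=annotations.term_name(term_id),
            counts=counts,
            p_value=p,
            p_bonferroni=pb,
            fdr=q,
            significant=q < alpha,
        )
        for (term_id, counts), p, pb, q in zip(results, p_values, bonf, fdr)
    ]
    out.sort(key=lambda r: (r.p_value, r.term_id))
    return out


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write(
            "term_id\tterm_name\tk\tK\tn\tN\tp_value\tp_bonferroni\tfdr\t"
            "significant\n"
        )
        for r in results:
            c = r.counts
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{c.k}\t{c.K}\t{c.n}\t{c.N}\t"
                f"{r.p_value:.6g}\t{r.p_bonferroni:.6g}\t{r.fdr:.6g}\t"
                f"{str(r.significant).lower()}\n"
            )
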