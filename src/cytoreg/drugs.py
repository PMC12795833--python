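"""Drug-target cross-referencing of prioritized cytokines.

Candidate cytokines are matched against a local drug-target table (a TSV
snapshot standing in for curated drug databases) by exact, case-normalized
gene symbol.  Each candidate is classified as an approved-drug target, an
investigational-only target, or a cytokine with no known drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .graph import GeneSet, GraphError, _tsv_rows

__all__ = [
    "STATUSES",
    "DrugTargetRecord",
    "XrefResult",
    "load_drug_table",
    "xref_candidates",
    "write_xref_tsv",
]

STATUSES = frozenset({"approved", "investigational"})


@dataclass(frozen=True)
class DrugTargetRecord:
    target_symbol: str
    drug_id: str
    drug_name: str
    status: str

    def __post_init__(self) -> None:
        if not self.target_symbol:
            raise GraphError("drug record with empty target symbol")
        if self.status not in STATUSES:
            raise GraphError(f"unknown drug status {self.status!r}")
        object.__setattr__(self, "target_symbol", self.target_symbol.upper())


@dataclass
class XrefResult:
    symbol: str
    records: list[DrugTargetRecord]
    classification: str  # approved_target | investigational_target | no_known_drug


def load_drug_table(path: str | Path) -> list[DrugTargetRecord]:
    """Read a drug-target TSV (target_symbol, drug_id, drug_name, status)."""
    rows = _tsv_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise GraphError(f"{path}: empty drug table (header required)") from None
    required = ["target_symbol", "drug_id", "drug_name", "status"]
    if [h.strip() for h in header[:4]] != required:
        raise GraphError(f"{path}: drug table header must be {required}")
    records = []
    for lineno, row in rows:
        if len(row) < 4:
            raise GraphError(f"{path}:{lineno}: expected 4 columns")
        try:
            records.append(DrugTargetRecord(row[0], row[1], row[2], row[3]))
        except GraphError as exc:
            raise GraphError(f"{path}:{lineno}: {exc}") from None
    return records


def xref_candidates(
    candidates: GeneSet, table: Iterable[DrugTargetRecord]
) -> list[XrefResult]:
    """Classify every candidate cytokine by its drug-target records.

    ``approved_target`` requires at least one approved record;
    ``investigational_target`` means only investigational records matched.
    Output is ordered by symbol.
    """
    if not candidates.symbols:
        raise ValueError("empty candidate set")
    by_symbol: dict[str, list[DrugTargetRecord]] = {}
    for record in table:
        by_symbol.setdefault(record.target_symbol, []).append(record)
    results = []
    for symbol in sorted(candidates.symbols):
        records = sorted(
            by_symbol.get(symbol, []), key=lambda r: (r.drug_id, r.status)
        )
        if any(r.status == "approved" for r in records):
            classification = "approved_target"
        elif records:
            classification = "investigational_target"
        else:
            classification = "no_known_drug"
        results.append(XrefResult(symbol, records, classification))
    return results


def xref_counts(results: Sequence[XrefResult]) -> dict[str, int]:
    counts = {
        "approved_target": 0,
        "investigational_target": 0,
        "no_known_drug": 0,
    }
    for result in results:
        counts[result.classification] += 1
    return counts


def write_xref_tsv(results: Sequence[XrefResult], path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write(
            "symbol\tclassification\tn_approved_drugs\t"
            "n_investigational_drugs\tdrug_ids\n"
        )
        for r in results:
            n_app = sum(1 for rec in r.records if rec.status == "approved")
            n_inv = sum(
                1 for rec in r.records if rec.status == "investigational"
            )
            ids = ";".join(sorted({rec.drug_id for rec in r.records}))
            fh.write(
                f"{r.symbol}\t{r.classification}\t{n_app}\t{n_inv}\t{ids}\n"
            )
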