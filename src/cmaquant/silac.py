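"""SILAC quantification-table parsing, filtering, and regulation calling.

The lysosome-proteome comparison quantifies each protein as a linear
treatment/control abundance ratio (heavy/light SILAC channels) with a
replicate-derived p-value, a peptide count, and a search-engine FDR
confidence tier.  Three filters retain quantifiable, regulated proteins:
high confidence, more than one peptide, p <= 0.05, and a two-fold change
in either direction (ratio >= 2 or <= 0.5, boundaries inclusive).
Retained proteins are called up- or downregulated by which side of the
fold threshold they fall on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CONFIDENCE_LEVELS = ("high", "medium", "low")

#: Default column names, after a Proteome Discoverer protein export.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "protein_id": "Accession",
    "gene_symbol": "Gene Symbol",
    "ratio": "Abundance Ratio",
    "p_value": "Abundance Ratio P-Value",
    "peptide_count": "Number of Peptides",
    "confidence": "Protein FDR Confidence",
}


@dataclass(frozen=True)
class QuantRecord:
    """One protein's SILAC measurement for one treatment comparison."""

    protein_id: str
    gene_symbol: str
    ratio: float  # treatment/control, linear scale, > 0
    p_value: float
    peptide_count: int
    confidence: str  # high | medium | low
    treatment: str  # e.g. "PA" or "SA"

    def __post_init__(self):
        if not self.ratio > 0:
            raise ValueError(f"ratio must be positive, got {self.ratio}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")
        if self.peptide_count < 1:
            raise ValueError(f"peptide_count must be >= 1: {self.peptide_count}")
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(f"unknown confidence tier: {self.confidence!r}")


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds for the three-filter cascade, boundaries inclusive.

    ``min_peptides=2`` encodes "more than 1 peptide"; ``max_p`` is
    inclusive (p <= 0.05 passes); ``fold_threshold`` applies two-sided
    on the linear ratio (>= 2 or <= 1/2).
    """

    min_peptides: int = 2
    max_p: float = 0.05
    fold_threshold: float = 2.0
    require_confidence: frozenset = frozenset({"high"})

    def __post_init__(self):
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if not 0 < self.max_p < 1:
            raise ValueError("max_p must lie in (0, 1)")


@dataclass(frozen=True)
class RegulationCall:
    protein_id: str
    call: str  # up | down | unchanged
    treatment: str = ""


@dataclass
class ReadResult:
    """Parsed records plus quality-control tallies from table reading."""

    records: list
    n_rows: int = 0
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)


def read_quant_table(
    path,
    column_map: Mapping[str, str] | None = None,
    treatment: str = "",
    sep: str | None = None,
) -> ReadResult:
    """Read a delimited protein-quantification export into records.

    Rows with unparseable or missing ratio / p-value are dropped and
    counted (never treated as passing).  ``sep=None`` infers TSV vs CSV
    from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"empty table: {path}")
    missing = [col for col in colmap.values() if col not in df.columns]
    if missing:
        raise KeyError(f"mapped columns absent from {path.name}: {missing}")

    result = ReadResult(records=[], n_rows=len(df))
    for _, row in df.iterrows():
        reason = None
        try:
            ratio = float(row[colmap["ratio"]])
            p_value = float(row[colmap["p_value"]])
        except (TypeError, ValueError):
            reason = "unparseable ratio/p"
        else:
            if pd.isna(ratio) or pd.isna(p_value):
                reason = "missing ratio/p"
        if reason is None:
            try:
                record = QuantRecord(
                    protein_id=str(row[colmap["protein_id"]]),
                    gene_symbol=str(row[colmap["gene_symbol"]]),
                    ratio=ratio,
                    p_value=p_value,
                    peptide_count=int(row[colmap["peptide_count"]]),
                    confidence=str(row[colmap["confidence"]]).strip().lower(),
                    treatment=treatment,
                )
            except (TypeError, ValueError) as exc:
                reason = f"invariant violation ({exc})"
            else:
                result.records.append(record)
                continue
        result.n_dropped += 1
        result.drop_reasons[reason] = result.drop_reasons.get(reason, 0) + 1
    if result.n_dropped:
        logger.info(
            "read_quant_table: dropped %d/%d rows (%s)",
            result.n_dropped,
            result.n_rows,
            result.drop_reasons,
        )
    return result


def passes_filters(record: QuantRecord, criteria: FilterCriteria) -> bool:
    return (
        record.confidence in criteria.require_confidence
        and record.peptide_count >= criteria.min_peptides
        and record.p_value <= criteria.max_p
        and (
            record.ratio >= criteria.fold_threshold
            or record.ratio <= 1.0 / criteria.fold_threshold
        )
    )


def apply_filters(
    records: Sequence[QuantRecord], criteria: FilterCriteria | None = None
) -> list[QuantRecord]:
    """Keep records passing all three filters; input order preserved."""
    criteria = criteria or FilterCriteria()
    kept = [r for r in records if passes_filters(r, criteria)]
    logger.info(
        "apply_filters: kept %d/%d records (criteria=%s)",
        len(kept),
        len(records),
        criteria,
    )
    return kept


def call_regulation(
    record: QuantRecord, criteria: FilterCriteria | None = None
) -> RegulationCall:
    """Call up/down/unchanged from the linear ratio, boundaries inclusive."""
    criteria = criteria or FilterCriteria()
    if record.ratio >= criteria.fold_threshold:
        call = "up"
    elif record.ratio <= 1.0 / criteria.fold_threshold:
        call = "down"
    else:
        call = "unchanged"
    return RegulationCall(
        protein_id=record.protein_id, call=call, treatment=record.treatment
    )


def call_all(
    records: Sequence[QuantRecord], criteria: FilterCriteria | None = None
) -> list[RegulationCall]:
    criteria = criteria or FilterCriteria()
    return [call_regulation(r, criteria) for r in records]


def summarize_regulation(calls: Sequence[RegulationCall]) -> dict:
    """Counts and percentages of up/down calls (unchanged excluded from
    the percentage base, matching pie-chart reporting)."""
    if not calls:
        raise ValueError("no regulation calls to summarize")
    n_up = sum(1 for c in calls if c.call == "up")
    n_down = sum(1 for c in calls if c.call == "down")
    n_unchanged = len(calls) - n_up - n_down
    out = {
        "n_total": len(calls),
        "n_up": n_up,
        "n_down": n_down,
        "n_unchanged": n_unchanged,
    }
    regulated = n_up + n_down
    if regulated:
        out["pct_up"] = round(100 * n_up / regulated)
        out["pct_down"] = round(100 * n_down / regulated)
    else:
        out["pct_up"] = out["pct_down"] = None
    return out


def records_to_table(records: Sequence[QuantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            DEFAULT_COLUMN_MAP["protein_id"]: [r.protein_id for r in records],
            DEFAULT_COLUMN_MAP["gene_symbol"]: [r.gene_symbol for r in records],
            DEFAULT_COLUMN_MAP["ratio"]: [r.ratio for r in records],
            DEFAULT_COLUMN_MAP["p_value"]: [r.p_value for r in records],
            DEFAULT_COLUMN_MAP["peptide_count"]: [r.peptide_count for r in records],
            DEFAULT_COLUMN_MAP["confidence"]: [r.confidence for r in records],
            "Treatment": [r.treatment for r in records],
        }
    )


def write_filtered_table(records: Sequence[QuantRecord], path) -> None:
    records_to_table(records).to_csv(path, sep="\t", index=False)


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def export_string_list(
    records: Sequence[QuantRecord],
    calls: Sequence[RegulationCall],
    direction: str,
    path,
) -> int:
    """Write a single-column gene-symbol list (one direction) suitable
    for pasting into the STRING web interface; returns the count."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    call_by_id = {c.protein_id: c.call for c in calls}
    symbols = [
        r.gene_symbol
        for r in records
        if call_by_id.get(r.protein_id) == direction and r.gene_symbol
    ]
    Path(path).write_text("".join(s + "\n" for s in symbols))
    return len(symbols)
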