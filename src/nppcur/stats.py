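"""Bookkeeping arithmetic: retention rate, database totals, taxonomy breadth."""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import AnnotationTable, LINEAGE_RANKS
from .purge import PipelineCounts


@dataclass(frozen=True)
class TaxonomySummary:
    """Distinct non-empty names per rank across an annotation table."""

    phyla: int = 0
    classes: int = 0
    orders: int = 0
    families: int = 0
    genera: int = 0
    species: int = 0


_RANK_FIELD = {
    "phylum": "phyla",
    "class": "classes",
    "order": "orders",
    "family": "families",
    "genus": "genera",
    "species": "species",
}


def retention_rate(n_final: int, n_input: int) -> float:
    """Percentage of input sequences retained, truncated to 2 decimals.

    Truncation (not rounding) is the reported convention: the quotient is
    floored at the second decimal, so 719/13778 prints as 5.21.
    Implemented in integer arithmetic to avoid float floor surprises.
    """
    if n_input <= 0:
        raise ValueError("n_input must be positive")
    if not 0 <= n_final <= n_input:
        raise ValueError("need 0 <= n_final <= n_input")
    return (10000 * n_final // n_input) / 100.0


def summarize_pipeline(counts: PipelineCounts) -> dict:
    """Render the stage table; validates the additions arithmetic."""
    if any(v < 0 for v in counts.additions.values()):
        raise ValueError("negative addition count")
    expected = counts.n_convertase + sum(counts.additions.values())
    if counts.n_final != expected:
        raise ValueError(
            f"n_final {counts.n_final} inconsistent with stage counts ({expected})"
        )
    return {
        "n_input": counts.n_input,
        "n_structural": counts.n_structural,
        "n_dibasic": counts.n_dibasic,
        "n_convertase": counts.n_convertase,
        "additions": dict(counts.additions),
        "n_final": counts.n_final,
    }


def summarize_taxonomy(table: AnnotationTable) -> TaxonomySummary:
    """Count distinct non-empty names at each rank; empty names excluded."""
    values = {}
    for rank in LINEAGE_RANKS:
        if len(table) and rank in table.frame.columns:
            names = {v for v in table.frame[rank].astype(str) if v.strip()}
        else:
            names = set()
        values[_RANK_FIELD[rank]] = len(names)
    return TaxonomySummary(**values)
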