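"""Shared record model and FASTA / annotation-table input-output.

A :class:`PrecursorRecord` is the unit of analysis everywhere in the
package: one candidate neuropeptide precursor with its amino-acid
sequence, optional coding sequence, taxonomy lineage and any family tag
carried over from source metadata.

Coordinates are 0-based, half-open throughout the package; reports print
positions 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: non-standard one-letter codes collapsed to X at read time; motif rules
#: downstream are defined only on the 20 standard residues
NONSTANDARD_AA = frozenset("BZUOJ")
VALID_AA = STANDARD_AA | {"X"}

LINEAGE_RANKS = ("phylum", "class", "order", "family", "genus", "species")


def translate_cds(cds: str) -> str:
    """Translate a CDS under the standard code; ambiguous codons give X."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return str(Seq(cds.upper()).translate())


@dataclass(frozen=True)
class PrecursorRecord:
    """One candidate precursor sequence with optional CDS and metadata."""

    record_id: str
    aa_seq: str
    species: str = ""
    lineage: tuple = ()  # ordered (rank, name) pairs, phylum -> species
    cds_seq: Optional[str] = None
    family_claim: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise ValueError(f"record {self.record_id!r}: empty amino-acid sequence")
        bad = set(self.aa_seq) - VALID_AA
        if bad:
            raise ValueError(
                f"record {self.record_id!r}: invalid residues {sorted(bad)}"
            )
        if self.cds_seq is not None:
            aa = translate_cds(self.cds_seq)
            if aa.endswith("*"):
                aa = aa[:-1]
            if aa != self.aa_seq:
                raise ValueError(
                    f"record {self.record_id!r}: CDS translation does not match "
                    f"amino-acid sequence"
                )


def _clean_aa(raw: str, record_id: str) -> str:
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if any(c in NONSTANDARD_AA for c in seq):
        warnings.warn(
            f"record {record_id!r}: non-standard residues mapped to X",
            stacklevel=3,
        )
        seq = "".join("X" if c in NONSTANDARD_AA else c for c in seq)
    return seq


def read_fasta(path) -> list[PrecursorRecord]:
    """Read an amino-acid FASTA into records.

    The header token before the first whitespace becomes ``record_id``;
    sequences are uppercased, a single trailing ``*`` (stop) is stripped
    and non-standard residues are mapped to X with a warning.  Duplicate
    identifiers are a hard error.
    """
    records: list[PrecursorRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise ValueError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        records.append(PrecursorRecord(record_id=rid, aa_seq=_clean_aa(str(rec.seq), rid)))
    return records


def write_fasta(records: Iterable[PrecursorRecord], path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    seqrecs = [
        SeqRecord(Seq(r.aa_seq), id=r.record_id, description="") for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


@dataclass
class AnnotationTable:
    """Per-record taxonomy lineage and claimed family, keyed by record id."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.frame) and self.frame["record_id"].duplicated().any():
            dup = self.frame.loc[self.frame["record_id"].duplicated(), "record_id"]
            raise ValueError(f"duplicate record ids in annotation table: {sorted(set(dup))}")

    def __len__(self) -> int:
        return len(self.frame)

    def lineage(self, record_id: str) -> tuple:
        """Ordered (rank, name) pairs for one record; missing ranks empty."""
        row = self.frame.loc[self.frame["record_id"] == record_id]
        if row.empty:
            raise KeyError(record_id)
        row = row.iloc[0]
        return tuple(
            (rank, str(row[rank]) if rank in row.index else "")
            for rank in LINEAGE_RANKS
        )

    def family_claim(self, record_id: str) -> str:
        row = self.frame.loc[self.frame["record_id"] == record_id]
        if row.empty:
            raise KeyError(record_id)
        return str(row.iloc[0].get("family_claim", ""))


def read_annotation_table(path) -> AnnotationTable:
    """Read a TSV of record_id, phylum..species, family_claim.

    Missing ranks are kept as empty strings so the lineage retains its
    rank slots.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "record_id" not in frame.columns:
        raise ValueError(f"annotation table {path} lacks a 'record_id' column")
    for rank in LINEAGE_RANKS:
        if rank not in frame.columns:
            frame[rank] = ""
    if "family_claim" not in frame.columns:
        frame["family_claim"] = ""
    return AnnotationTable(frame=frame)


def write_annotation_table(table: AnnotationTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def longest_orf(nt_seq: str) -> tuple:
    """Longest ATG..stop open reading frame on the forward strand.

    Returns (start, end) half-open in nucleotides, stop codon included;
    (0, 0) when no complete ORF exists.  Case-insensitive, so cDNA with
    lowercase UTRs can be scanned directly.
    """
    seq = nt_seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    best = (0, 0)
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG" and start is None:
                start = i
            elif codon in stops and start is not None:
                if i + 3 - start > best[1] - best[0]:
                    best = (start, i + 3)
                start = None
    return best
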