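"""Three-stage purification of candidate neuropeptide precursors.

A genuine precursor (pre-pro-peptide) carries a signal peptide, one or
more active peptides flanked by dibasic excision motifs (KR/RK/RR/KK)
recognised by pro-protein convertases, and usually a glycine immediately
before the dibasic pair that amidates the mature peptide C-terminus.

The purge applies, in order:

1. **structural screen** -- signal peptide present, at least one dibasic
   dyad, overall length within the 40-2000 aa window of real precursors;
2. **dibasic screen** -- at least one dyad is glycine-preceded, i.e. the
   precursor can donate a C-terminal amide;
3. **convertase screen** -- at least one such site scores at or above the
   productive threshold ``TAU`` under the rule-based convertase score.

Stage flags are therefore monotone: a record passing stage *k* passed all
earlier stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core_io import PrecursorRecord

#: canonical prohormone-convertase dibasic dyads
DYADS = ("KR", "RK", "RR", "KK")
#: productive convertase-score threshold
TAU = 0.5
#: residues counted as hydrophobic by the signal-peptide heuristic
HYDROPHOBIC = frozenset("AILMFVWC")
#: precursor length gate (aa) for "neuropeptide structural organization"
MIN_LEN, MAX_LEN = 40, 2000
#: inter-site segments shorter than this are spacers, not peptides
MIN_PEPTIDE_LEN = 3


@dataclass(frozen=True)
class CleavageSite:
    """A dibasic convertase site: dyad start (0-based), motif, score."""

    pos: int
    motif: str
    convertase_score: float


@dataclass(frozen=True)
class ActivePeptide:
    """A mature peptide excised between productive cleavage sites."""

    seq: str
    span: tuple  # half-open (start, end) in the precursor
    amidated: bool
    copy_index: int


@dataclass
class PrecursorAnnotation:
    """Structural call for one record, with per-stage pass flags."""

    record_id: str
    signal_span: Optional[tuple] = None
    sites: list = field(default_factory=list)
    peptides: list = field(default_factory=list)
    passed_structural: bool = False
    passed_dibasic: bool = False
    passed_convertase: bool = False


@dataclass
class PipelineCounts:
    """Survivors per purge stage plus family-search additions."""

    n_input: int
    n_structural: int
    n_dibasic: int
    n_convertase: int
    additions: dict = field(default_factory=dict)
    n_final: int = -1

    def __post_init__(self) -> None:
        if not (self.n_input >= self.n_structural >= self.n_dibasic >= self.n_convertase >= 0):
            raise ValueError("stage counts must be monotone non-increasing")
        if any(v < 0 for v in self.additions.values()):
            raise ValueError("negative addition count")
        expected = self.n_convertase + sum(self.additions.values())
        if self.n_final == -1:
            self.n_final = expected
        elif self.n_final != expected:
            raise ValueError(
                f"n_final {self.n_final} != n_convertase + additions = {expected}"
            )


def score_convertase_site(aa_seq: str, pos: int) -> float:
    """Rule-based convertase score for the dyad starting at ``pos``.

    Base 0.5 for any dibasic dyad, +0.5 if the dyad is KR (the dyad most
    consistently cleaved in vivo), zeroed when the residue immediately
    after the dyad is proline (proline blocks cleavage); clamped to
    [0, 1].  Scores >= ``TAU`` mark a productive site.
    """
    motif = aa_seq[pos : pos + 2]
    if motif not in DYADS:
        raise ValueError(f"position {pos} is not a dibasic dyad (found {motif!r})")
    score = 0.5
    if motif == "KR":
        score += 0.5
    if pos + 2 < len(aa_seq) and aa_seq[pos + 2] == "P":
        score = 0.0
    return min(1.0, max(0.0, score))


def find_cleavage_sites(aa_seq: str) -> list[CleavageSite]:
    """All dibasic dyads, overlapping ones included, sorted by position."""
    sites = []
    for i in range(len(aa_seq) - 1):
        motif = aa_seq[i : i + 2]
        if motif in DYADS:
            sites.append(CleavageSite(i, motif, score_convertase_site(aa_seq, i)))
    return sites


def detect_signal_peptide(aa_seq: str) -> Optional[tuple]:
    """Heuristic signal-peptide call: interval [0, c) or None.

    Fires when the sequence starts with M and some 8-residue window fully
    inside the first 30 residues contains >= 6 hydrophobic residues; the
    cleavage point is the window end + 5, kept within [15, 35].
    """
    if not aa_seq.startswith("M"):
        return None
    limit = min(30, len(aa_seq))
    for start in range(0, limit - 8 + 1):
        window = aa_seq[start : start + 8]
        if sum(1 for c in window if c in HYDROPHOBIC) >= 6:
            c = min(start + 8 + 5, 35)
            c = max(c, 15)
            if c >= len(aa_seq):
                return None
            return (0, c)
    return None


def _contains_dyad(seq: str) -> bool:
    return any(seq[i : i + 2] in DYADS for i in range(len(seq) - 1))


def is_productive(site: CleavageSite) -> bool:
    return site.convertase_score >= TAU


def is_g_preceded(aa_seq: str, site: CleavageSite) -> bool:
    """True when the dyad is immediately preceded by the amide-donor G."""
    return site.pos > 0 and aa_seq[site.pos - 1] == "G"


def extract_peptides_from_sites(
    aa_seq: str,
    sites: Sequence[CleavageSite],
    signal_span: Optional[tuple] = None,
) -> list[ActivePeptide]:
    """Segments between productive cleavage sites, as mature peptides.

    Each segment is trimmed of its amide-donor glycine when the following
    dyad exists; segments shorter than ``MIN_PEPTIDE_LEN`` or still
    containing a dyad (not a clean mature peptide) are dropped.
    ``copy_index`` runs left to right from 1.
    """
    productive = [s for s in sites if is_productive(s)]
    if not productive:
        return []
    bounds_start = signal_span[1] if signal_span else 0
    segments = []  # (start, end, followed_by_site)
    prev_end = bounds_start
    for s in productive:
        if s.pos > prev_end:
            segments.append((prev_end, s.pos, True))
        prev_end = max(prev_end, s.pos + 2)
    if prev_end < len(aa_seq):
        segments.append((prev_end, len(aa_seq), False))

    peptides: list[ActivePeptide] = []
    idx = 1
    for start, end, followed in segments:
        seg = aa_seq[start:end]
        amidated = followed and seg.endswith("G")
        pep = seg[:-1] if amidated else seg
        pep_end = end - 1 if amidated else end
        if len(pep) < MIN_PEPTIDE_LEN or _contains_dyad(pep):
            continue
        peptides.append(ActivePeptide(pep, (start, pep_end), amidated, idx))
        idx += 1
    return peptides


def structural_screen(record: PrecursorRecord) -> PrecursorAnnotation:
    """Stage-1 structural call; sites and peptides are annotated as found."""
    aa = record.aa_seq
    sites = find_cleavage_sites(aa)
    signal = detect_signal_peptide(aa)
    peptides = extract_peptides_from_sites(aa, sites, signal)
    passed = signal is not None and len(sites) >= 1 and MIN_LEN <= len(aa) <= MAX_LEN
    return PrecursorAnnotation(
        record_id=record.record_id,
        signal_span=signal,
        sites=sites,
        peptides=peptides,
        passed_structural=passed,
    )


def dibasic_screen(record: PrecursorRecord, ann: PrecursorAnnotation) -> bool:
    """Stage 2: some dyad carries the amide-donor glycine."""
    if not ann.passed_structural:
        return False
    return any(is_g_preceded(record.aa_seq, s) for s in ann.sites)


def convertase_screen(record: PrecursorRecord, ann: PrecursorAnnotation) -> bool:
    """Stage 3: some glycine-preceded dyad scores productive."""
    if not ann.passed_dibasic:
        return False
    return any(
        is_g_preceded(record.aa_seq, s) and is_productive(s) for s in ann.sites
    )


def run_purge(
    records: Sequence[PrecursorRecord],
    allowlist: Optional[Iterable[str]] = None,
    denylist: Optional[Iterable[str]] = None,
) -> tuple[list[PrecursorAnnotation], PipelineCounts]:
    """Apply the three screens; return stage-3 survivors and stage counts.

    The optional allow/deny lists model the manual-curation step: they
    adjust the retained set after stage 3 but never the stage counts.
    """
    allow = set(allowlist or ())
    deny = set(denylist or ())
    annotations = []
    for rec in records:
        ann = structural_screen(rec)
        ann.passed_dibasic = dibasic_screen(rec, ann)
        ann.passed_convertase = convertase_screen(rec, ann)
        annotations.append(ann)
    counts = PipelineCounts(
        n_input=len(records),
        n_structural=sum(a.passed_structural for a in annotations),
        n_dibasic=sum(a.passed_dibasic for a in annotations),
        n_convertase=sum(a.passed_convertase for a in annotations),
    )
    retained = [
        a
        for a in annotations
        if (a.passed_convertase or a.record_id in allow)
        and a.record_id not in deny
    ]
    return retained, counts


def merge_additions(counts: PipelineCounts, additions: dict) -> PipelineCounts:
    """Fold externally identified per-family record counts into the totals.

    Values may be integers or sequences of records/ids; sequences are
    counted.
    """
    extra = {
        fam: (v if isinstance(v, int) else len(v)) for fam, v in additions.items()
    }
    merged = dict(counts.additions)
    for fam, n in extra.items():
        merged[fam] = merged.get(fam, 0) + n
    return PipelineCounts(
        n_input=counts.n_input,
        n_structural=counts.n_structural,
        n_dibasic=counts.n_dibasic,
        n_convertase=counts.n_convertase,
        additions=merged,
    )
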