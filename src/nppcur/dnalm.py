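"""DNA-loss-model engine.

The DNA loss model holds that new neuropeptide genes arose by loss of
codons from ancestral multi-copy precursors followed by fusion of the
surviving conserved codon blocks.  This module provides the machinery to
exercise that idea: a global affine-gap aligner whose terminal gaps are
priced separately (so the two parameter regimes contrasted in the
analysis -- the DNA-LM penalties and ordinary defaults -- are just two
:class:`AlignParams`), progressive multiple alignment over a k-mer guide
tree, back-mapping of amino-acid alignments onto codons, detection of
conserved codon blocks, and fusion of those blocks into a virtual
precursor (NPP) whose peptide layout can then be validated.

Alignment scoring
-----------------
A gap run of length *L* costs ``gap_open + gap_extend*(L-1)`` when
internal; a run touching either end of the alignment is terminal and
costs ``terminal_gap`` per residue instead.  Aligned residue pairs score
their substitution-matrix value plus the flat per-column ``bonus``
(0 by default, i.e. a no-op).  Ties are broken deterministically,
preferring a residue pair over a gap in the first sequence over a gap in
the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .core_io import PrecursorRecord, translate_cds
from .families import UNCLASSIFIED, classify_family
from .purge import detect_signal_peptide, extract_peptides_from_sites, find_cleavage_sites

GAP = "-"
CODON_GAP = "---"
NEG = float("-inf")

#: conserved-block defaults: the model's four-codon conserved runs
DEFAULT_MIN_BLOCK_LEN = 4
DEFAULT_MIN_BLOCK_IDENT = 0.8


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap parameters with a distinct terminal-gap rate."""

    gap_open: float
    gap_extend: float
    terminal_gap: float
    bonus: float = 0.0
    matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if min(self.gap_open, self.gap_extend, self.terminal_gap) < 0:
            raise ValueError("gap penalties must be non-negative")


#: the DNA-LM regime and a conventional default regime
PRESETS = {
    "dnalm": AlignParams(gap_open=9.0, gap_extend=0.2, terminal_gap=0.45, bonus=0.0),
    "default": AlignParams(gap_open=11.0, gap_extend=0.85, terminal_gap=0.45, bonus=0.0),
}


@lru_cache(maxsize=None)
def _matrix(name: str) -> dict:
    mat = substitution_matrices.load(name)
    table = {}
    for x in mat.alphabet:
        for y in mat.alphabet:
            table[(x, y)] = float(mat[x, y])
    return table


# ---------------------------------------------------------------------------
# core DP over abstract columns


def _affine_dp(
    m: int,
    n: int,
    score: Callable[[int, int], float],
    params: AlignParams,
) -> tuple[list, float]:
    """Global affine DP over column indices 0..m-1 and 0..n-1.

    Returns (path, score); the path is a list of (i, j) with None marking
    a gap.  States: M (pair), GB (gap in second seq, consumes i), GA
    (gap in first seq, consumes j).
    """
    op, ex, tg = params.gap_open, params.gap_extend, params.terminal_gap

    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    GA = [[NEG] * (n + 1) for _ in range(m + 1)]
    GB = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for i in range(1, m + 1):
        GB[i][0] = -tg * i
    for j in range(1, n + 1):
        GA[0][j] = -tg * j

    for i in range(1, m + 1):
        Mi, Mi1 = M[i], M[i - 1]
        GAi, GAi1 = GA[i], GA[i - 1]
        GBi, GBi1 = GB[i], GB[i - 1]
        for j in range(1, n + 1):
            best_prev = max(Mi1[j - 1], GAi1[j - 1], GBi1[j - 1])
            if best_prev > NEG:
                Mi[j] = best_prev + score(i - 1, j - 1) + params.bonus
            gb = max(Mi1[j] - op, GBi1[j] - ex, GAi1[j] - op)
            if gb > NEG:
                GBi[j] = gb
            ga = max(Mi[j - 1] - op, GAi[j - 1] - ex, GBi[j - 1] - op)
            if ga > NEG:
                GAi[j] = ga

    # terminal candidates: plain corner, or a trailing terminal run that
    # starts right after (i, n) / (m, j); the run is priced at tg per
    # residue, so the pre-run state may not already be in that gap state.
    best = M[m][n]
    choice = ("corner",)
    for i in range(m - 1, -1, -1):
        for state, tab in (("M", M), ("GA", GA)):
            cand = tab[i][n] - tg * (m - i)
            if cand > best:
                best, choice = cand, ("row", i, state)
    for j in range(n - 1, -1, -1):
        for state, tab in (("M", M), ("GB", GB)):
            cand = tab[m][j] - tg * (n - j)
            if cand > best:
                best, choice = cand, ("col", j, state)
    if best == NEG:  # both sequences empty
        return [], 0.0

    # traceback
    path: list = []
    if choice[0] == "corner":
        i, j, state = m, n, "M"
    elif choice[0] == "row":
        _, i, state = choice
        j = n
        for k in range(m, i, -1):
            path.append((k - 1, None))
    else:
        _, j, state = choice
        i = m
        for k in range(n, j, -1):
            path.append((None, k - 1))

    while i > 0 or j > 0:
        if state == "M":
            path.append((i - 1, j - 1))
            tgt = M[i][j] - score(i - 1, j - 1) - params.bonus
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = _pick_prev(tgt, M[i][j], GA[i][j], GB[i][j])
        elif state == "GB":
            path.append((i - 1, None))
            if j == 0:
                i -= 1
                state = "GB" if i > 0 else "M"
                continue
            tgt = GB[i][j]
            i -= 1
            if abs(M[i][j] - op - tgt) < 1e-9:
                state = "M"
            elif abs(GA[i][j] - op - tgt) < 1e-9:
                state = "GA"
            else:
                state = "GB"
        else:  # GA
            path.append((None, j - 1))
            if i == 0:
                j -= 1
                state = "GA" if j > 0 else "M"
                continue
            tgt = GA[i][j]
            j -= 1
            if abs(M[i][j] - op - tgt) < 1e-9:
                state = "M"
            elif abs(GA[i][j] - ex - tgt) < 1e-9:
                state = "GA"
            else:
                state = "GB"
    path.reverse()
    return path, best


def _pick_prev(target: float, m_val: float, ga_val: float, gb_val: float) -> str:
    for state, val in (("M", m_val), ("GA", ga_val), ("GB", gb_val)):
        if abs(val - target) < 1e-9:
            return state
    # fall back to the largest (float slack)
    return max((("M", m_val), ("GA", ga_val), ("GB", gb_val)), key=lambda t: t[1])[0]


def pairwise_affine_align(
    a: str, b: str, params: AlignParams
) -> tuple[str, str, float]:
    """Optimal global alignment of two amino-acid sequences.

    Returns the two gapped strings and the alignment score.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    table = _matrix(params.matrix)
    score = lambda i, j: table[(a[i], b[j])]
    path, total = _affine_dp(len(a), len(b), score, params)
    row_a = "".join(a[i] if i is not None else GAP for i, _ in path)
    row_b = "".join(b[j] if j is not None else GAP for _, j in path)
    return row_a, row_b, total


# ---------------------------------------------------------------------------
# progressive multiple alignment


@dataclass
class Alignment:
    """A gapped multiple alignment; rows ordered by sequence id."""

    ids: list
    rows: list

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("ragged alignment rows")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


def _kmer_cosine_distances(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    vocab: dict = {}
    vecs = []
    for s in seqs:
        counts: dict = {}
        for i in range(max(0, len(s) - k + 1)):
            kmer = s[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
            vocab.setdefault(kmer, len(vocab))
        vecs.append(counts)
    mat = np.zeros((len(seqs), len(vocab)))
    for r, counts in enumerate(vecs):
        for kmer, c in counts.items():
            mat[r, vocab[kmer]] = c
    norms = np.linalg.norm(mat, axis=1)
    norms[norms == 0] = 1.0
    unit = mat / norms[:, None]
    dist = 1.0 - unit @ unit.T
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, None)


def _profile_col_score(cols_a, cols_b, table):
    # bonus is added per matched column inside the DP itself
    def score(i: int, j: int) -> float:
        total, pairs = 0.0, 0
        for x in cols_a[i]:
            if x == GAP:
                continue
            for y in cols_b[j]:
                if y == GAP:
                    continue
                total += table[(x, y)]
                pairs += 1
        return total / pairs if pairs else 0.0

    return score


def progressive_align(records: Sequence, params: AlignParams) -> Alignment:
    """Progressive multiple alignment over a 3-mer-distance UPGMA guide tree.

    Accepts :class:`PrecursorRecord` objects or (id, sequence) pairs.
    Input order never matters: sequences are sorted by id before the
    guide tree is built, which also fixes tie-breaking.
    """
    pairs = [
        (r.record_id, r.aa_seq) if isinstance(r, PrecursorRecord) else tuple(r)
        for r in records
    ]
    if len(pairs) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    pairs.sort(key=lambda p: p[0])
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    seqs = [p[1] for p in pairs]

    table = _matrix(params.matrix)
    # profiles: cluster index -> list of (id, gapped seq)
    profiles = {i: [(ids[i], seqs[i])] for i in range(len(ids))}
    if len(ids) == 2:
        merge_order = [(0, 1)]
    else:
        dist = _kmer_cosine_distances(seqs)
        Z = linkage(squareform(dist, checks=False), method="average")
        merge_order = [(int(a), int(b)) for a, b, _, _ in Z]

    next_idx = len(ids)
    for a_idx, b_idx in merge_order:
        prof_a, prof_b = profiles.pop(a_idx), profiles.pop(b_idx)
        rows_a = [s for _, s in prof_a]
        rows_b = [s for _, s in prof_b]
        cols_a = ["".join(r[c] for r in rows_a) for c in range(len(rows_a[0]))]
        cols_b = ["".join(r[c] for r in rows_b) for c in range(len(rows_b[0]))]
        path, _ = _affine_dp(
            len(cols_a),
            len(cols_b),
            _profile_col_score(cols_a, cols_b, table),
            params,
        )
        merged = []
        for sid, row in prof_a:
            merged.append(
                (sid, "".join(row[i] if i is not None else GAP for i, _ in path))
            )
        for sid, row in prof_b:
            merged.append(
                (sid, "".join(row[j] if j is not None else GAP for _, j in path))
            )
        profiles[next_idx] = merged
        next_idx += 1

    final = profiles.popitem()[1]
    final.sort(key=lambda p: p[0])
    return Alignment(ids=[p[0] for p in final], rows=[p[1] for p in final])


# ---------------------------------------------------------------------------
# codon back-mapping, conserved blocks, fusion


@dataclass
class CodonAlignment:
    """Codon-resolution view of an amino-acid alignment.

    ``codon_rows[r][c]`` is a 3-nucleotide codon or ``---``;
    ``provenance[r][c]`` is the CDS offset of that codon (None at gaps).
    """

    ids: list
    codon_rows: list
    provenance: list

    @property
    def n_cols(self) -> int:
        return len(self.codon_rows[0]) if self.codon_rows else 0


def codon_backmap(aa_alignment: Alignment, cds_map: dict) -> CodonAlignment:
    """Map each aligned residue back to its source codon.

    A CDS may carry one trailing stop codon, which is dropped; any other
    length mismatch is an error naming the row.
    """
    codon_rows, prov_rows = [], []
    for sid, row in zip(aa_alignment.ids, aa_alignment.rows):
        cds = cds_map[sid].upper()
        n_aa = sum(1 for c in row if c != GAP)
        if len(cds) == 3 * (n_aa + 1) and translate_cds(cds[-3:]) == "*":
            cds = cds[:-3]
        if len(cds) != 3 * n_aa:
            raise ValueError(
                f"row {sid!r}: CDS length {len(cds)} does not match "
                f"{n_aa} aligned residues"
            )
        codons, prov = [], []
        k = 0
        for c in row:
            if c == GAP:
                codons.append(CODON_GAP)
                prov.append(None)
            else:
                codons.append(cds[3 * k : 3 * k + 3])
                prov.append(3 * k)
                k += 1
        codon_rows.append(codons)
        prov_rows.append(prov)
    return CodonAlignment(list(aa_alignment.ids), codon_rows, prov_rows)


@dataclass(frozen=True)
class ConservedBlock:
    """A maximal run of conserved codon columns."""

    start: int  # column interval, half-open
    end: int
    mean_identity: float
    consensus: tuple  # one codon per column

    def __len__(self) -> int:
        return self.end - self.start


def _column_identity(codon_aln: CodonAlignment, col: int) -> float:
    codons = [row[col] for row in codon_aln.codon_rows if row[col] != CODON_GAP]
    if len(codons) < 2:
        return 0.0
    total, pairs = 0, 0
    for i in range(len(codons)):
        for j in range(i + 1, len(codons)):
            total += sum(x == y for x, y in zip(codons[i], codons[j]))
            pairs += 1
    return total / (3 * pairs)


def _consensus_codon(codon_aln: CodonAlignment, col: int) -> str:
    codons = [row[col] for row in codon_aln.codon_rows if row[col] != CODON_GAP]
    counts: dict = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
    # plurality with lexicographic tie-break
    return min(counts, key=lambda c: (-counts[c], c))


def find_conserved_blocks(
    codon_aln: CodonAlignment,
    min_len: int = DEFAULT_MIN_BLOCK_LEN,
    min_ident: float = DEFAULT_MIN_BLOCK_IDENT,
) -> list[ConservedBlock]:
    """Maximal runs of columns with mean pairwise nucleotide identity
    >= ``min_ident`` (gaps excluded) and length >= ``min_len``, found by
    greedy left-to-right extension."""
    idents = [_column_identity(codon_aln, c) for c in range(codon_aln.n_cols)]
    blocks = []
    c = 0
    while c < len(idents):
        if idents[c] >= min_ident:
            start = c
            while c < len(idents) and idents[c] >= min_ident:
                c += 1
            if c - start >= min_len:
                consensus = tuple(
                    _consensus_codon(codon_aln, col) for col in range(start, c)
                )
                mean_ident = sum(idents[start:c]) / (c - start)
                blocks.append(ConservedBlock(start, c, mean_ident, consensus))
        else:
            c += 1
    return blocks


@dataclass
class Npp:
    """A virtual precursor fused from conserved codon blocks."""

    fused_cds: str
    aa_seq: str
    provenance: list  # per block: dict with column interval and cds offset
    layout: dict  # family -> copy count on the translated product


def fuse_blocks(
    blocks: Sequence[ConservedBlock],
    codon_aln: CodonAlignment,
    template_row_id: Optional[str] = None,
) -> Npp:
    """Concatenate block consensus codons in template coordinate order.

    Blocks are column intervals of the alignment, so template-row
    coordinate order coincides with column order for any template row;
    out-of-order input is sorted.
    """
    if not blocks:
        raise ValueError("no blocks to fuse")
    ordered = sorted(blocks, key=lambda b: b.start)
    fused = []
    provenance = []
    offset = 0
    for b in ordered:
        cds_part = "".join(b.consensus)
        provenance.append(
            {
                "columns": (b.start, b.end),
                "fused_offset": (offset, offset + len(cds_part)),
                "template_row": template_row_id,
            }
        )
        fused.append(cds_part)
        offset += len(cds_part)
    fused_cds = "".join(fused)
    aa = translate_cds(fused_cds).replace("*", "X")
    return Npp(fused_cds, aa, provenance, validate_npp_layout(aa))


def validate_npp_layout(precursor_aa: str, lineage: Optional[Sequence] = None) -> dict:
    """Active-peptide copy counts per family for one precursor sequence.

    Runs cleavage-site annotation and peptide extraction on the sequence
    and classifies every extracted peptide; unclassified peptides are not
    counted.
    """
    sites = find_cleavage_sites(precursor_aa)
    signal = detect_signal_peptide(precursor_aa)
    peptides = extract_peptides_from_sites(precursor_aa, sites, signal)
    layout: dict = {}
    for pep in peptides:
        call = classify_family(pep.seq, pep.amidated, lineage)
        if call.family != UNCLASSIFIED:
            layout[call.family] = layout.get(call.family, 0) + 1
    return layout
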