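# Methods

This note documents the models, rules and numerical choices behind
`nppcur`, and what the synthetic benchmarks do and do not demonstrate.

## Precursor model and the purge

A neuropeptide precursor is modeled as
`signal peptide — [active peptide — G — dibasic dyad]* — related peptides`,
with the dyad drawn from the four canonical pro-protein convertase
pairs KR, RK, RR, KK. Coordinates are 0-based half-open internally and
printed 1-based in reports.

The purge applies three screens in a fixed order, so the pass flags
form an implication chain (convertase ⇒ dibasic ⇒ structural):

1. **Structural.** The sequence starts with M and some 8-residue window
   fully inside the first 30 residues holds ≥ 6 residues from
   {A, I, L, M, F, V, W, C}; the signal cleavage point is window end
   + 5, clamped to [15, 35]. At least one dyad must exist and the
   length must fall in 40–2000 aa (the shortest real precursors, the
   AKH type, exceed 40 aa; the ceiling removes concatenated assembly
   artifacts). The signal heuristic is deliberately simple — the screen
   models the *concept* of a signal peptide, not any specific
   predictor.
2. **Dibasic.** At least one dyad is immediately preceded by the
   amide-donor glycine. This is the property that lets the precursor
   produce a C-terminally amidated peptide.
3. **Convertase.** A rule-based score stands in for neural-network
   convertase predictors: base 0.5 for any dyad, +0.5 for KR (the dyad
   most consistently cleaved), set to 0 when the residue after the dyad
   is proline (proline blocks cleavage), clamped to [0, 1]. Sites with
   score ≥ τ = 0.5 are productive; stage 3 requires a Gly-preceded
   productive site. The rule is deterministic and monotone; τ sits at
   the base score so that any non-blocked dyad class can be productive
   while proline-blocked sites never are.

Mature peptides are the segments between productive sites, trimmed of
the amide-donor G; segments shorter than 3 aa are spacers and segments
still containing a dyad are not clean mature peptides — both are
dropped. Manual curation is represented by allow/deny lists applied
after stage 3; externally identified family members (e.g. via BLAST
searches, which this package does not run) enter the totals through
`merge_additions`.

## Family rules

Classification is a first-match scan over an ordered, declarative rule
set (exported/imported as JSON so tests can freeze it). Feature-rich
families come first so the short C-terminal signatures cannot shadow
them: RPCH/AKH1 → AKH2 → AKH3 → AKH4 → ACP → CRZ → GnRH → APGWamide →
LWamide. Positions are 1-based on the mature peptide; an N-terminal Q
is read as pyroglutamate without editing the sequence.

Only a handful of features per family are established knowledge
(octapeptide F4/W8 core; G vs Q after the Trp; crustacean ACP two
residues longer; corazonin's Gln-Tyr between Phe and Ser and the
Thr-Asn-Gly repeat; GnRH protostome forms sharing G1/S5 at full length
and deuterostome forms two shorter with G/W/P; leucine absent from
APGWamide). The exact length windows, the AKH4 by-exclusion clause
(AKH-like length, pyroglutamate start, Trp present, no proline, but a
non-canonical F4/W8 arrangement), and the ACP anchor (length 10–12,
Q1/F4, Trp at position ≥ 8) are this package's declared
operationalizations; they are chosen to be mutually exclusive in the
stated order and are exercised against constructed examples in the
tests. RPCH and AKH1 are not separable on sequence features, so the
classifier returns the merged call and defers to taxonomy (a
crustacean lineage refines it to RPCH, the family exclusive to that
taxon).

## Alignment engine

The aligner is a global affine-gap dynamic program (Gotoh three-state)
with one extension: gap runs touching either end of the alignment are
"terminal" and cost `terminal_gap` per residue instead of
`gap_open + gap_extend·(L−1)`. This is the knob that distinguishes the
two regimes under study:

| preset | open | extend | terminal | bonus |
|---|---|---|---|---|
| `dnalm` | 9 | 0.2 | 0.45 | 0.0 |
| `default` | 11 | 0.85 | 0.45 | 0.0 |

The `default` preset follows the conventional amino-acid defaults of
Kalign-style progressive aligners; the analysis only requires the two
regimes to be contrasted, not any particular third-party
implementation. The `bonus` term adds a constant per matched column
(0 ⇒ no-op) and is carried for parameter-set fidelity. Substitution
scores come from BLOSUM62 (tests pin anchor entries). Tie-breaking
prefers a residue pair over a gap in the first sequence over a gap in
the second, making output deterministic. With terminal gaps at 0.45
per residue and the minimum BLOSUM62 score at −4, an optimal global
alignment may legitimately gap both termini rather than force a bad
end pairing; the enumeration oracle in the tests scores alignments
under the same published rule, independently.

Progressive alignment builds a guide tree by UPGMA over 3-mer-count
cosine distances (fast, deterministic, adequate for small family
sets), sorts sequences by id first so input order never matters, and
merges profiles with the same affine machinery using mean pairwise
column scores (gap-residue pairs contribute nothing).

## Codon blocks and virtual precursors

An amino-acid alignment is back-mapped codon-by-codon onto each row's
CDS (a trailing stop codon is tolerated and dropped). Column
conservation is the mean pairwise nucleotide identity over rows with a
codon in that column (< 2 codons ⇒ 0). Conserved blocks are maximal
runs with identity ≥ `min_ident` and length ≥ `min_len`, by greedy
left-to-right extension; defaults are `min_len = 4` codons (the
four-codon conserved runs the DNA loss model describes) and
`min_ident = 0.8`. Raising `min_ident` can only shrink total block
coverage (tested). The consensus codon per column is the plurality
with a lexicographic tie-break. Fusion concatenates block consensus
codons in column order — which is template-row coordinate order for
any row — records per-block provenance tiling the fused CDS exactly,
translates it, and validates the resulting layout by running the purge
annotation and family classifier over the virtual precursor.

The bundled multi-copy fixture (three APGWamide copies plus one
AKH-like decapeptide behind a signal peptide) reproduces the layout of
the rotifer-type APGW/AKH precursor; its decapeptide is built to the
AKH3 pattern (F4, W8, Q9) so the layout reads
`{APGWamide: 3, AKH3: 1}`.

## Trees and Robinson-Foulds

Tree inference is neighbor joining on p-distances (mismatch fraction
over columns where neither row has a gap), with Q-criterion ties broken
by the lexicographically smallest pair of cluster labels. NJ is a
deterministic stand-in: the deliverable is the *contrast* between the
two alignment regimes, not any specific likelihood tree.

RF is the size of the symmetric difference of the two trees'
nontrivial split sets; splits are kept in canonical smaller-side form,
which also makes a rooted degree-2 root contribute no duplicate split,
so RF is effectively computed on unrooted topologies. The normalized
variant divides by |S1| + |S2| (0 when both trees are stars). Published
RF values of non-integer magnitude correspond to some averaged or
normalized variant whose definition is not recoverable; this package
reports both the raw integer and its own normalization and makes no
claim of reproducing any particular printed value.

"Clade association" between families is operationalized as: a leaf is
associated with a reference family when its sibling subtree (the other
children at its parent) contains at least one reference-family leaf.
This is one defensible formalization of "sharing a node"; others
(e.g. nearest labeled ancestor rules) would give different counts.

## Synthetic data

The generator emulates the candidate pool a database search returns:
valid records with the full anatomy (`M` + 14 hydrophobic residues,
then `G`+dyad, then 1–3 copies of a family template each followed by
`G`+dyad, then a polar related-peptide tail padded to ≥ 48 aa) and
invalid records with exactly one defect — hydrophilic start
(`drop_signal`), no basic residues (`drop_dyad`), dyads without the
amide-donor glycine (`drop_amide_G`), or truncation below the length
floor (`truncate`). Templates are the canonical rule-satisfying
peptide per family. Validity is stratified (exactly
`round(n·p_valid)` valid) so count assertions are exact; a Bernoulli
mode exists for statistical tests. CDSs are uniform-synonymous reverse
translations; point mutation re-encodes the mutated residue so CDS and
protein stay consistent. All randomness flows from one seed through
numpy's PCG64 generator, giving byte-identical output across runs.

What passing these benchmarks shows: the screens, classifier, aligner
and tree metrics implement their stated rules exactly and recover
planted structure perfectly in the noiseless regime. What they do not
show: performance on real database sequences, whose signal peptides,
cleavage contexts and family motifs are far more variable than the
templates, which contain non-standard residues, fragments and
mislabeled entries, and whose invalid records can carry several
defects at once. Real-data retention rates therefore cannot be
predicted from the synthetic recovery fraction.

## Problem sizes and determinism

The default test suite and the acceptance script use problem sizes
chosen to exercise each property at full strength while staying quick
on a laptop: enumeration-oracle alignment checks on sequence pairs up
to length 8 (exhaustive enumeration grows as the Delannoy numbers),
RF oracle checks on trees of up to 8 leaves, purge recovery on batches
of 1000 records, regime contrast on 24 retained synthetic precursors,
and tree-pair bounds at 20 leaves. Every stochastic component takes an
explicit seed; identical configurations produce identical bytes, which
the run manifest (sha256 per artifact) makes checkable.

## Known limitations

- The signal-peptide heuristic and the convertase score are declared
  rules, not trained predictors; they are intentionally conservative
  and deterministic.
- Family rules cover the seven families' canonical forms; unusual
  isoforms (e.g. cerebral peptide, PTSP homologs) report as
  `unclassified`.
- The progressive aligner is not a reimplementation of any published
  MSA tool; only the penalty interface matches the two regimes under
  study.
- NJ on p-distances ignores rate heterogeneity and support values;
  conclusions should rest on regime *differences*, which is all the
  pipeline claims.
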