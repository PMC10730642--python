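import random

import pytest

from oracles import brute_force_align_score
from conftest import random_aa
from nppcur.dnalm import (
    AlignParams,
    Alignment,
    PRESETS,
    _matrix,
    codon_backmap,
    find_conserved_blocks,
    fuse_blocks,
    pairwise_affine_align,
    progressive_align,
    validate_npp_layout,
)


def test_blosum62_anchor_values():
    # pin a few canonical entries so matrix drift would be caught
    table = _matrix("BLOSUM62")
    assert table[("W", "W")] == 11
    assert table[("A", "A")] == 4
    assert table[("W", "P")] == -4
    assert table[("G", "G")] == 6


def test_presets():
    p = PRESETS["dnalm"]
    assert (p.gap_open, p.gap_extend, p.terminal_gap, p.bonus) == (9, 0.2, 0.45, 0.0)
    with pytest.raises(ValueError):
        AlignParams(gap_open=-1, gap_extend=0, terminal_gap=0)


def test_identity_alignment_has_no_gaps(dnalm_params):
    table = _matrix("BLOSUM62")
    a, b, score = pairwise_affine_align("APGW", "APGW", dnalm_params)
    assert (a, b) == ("APGW", "APGW")
    assert score == sum(table[(c, c)] for c in "APGW")


def test_single_internal_gap_matches_enumeration(dnalm_params):
    table = _matrix("BLOSUM62")
    a, b, score = pairwise_affine_align("APGW", "APW", dnalm_params)
    assert score == brute_force_align_score("APGW", "APW", dnalm_params, table)
    assert (a.count("-"), b.count("-")) == (0, 1)


def test_cheap_terminal_gaps_pushed_to_ends(dnalm_params):
    """With terminal gaps at 0.45/residue the 2-residue overhang splits
    across the ends rather than paying an internal gap open of 9."""
    a, b, score = pairwise_affine_align("AAAA", "AAAAAA", dnalm_params)
    assert b == "AAAAAA"
    assert a.strip("-") == "AAAA"  # all gaps terminal
    assert score == pytest.approx(4 * 4 - 2 * 0.45)


def test_empty_sequence_rejected(dnalm_params):
    with pytest.raises(ValueError):
        pairwise_affine_align("", "APGW", dnalm_params)


def test_aligner_optimal_vs_brute_force_short_pairs(dnalm_params):
    table = _matrix("BLOSUM62")
    rng = random.Random(42)
    for _ in range(60):
        a = random_aa(rng, rng.randint(1, 8))
        b = random_aa(rng, rng.randint(1, 8))
        _, _, score = pairwise_affine_align(a, b, dnalm_params)
        expected = brute_force_align_score(a, b, dnalm_params, table)
        assert score == pytest.approx(expected), (a, b)


def test_alignment_score_symmetry(dnalm_params):
    rng = random.Random(7)
    for _ in range(30):
        a = random_aa(rng, rng.randint(1, 12))
        b = random_aa(rng, rng.randint(1, 12))
        s_ab = pairwise_affine_align(a, b, dnalm_params)[2]
        s_ba = pairwise_affine_align(b, a, dnalm_params)[2]
        assert s_ab == pytest.approx(s_ba)


def test_progressive_identical_sequences_no_gaps(dnalm_params):
    recs = [("s1", "MKLVAPGW"), ("s2", "MKLVAPGW"), ("s3", "MKLVAPGW")]
    aln = progressive_align(recs, dnalm_params)
    assert aln.rows == ["MKLVAPGW"] * 3


def test_progressive_two_sequences_reduces_to_pairwise(dnalm_params):
    a, b = "MKLVAPGWGKR", "MKLVPGWGKR"
    ra, rb, _ = pairwise_affine_align(a, b, dnalm_params)
    aln = progressive_align([("x", a), ("y", b)], dnalm_params)
    assert aln.row("x") == ra and aln.row("y") == rb


def test_progressive_order_invariance(dnalm_params):
    recs = [("a", "MKLVAPGWGKR"), ("b", "MKLVPGWGKR"), ("c", "MKLVAPGWGK"), ("d", "MKAPGWGKR")]
    aln1 = progressive_align(recs, dnalm_params)
    aln2 = progressive_align(list(reversed(recs)), dnalm_params)
    assert aln1.ids == aln2.ids and aln1.rows == aln2.rows


def test_progressive_recovers_indel_columns(dnalm_params):
    """Four descendants of one ancestor, one deletion each and no
    substitutions: homologous columns must be homogeneous."""
    ancestor = "MKLVNDAPGWHECFYSTQRI"
    recs = []
    for idx, cut in enumerate((3, 8, 12, 17)):
        recs.append((f"s{idx}", ancestor[:cut] + ancestor[cut + 1 :]))
    aln = progressive_align(recs, dnalm_params)
    assert aln.n_cols == len(ancestor)
    for col in range(aln.n_cols):
        residues = {r[col] for r in aln.rows} - {"-"}
        assert len(residues) == 1


def test_codon_backmap_mechanical():
    aln = Alignment(ids=["x"], rows=["AP-GW"])
    ca = codon_backmap(aln, {"x": "GCTCCAGGTTGG"})
    assert ca.codon_rows[0] == ["GCT", "CCA", "---", "GGT", "TGG"]
    assert ca.provenance[0] == [0, 3, None, 6, 9]


def test_codon_backmap_preserves_all_gap_column():
    aln = Alignment(ids=["x", "y"], rows=["A-G", "A-G"])
    ca = codon_backmap(aln, {"x": "GCTGGT", "y": "GCAGGA"})
    assert [row[1] for row in ca.codon_rows] == ["---", "---"]


def test_codon_backmap_length_mismatch_names_row():
    aln = Alignment(ids=["x"], rows=["APGW"])
    with pytest.raises(ValueError, match="'x'"):
        codon_backmap(aln, {"x": "GCTCCA"})


def test_backtranslation_roundtrip():
    aln = Alignment(ids=["x", "y"], rows=["AP-GW", "APQGW"])
    cds = {"x": "GCTCCAGGTTGG", "y": "GCACCGCAAGGATGG"}
    ca = codon_backmap(aln, cds)
    for sid, row in zip(ca.ids, ca.codon_rows):
        assert "".join(c for c in row if c != "---") == cds[sid]


def test_conserved_blocks_identical_rows():
    aln = Alignment(ids=["a", "b"], rows=["APGW", "APGW"])
    ca = codon_backmap(aln, {"a": "GCTCCAGGTTGG", "b": "GCTCCAGGTTGG"})
    blocks = find_conserved_blocks(ca, min_len=4, min_ident=0.8)
    assert len(blocks) == 1
    assert (blocks[0].start, blocks[0].end) == (0, 4)
    assert blocks[0].mean_identity == 1.0


def test_conserved_blocks_two_islands():
    """Columns 0-3 and 8-11 identical, 4-7 divergent: exactly 2 blocks."""
    row_a = "AAAAGCHWAAAA"
    row_b = "AAAAMDYKAAAA"
    cds_a = "GCT" * 4 + "GGCTGTCACTGG" + "GCT" * 4
    cds_b = "GCT" * 4 + "ATGGACTATAAA" + "GCT" * 4
    ca = codon_backmap(
        Alignment(ids=["a", "b"], rows=[row_a, row_b]), {"a": cds_a, "b": cds_b}
    )
    blocks = find_conserved_blocks(ca, min_len=4, min_ident=0.9)
    assert [(b.start, b.end) for b in blocks] == [(0, 4), (8, 12)]


def test_conserved_blocks_min_len_exceeds_alignment():
    aln = Alignment(ids=["a", "b"], rows=["APGW", "APGW"])
    ca = codon_backmap(aln, {"a": "GCTCCAGGTTGG", "b": "GCTCCAGGTTGG"})
    assert find_conserved_blocks(ca, min_len=10, min_ident=0.5) == []


def test_raising_min_ident_never_increases_coverage():
    row_a = "AAAAGCHWAAAA"
    row_b = "AAAAMCHKAAAA"
    cds_a = "GCT" * 4 + "GGCTGTCACTGG" + "GCT" * 4
    cds_b = "GCT" * 4 + "ATGTGCCATAAA" + "GCT" * 4
    ca = codon_backmap(
        Alignment(ids=["a", "b"], rows=[row_a, row_b]), {"a": cds_a, "b": cds_b}
    )
    prev = None
    for ident in (0.2, 0.4, 0.6, 0.8, 1.0):
        cover = sum(len(b) for b in find_conserved_blocks(ca, 2, ident))
        if prev is not None:
            assert cover <= prev
        prev = cover


def test_fuse_single_block_translates_to_apgw():
    aln = Alignment(ids=["a", "b"], rows=["APGW", "APGW"])
    ca = codon_backmap(aln, {"a": "GCTCCAGGTTGG", "b": "GCTCCAGGTTGG"})
    blocks = find_conserved_blocks(ca, min_len=4, min_ident=0.8)
    npp = fuse_blocks(blocks, ca)
    assert npp.aa_seq == "APGW"
    assert npp.fused_cds == "GCTCCAGGTTGG"


def test_fuse_blocks_concatenates_in_column_order():
    row_a = "AAAAGCHWAAAA"
    row_b = "AAAAMDYKAAAA"
    cds_a = "GCT" * 4 + "GGCTGTCACTGG" + "GCT" * 4
    cds_b = "GCT" * 4 + "ATGGACTATAAA" + "GCT" * 4
    ca = codon_backmap(Alignment(ids=["a", "b"], rows=[row_a, row_b]),
                       {"a": cds_a, "b": cds_b})
    blocks = find_conserved_blocks(ca, min_len=4, min_ident=0.9)
    assert len(blocks) == 2
    # hand the blocks over in reversed order: output stays in column order
    npp = fuse_blocks(list(reversed(blocks)), ca, template_row_id="a")
    assert len(npp.fused_cds) == 3 * len(npp.aa_seq)
    offsets = [p["fused_offset"] for p in npp.provenance]
    assert offsets == sorted(offsets)
    # provenance tiles the fused cds exactly
    assert offsets[0][0] == 0 and offsets[-1][1] == len(npp.fused_cds)
    for (_, end), (start, _) in zip(offsets, offsets[1:]):
        assert end == start


def test_fuse_requires_blocks():
    aln = Alignment(ids=["a"], rows=["APGW"])
    ca = codon_backmap(aln, {"a": "GCTCCAGGTTGG"})
    with pytest.raises(ValueError):
        fuse_blocks([], ca)


ROTIFER_STYLE_FIXTURE = (
    "M" + "L" * 14 + "GKR" + ("APGW" + "GKR") * 3 + "QLNFSTGWQG" + "GKR"
    + "SDEQNTSDEQNT"
)


def test_npp_layout_three_apgw_one_akh():
    """A precursor built with three APGWamide copies and one AKH-like
    decapeptide reports exactly that layout."""
    layout = validate_npp_layout(ROTIFER_STYLE_FIXTURE)
    assert layout["APGWamide"] == 3
    akh_group = sum(
        layout.get(f, 0) for f in ("RPCH/AKH1", "AKH2", "AKH3", "AKH4")
    )
    assert akh_group == 1


def test_npp_layout_two_copies():
    seq = "M" + "L" * 14 + "GKR" + ("APGW" + "GKR") * 2 + "SDEQNTSDEQNT"
    assert validate_npp_layout(seq) == {"APGWamide": 2}


def test_npp_layout_without_sites_is_empty():
    assert validate_npp_layout("MAPGWAPGWSDEQNT") == {}
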