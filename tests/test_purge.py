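import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import naive_dyad_scan
from nppcur.core_io import PrecursorRecord
from nppcur.purge import (
    PipelineCounts,
    detect_signal_peptide,
    find_cleavage_sites,
    run_purge,
    score_convertase_site,
    structural_screen,
)
from nppcur.synth import SyntheticConfig, generate_precursors

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("MAAPGWGKRAPGWGKR", [(7, "KR"), (14, "KR")]),
        ("ACDEFGHILM", []),
        ("AKKRA", [(1, "KK"), (2, "KR")]),  # overlapping dyads both reported
        ("", []),
    ],
)
def test_find_cleavage_sites(seq, expected):
    sites = find_cleavage_sites(seq)
    assert [(s.pos, s.motif) for s in sites] == expected
    assert all(seq[s.pos : s.pos + 2] == s.motif for s in sites)


@settings(max_examples=150, deadline=None)
@given(st.text(alphabet=AA, min_size=0, max_size=500))
def test_cleavage_sites_agree_with_naive_scan(seq):
    """The site finder equals a check of every length-2 substring."""
    assert [(s.pos, s.motif) for s in find_cleavage_sites(seq)] == naive_dyad_scan(seq)


@pytest.mark.parametrize(
    "seq,pos,score",
    [
        ("AGKRA", 2, 1.0),  # KR scores full regardless of context
        ("AKKSA", 1, 0.5),  # non-KR dyad, no blocking proline
        ("AKRPA", 1, 0.0),  # proline after the dyad blocks cleavage
        ("AGRRA", 2, 0.5),
    ],
)
def test_convertase_score_rule_table(seq, pos, score):
    assert score_convertase_site(seq, pos) == score


def test_convertase_score_requires_dyad():
    with pytest.raises(ValueError):
        score_convertase_site("AAAA", 1)


def test_signal_peptide_hydrophobic_core_found():
    seq = "M" + "L" * 12 + "A" * 6 + "SDEQNTSDEQNTSDEQNT"
    span = detect_signal_peptide(seq)
    assert span is not None and span[0] == 0
    assert 15 <= span[1] <= 35


def test_signal_peptide_requires_leading_met():
    assert detect_signal_peptide("A" + "L" * 20 + "SDEQNT" * 5) is None


def test_signal_peptide_requires_hydrophobic_core():
    assert detect_signal_peptide("M" + "D" * 30) is None


def test_structural_screen_valid_construct(valid_precursor):
    ann = structural_screen(PrecursorRecord(record_id="v", aa_seq=valid_precursor))
    assert ann.passed_structural
    assert ann.signal_span is not None
    assert len(ann.sites) >= 1


def test_structural_screen_length_floor():
    ann = structural_screen(PrecursorRecord(record_id="f", aa_seq="M" + "L" * 19))
    assert not ann.passed_structural


def test_structural_screen_signalless():
    seq = "A" * 20 + "GKR" + "APGWGKR" + "SDEQNT" * 4
    ann = structural_screen(PrecursorRecord(record_id="s", aa_seq=seq))
    assert not ann.passed_structural


def test_run_purge_empty_input():
    retained, counts = run_purge([])
    assert retained == []
    assert (counts.n_input, counts.n_convertase, counts.n_final) == (0, 0, 0)


def test_run_purge_no_glycine_before_dyads():
    """Records whose dyads all lack the amide-donor G stop at stage 2."""
    seq = "M" + "L" * 14 + "KR" + "APGWSKR"[:-3] + "APGWKR" + "SDEQNT" * 4
    records = [PrecursorRecord(record_id="x", aa_seq=seq)]
    retained, counts = run_purge(records)
    assert counts.n_dibasic == 0 and counts.n_convertase == 0
    assert retained == []


@settings(max_examples=25, deadline=None)
@given(
    st.integers(min_value=0, max_value=60),
    st.floats(min_value=0.0, max_value=1.0),
    st.integers(min_value=0, max_value=2**31 - 1),
)
def test_stage_counts_monotone_on_random_batches(n, p_valid, seed):
    """n_input >= n_structural >= n_dibasic >= n_convertase always holds."""
    records, _ = generate_precursors(
        SyntheticConfig(n_records=n, p_valid=p_valid, seed=seed, bernoulli=True)
    )
    _, c = run_purge(records)
    assert c.n_input >= c.n_structural >= c.n_dibasic >= c.n_convertase >= 0


def test_purge_retains_exactly_truth_valid_records():
    records, truth = generate_precursors(
        SyntheticConfig(n_records=100, p_valid=0.4, seed=7)
    )
    retained, counts = run_purge(records)
    valid = {t.record_id for t in truth if t.is_valid}
    assert {a.record_id for a in retained} == valid
    assert counts.n_convertase == len(valid) == 40


def test_purge_is_deterministic():
    records, _ = generate_precursors(SyntheticConfig(n_records=30, seed=3))
    r1, c1 = run_purge(records)
    r2, c2 = run_purge(records)
    assert c1 == c2
    assert [(a.record_id, a.sites, a.peptides) for a in r1] == [
        (a.record_id, a.sites, a.peptides) for a in r2
    ]


def test_bernoulli_validity_fraction_within_three_sd():
    """Stage-3 retention recovers the generator's p_valid statistically."""
    n, p = 1500, 0.5
    records, truth = generate_precursors(
        SyntheticConfig(n_records=n, p_valid=p, seed=11, bernoulli=True)
    )
    _, counts = run_purge(records)
    sd = (n * p * (1 - p)) ** 0.5
    assert abs(counts.n_convertase - n * p) <= 3 * sd
    assert counts.n_convertase == sum(t.is_valid for t in truth)


def test_pipeline_counts_invariants():
    with pytest.raises(ValueError):
        PipelineCounts(n_input=5, n_structural=6, n_dibasic=1, n_convertase=0)
    with pytest.raises(ValueError):
        PipelineCounts(
            n_input=5, n_structural=4, n_dibasic=3, n_convertase=2,
            additions={"ACP": -1},
        )
    c = PipelineCounts(
        n_input=10, n_structural=8, n_dibasic=6, n_convertase=5,
        additions={"ACP": 2, "NPP": 1},
    )
    assert c.n_final == 8
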