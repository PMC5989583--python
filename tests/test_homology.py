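"""Aligner correctness vs independent oracles; criteria semantics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crtprofiler.homology import (
    AlignmentParams,
    OrthologyCriteria,
    ProteinAlignment,
    align_proteins,
    apply_criteria,
    call_orthologues,
    evalue,
)
from oracles import local_score_bruteforce


def test_self_alignment_is_perfect():
    a = align_proteins("MKV", "MKV")
    assert a.identity_fraction == 1.0
    assert a.alignment_length == 3
    assert a.query_span == (0, 3) and a.subject_span == (0, 3)


def test_unrelated_letters_give_no_extended_alignment():
    # A vs C scores 0 under BLOSUM62; no positive-scoring path exists
    a = align_proteins("AAAA", "CCCC")
    assert a.raw_score <= 0
    assert a.alignment_length <= 1


def test_classic_peptide_pair_matches_bruteforce_value():
    # frozen from the exhaustive substring-pair enumeration oracle
    a = align_proteins("PAWHEAE", "HEAGAWGHEE")
    assert a.raw_score == 17


def test_x_residue_scores_zero_everywhere():
    a = align_proteins("MKXV", "MKLV")
    b = align_proteins("MKAV", "MKLV")
    assert a.raw_score <= b.raw_score + 4  # X never beats a real residue by much
    with pytest.raises(ValueError, match="unknown residue"):
        align_proteins("MK!V", "MKV")
    with pytest.raises(ValueError, match="empty"):
        align_proteins("", "MKV")


def test_exhaustive_oracle_agreement_short_peptides():
    """Implementation equals brute-force enumeration on all short pairs."""
    alphabet = "ACDE"
    words = [
        "".join(w)
        for n in (1, 2, 3)
        for w in itertools.product(alphabet, repeat=n)
    ]
    for a in words[:30]:  # all length-1/2 and some length-3 on one side
        for b in words:
            assert align_proteins(a, b).raw_score == local_score_bruteforce(a, b), (a, b)


def test_oracle_agreement_sampled_longer_peptides():
    rng = np.random.default_rng(42)
    alphabet = np.array(list("ACDE"))
    for _ in range(120):
        a = "".join(rng.choice(alphabet, size=rng.integers(4, 7)))
        b = "".join(rng.choice(alphabet, size=rng.integers(4, 7)))
        assert align_proteins(a, b).raw_score == local_score_bruteforce(a, b), (a, b)


def test_biotite_cross_check_random_proteins():
    """Independent library implementation agrees on optimal local scores."""
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    rng = np.random.default_rng(7)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for _ in range(15):
        a = "".join(rng.choice(letters, size=rng.integers(20, 60)))
        b = "".join(rng.choice(letters, size=rng.integers(20, 60)))
        ours = align_proteins(a, b).raw_score
        alns = balign.align_optimal(
            bseq.ProteinSequence(a), bseq.ProteinSequence(b), matrix,
            gap_penalty=(-12, -1), local=True,
        )
        assert ours == alns[0].score


@settings(max_examples=60, deadline=None)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25),
       st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25))
def test_score_symmetry(a, b):
    assert align_proteins(a, b).raw_score == align_proteins(b, a).raw_score


def test_evalue_closed_form_and_identities():
    bit, ev = evalue(100, AlignmentParams(), m=300, n=10**6)
    assert bit == pytest.approx(43.128189, abs=1e-4)
    assert ev == pytest.approx(3.12063e-5, rel=1e-4)
    # bit == log2(m*n) implies E == 1
    params = AlignmentParams()
    m, n = 250, 4_000_000
    target_bit = math.log2(m * n)
    raw = (target_bit * math.log(2) + math.log(params.K)) / params.lam
    bit2, ev2 = evalue(int(round(raw)), params, m, n)
    assert ev2 == pytest.approx(1.0, rel=0.2)  # raw is integral, small rounding
    # monotone decreasing in raw score, vanishing in the limit
    evs = [evalue(s, params, m, n)[1] for s in range(0, 2000, 50)]
    assert all(x > y for x, y in zip(evs, evs[1:]))
    assert evalue(100000, params, m, n)[1] == 0.0
    with pytest.raises(ValueError):
        evalue(10, params, m=0, n=5)


def _fake_alignment(identity, bit, ev, length=100):
    return ProteinAlignment(0, bit, ev, identity, length, (0, length), (0, length))


@pytest.mark.parametrize(
    "identity,ldiff_len,bit,ev,expected_reasons",
    [
        (0.299, 100, 200.0, 1e-30, {"min_identity"}),
        (0.30, 100, 200.0, 1e-30, set()),          # boundary inclusive
        (0.50, 120, 200.0, 1e-30, {"max_length_difference"}),  # 20% strict
        (0.50, 119, 200.0, 1e-30, set()),
        (0.50, 100, 49.9, 1e-30, {"min_bit_score"}),
        (0.50, 100, 50.0, 1e-30, set()),           # boundary inclusive
        (0.50, 100, 200.0, 1e-10, {"max_e_value"}),  # boundary exclusive
        (0.50, 100, 200.0, 0.9e-10, set()),
    ],
)
def test_criteria_boundaries(identity, ldiff_len, bit, ev, expected_reasons):
    aln = _fake_alignment(identity, bit, ev)
    _, reasons = apply_criteria(aln, query_length=100, subject_length=ldiff_len)
    assert set(reasons) == expected_reasons


def test_call_orthologues_best_hit_and_self(panel):
    proteome = {"locus1": panel["crtB"], "locus2": panel["crtI"]}
    hits = call_orthologues({"crtB": panel["crtB"]}, proteome)
    assert hits["crtB"].subject == "locus1"
    assert hits["crtB"].alignment.identity_fraction == 1.0
    assert hits["crtB"].length_difference == 0.0


def test_call_orthologues_prefers_highest_identity(panel):
    from crtprofiler.synthetic_data import mutate_to_identity

    q = panel["crtZ"]
    p55, _ = mutate_to_identity(q, 0.55, seed=11)
    p70, _ = mutate_to_identity(q, 0.70, seed=12)
    hits = call_orthologues({"crtZ": q}, {"a_low": p55, "b_high": p70})
    assert hits["crtZ"].subject == "b_high"


def test_call_orthologues_empty_cases(panel):
    assert call_orthologues({"crtB": panel["crtB"]}, {}) == {}
    with pytest.raises(ValueError):
        call_orthologues({}, {"x": "MKV"})
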