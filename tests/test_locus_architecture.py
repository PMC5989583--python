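"""Adjacency arithmetic, locus construction, pattern classification."""

import numpy as np
import pytest

from crtprofiler.genome_io import CdsFeature, GenomeRecord
from crtprofiler.locus_architecture import (
    adjacency,
    build_loci,
    classify_architecture,
    relative_position,
    yi_cooccurrence,
)


def _feat(tag, start, end, strand="+", replicon="r"):
    return CdsFeature(tag, replicon, start, end, strand, protein="M")


class _Hit:
    def __init__(self, subject):
        self.subject = subject
        self.accepted = True


def _genome(feats, length=1_000_000):
    replicons = {}
    for f in feats:
        replicons.setdefault(f.replicon_id, (length, None))
    return GenomeRecord("t", replicons, list(feats))


@pytest.mark.parametrize(
    "a,b,overlap,gap,co",
    [
        ((0, 200, "+"), (196, 300, "+"), 4, 0, True),   # translational-coupling style
        ((0, 200, "+"), (206, 300, "+"), 0, 6, True),
        ((0, 200, "+"), (150, 400, "-"), 50, 0, False),
        ((0, 200, "+"), (200, 300, "+"), 0, 0, True),   # abutting
    ],
)
def test_adjacency_interval_arithmetic(a, b, overlap, gap, co):
    fa = _feat("a", a[0], a[1], a[2])
    fb = _feat("b", b[0], b[1], b[2])
    rel = adjacency(fa, fb)
    assert (rel.overlap_bp, rel.gap_bp, rel.co_oriented) == (overlap, gap, co)
    assert rel.overlap_bp * (rel.gap_bp or 0) == 0


def test_adjacency_different_replicons_is_non_adjacent():
    rel = adjacency(_feat("a", 0, 10, replicon="c1"), _feat("b", 0, 10, replicon="c2"))
    assert not rel.same_replicon
    assert rel.gap_bp is None


def test_overlap_agrees_with_base_membership_count():
    rng = np.random.default_rng(3)
    for _ in range(200):
        s1, s2 = rng.integers(0, 500, size=2)
        e1 = s1 + rng.integers(1, 300)
        e2 = s2 + rng.integers(1, 300)
        brute = len(set(range(s1, e1)) & set(range(s2, e2)))
        rel = adjacency(_feat("a", int(s1), int(e1)), _feat("b", int(s2), int(e2)))
        assert rel.overlap_bp == brute


def test_intervening_orf_count():
    feats = [
        _feat("y", 0, 200),
        _feat("d1", 250, 350),
        _feat("d2", 400, 500),
        _feat("b", 600, 800),
    ]
    rel = adjacency(feats[0], feats[3], _genome(feats))
    assert rel.intervening_orfs == 2


def _locus_genome(members, decoy_positions=()):
    """members: list of (symbol, start, end, strand)."""
    feats = []
    hits = {}
    for i, (sym, s, e, strand) in enumerate(members):
        tag = f"t{i}"
        feats.append(_feat(tag, s, e, strand))
        hits[sym] = _Hit(tag)
    for j, (s, e) in enumerate(decoy_positions):
        feats.append(_feat(f"d{j}", s, e))
    return hits, _genome(feats)


def test_build_loci_splits_on_intervening_threshold():
    # four decoys between crt genes -> two loci at the default threshold
    hits, genome = _locus_genome(
        [("crtY", 0, 900, "+"), ("crtI", 896, 2300, "+"), ("crtB", 10_000, 11_000, "+")],
        decoy_positions=[(3000, 3500), (4000, 4500), (5000, 5500), (6000, 6500)],
    )
    loci = build_loci(hits, genome)
    assert [sorted(l.symbols) for l in loci] == [["crtI", "crtY"], ["crtB"]]
    # with a permissive threshold they merge
    loci2 = build_loci(hits, genome, max_intervening=4, max_span_gap_bp=20_000)
    assert len(loci2) == 1


def test_build_loci_splits_on_distance():
    hits, genome = _locus_genome(
        [("crtY", 0, 900, "+"), ("crtI", 896, 2300, "+"), ("crtE", 1_000_000 - 900, 1_000_000, "-")]
    )
    loci = build_loci(hits, genome)
    assert len(loci) == 2
    assert {tuple(sorted(l.symbols)) for l in loci} == {("crtI", "crtY"), ("crtE",)}


def test_build_loci_invariant_to_hit_ordering_and_translation():
    members = [("crtY", 100, 1000, "+"), ("crtI", 996, 2400, "+"), ("crtB", 2450, 3400, "+")]
    hits, genome = _locus_genome(members)
    base = [l.members for l in build_loci(hits, genome)]
    reordered = dict(reversed(list(hits.items())))
    assert [l.members for l in build_loci(reordered, genome)] == base
    shifted, genome2 = _locus_genome([(s, a + 5000, b + 5000, st) for s, a, b, st in members])
    shifted_loci = build_loci(shifted, genome2)
    assert [[m[0] for m in l.members] for l in shifted_loci] == [
        [m[0] for m in l.members] for l in [l for l in build_loci(hits, genome)]
    ]
    assert [r.gap_bp for l in shifted_loci for r in l.adjacencies] == [
        r.gap_bp for l in build_loci(hits, genome) for r in l.adjacencies
    ]


def test_classify_p4_p5_partial():
    hits, genome = _locus_genome(
        [("crtY", 0, 900, "+"), ("crtI", 896, 2300, "+"), ("crtB", 2350, 3300, "+"),
         ("crtG", 500_000, 500_700, "-")]
    )
    label, _ = classify_architecture(build_loci(hits, genome), set(hits))
    assert label == "P4_YIB_together"

    hits5, genome5 = _locus_genome(
        [("crtY", 0, 900, "+"), ("crtI", 896, 2300, "+"), ("crtG", 2350, 3000, "+"),
         ("crtB", 500_000, 500_900, "-")]
    )
    label5, _ = classify_architecture(build_loci(hits5, genome5), set(hits5))
    assert label5 == "P5_YIG_together"

    hits1, genome1 = _locus_genome([("crtE", 0, 900, "+")])
    label1, _ = classify_architecture(build_loci(hits1, genome1), set(hits1))
    assert label1 == "partial"


def test_classify_p1_with_accessory_members_still_contiguous():
    hits, genome = _locus_genome(
        [("crtY", 0, 900, "+"), ("crtI", 896, 2300, "+"), ("log", 2350, 2900, "+"),
         ("crtB", 2950, 3900, "+"), ("crtG", 3950, 4600, "-")]
    )
    label, ann = classify_architecture(build_loci(hits, genome), set(hits))
    assert label == "P1_contiguous"
    assert ann["log_between_crtI_crtB"] is True


def test_classify_p2_needs_1_to_3_separating_orfs():
    hits, genome = _locus_genome(
        [("crtY", 0, 900, "+"), ("crtI", 896, 2300, "+"), ("crtB", 2350, 3300, "+"),
         ("crtG", 5200, 5900, "-")],
        decoy_positions=[(3400, 3900), (4100, 4600)],
    )
    label, _ = classify_architecture(build_loci(hits, genome), set(hits))
    assert label == "P2_crtG_separated"


def test_classify_p3_mixed_strands():
    hits, genome = _locus_genome(
        [("crtG", 0, 700, "+"), ("crtY", 1500, 2400, "+"), ("crtI", 2396, 3800, "+"),
         ("crtB", 4800, 5700, "-")],
        decoy_positions=[(800, 1300), (4000, 4500)],
    )
    label, _ = classify_architecture(build_loci(hits, genome), set(hits))
    assert label == "P3_atypical"


def test_strand_aware_upstream_convention():
    # crtW before crtZ in coordinates; plus-strand crtZ reads W as upstream,
    # minus-strand crtZ reads it as downstream
    members_plus = [("crtW", 0, 700, "+"), ("crtZ", 750, 1300, "+")]
    members_minus = [("crtW", 0, 700, "-"), ("crtZ", 750, 1300, "-")]
    assert relative_position([(s, f"t{i}", st) for i, (s, _, _, st) in enumerate(members_plus)],
                             "crtW", "crtZ") == "upstream"
    assert relative_position([(s, f"t{i}", st) for i, (s, _, _, st) in enumerate(members_minus)],
                             "crtW", "crtZ") == "downstream"
    hits, genome = _locus_genome(members_plus)
    _, ann = classify_architecture(build_loci(hits, genome), set(hits))
    assert ann["crtW_upstream_of_crtZ"] is True
    assert ann["crtW_downstream_of_crtZ"] is False
    hits2, genome2 = _locus_genome(members_minus)
    _, ann2 = classify_architecture(build_loci(hits2, genome2), set(hits2))
    assert ann2["crtW_downstream_of_crtZ"] is True


def test_yi_summary_modal_overlap_and_gap_range():
    records = []
    for overlap in (4, 4, 1, 8):
        records.append({"both_present": True, "co_located": True, "co_oriented": True,
                        "overlap_bp": overlap, "gap_bp": None})
    for gap in (6, 25):
        records.append({"both_present": True, "co_located": True, "co_oriented": True,
                        "overlap_bp": None, "gap_bp": gap})
    records.append({"both_present": False, "co_located": False, "co_oriented": False,
                    "overlap_bp": None, "gap_bp": None})
    s = yi_cooccurrence(records)
    assert s["modal_overlap_bp"] == 4
    assert s["gap_range_bp"] == (6, 25)
    assert s["n_overlapping"] == 4
    assert s["n_both_present"] == 6


def test_yi_different_contigs_never_co_located():
    from crtprofiler.locus_architecture import yi_record

    feats = [_feat("y1", 0, 900, replicon="c1"), _feat("i1", 0, 1400, replicon="c2")]
    genome = GenomeRecord("draft", {"c1": (5000, None), "c2": (5000, None)}, feats, status="draft")
    rec = yi_record({"crtY": _Hit("y1"), "crtI": _Hit("i1")}, genome)
    assert rec["both_present"] is True
    assert rec["co_located"] is False
    assert rec["overlap_bp"] is None
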