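"""Generator contracts: identity control, determinism, manifest truth."""

import pytest

from crtprofiler.genome_io import parse_genome, translate_cds, write_genome
from crtprofiler.homology import align_proteins
from crtprofiler.synthetic_data import (
    FAMILY_LENGTHS,
    SyntheticSpec,
    build_cohort_fixture,
    build_synthetic_genome,
    mutate_to_identity,
    reference_panel,
)

CORE_G = frozenset({"crtE", "crtB", "crtI", "crtY", "crtZ", "crtG"})


def test_reference_panel_is_deterministic_with_typical_lengths():
    p1, p2 = reference_panel(), reference_panel()
    assert p1 == p2
    assert set(p1) == set(FAMILY_LENGTHS)
    assert len(p1["crtE"]) == 300  # GGPP synthases are ~300 aa
    assert all(prot[0] == "M" for prot in p1.values())


def test_mutate_identity_endpoints(panel):
    prot, realized = mutate_to_identity(panel["crtB"], 1.0, seed=1)
    assert prot == panel["crtB"] and realized == 1.0
    with pytest.raises(ValueError):
        mutate_to_identity(panel["crtB"], 0.10, seed=1)


@pytest.mark.parametrize("target", [0.30, 0.45, 0.60, 0.80])
def test_mutate_identity_hits_target_within_tolerance(panel, target):
    prot, realized = mutate_to_identity(panel["crtI"], target, seed=99)
    assert abs(realized - target) <= 0.02
    # the defining oracle is the package aligner itself
    assert align_proteins(panel["crtI"], prot).identity_fraction == pytest.approx(realized)


def test_mutate_identity_deterministic(panel):
    a = mutate_to_identity(panel["crtY"], 0.5, seed=7)
    b = mutate_to_identity(panel["crtY"], 0.5, seed=7)
    c = mutate_to_identity(panel["crtY"], 0.5, seed=8)
    assert a == b
    assert a != c


def test_same_seed_byte_identical_files(tmp_path):
    spec = SyntheticSpec(seed=13)
    r1, _ = build_synthetic_genome(spec)
    r2, _ = build_synthetic_genome(spec)
    write_genome(r1, tmp_path / "a.gff3")
    write_genome(r2, tmp_path / "b.gff3")
    assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


def test_emitted_genome_parses_cleanly_and_matches_manifest(tmp_path):
    spec = SyntheticSpec(seed=21, template="P1_contiguous", genotype=CORE_G)
    record, manifest = build_synthetic_genome(spec)
    files = write_genome(record, tmp_path / "g.gff3")
    back = parse_genome(files[0])
    assert len(back.features) == len(record.features)
    for symbol, facts in manifest.genes.items():
        f = back.feature_by_tag(facts["locus_tag"])
        assert (f.start, f.end, f.strand) == (facts["start"], facts["end"], facts["strand"])


def test_planted_genes_translate_from_their_dna():
    """DNA and annotation stay consistent, including the overlapped crtI."""
    spec = SyntheticSpec(seed=4, yi_overlap_bp=7)  # forces a 3-codon overlap head
    record, manifest = build_synthetic_genome(spec)
    seq = next(iter(record.replicons.values()))[1]
    for symbol, facts in manifest.genes.items():
        f = record.feature_by_tag(facts["locus_tag"])
        nt = seq[f.start : f.end]
        if f.strand == "-":
            from Bio.Seq import Seq

            nt = str(Seq(nt).reverse_complement())
        assert translate_cds(nt) == f.protein, symbol


@pytest.mark.parametrize("overlap", [1, 2, 4, 5, 7, 8])
def test_planted_yi_overlap_is_exact(overlap):
    spec = SyntheticSpec(seed=2, yi_overlap_bp=overlap)
    record, manifest = build_synthetic_genome(spec)
    fy = record.feature_by_tag(manifest.genes["crtY"]["locus_tag"])
    fi = record.feature_by_tag(manifest.genes["crtI"]["locus_tag"])
    assert fy.end - fi.start == overlap


@pytest.mark.parametrize("gap", [6, 25])
def test_planted_yi_gap_is_exact(gap):
    spec = SyntheticSpec(seed=2, yi_overlap_bp=None, yi_gap_bp=gap)
    record, manifest = build_synthetic_genome(spec)
    fy = record.feature_by_tag(manifest.genes["crtY"]["locus_tag"])
    fi = record.feature_by_tag(manifest.genes["crtI"]["locus_tag"])
    assert fi.start - fy.end == gap


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match="multiple of 3"):
        SyntheticSpec(seed=1, yi_overlap_bp=6)
    with pytest.raises(ValueError, match="requires genes"):
        SyntheticSpec(seed=1, template="P5_YIG_together",
                      genotype=frozenset({"crtE", "crtB", "crtI", "crtY", "crtZ"}))
    with pytest.raises(ValueError, match="yi_gap_bp"):
        SyntheticSpec(seed=1, yi_overlap_bp=None, yi_gap_bp=30)


def test_reverse_strand_genes_are_reverse_complemented():
    spec = SyntheticSpec(seed=6)
    record, manifest = build_synthetic_genome(spec)
    seq = next(iter(record.replicons.values()))[1]
    facts = manifest.genes["crtE"]  # planted on the minus strand
    assert facts["strand"] == "-"
    from Bio.Seq import Seq

    nt = str(Seq(seq[facts["start"] : facts["end"]]).reverse_complement())
    assert nt.startswith("ATG")
    assert translate_cds(nt) == record.feature_by_tag(facts["locus_tag"]).protein


def test_cohort_fixture_contents():
    df = build_cohort_fixture()
    assert len(df) == 41
    row13 = df[df["serial"] == 13].iloc[0]
    assert row13["symbols"] == frozenset(
        {"crtE", "crtB", "crtI", "crtY", "crtZ", "crtW", "crtX"}
    )
    assert row13["group"] == "III"
    row41 = df[df["serial"] == 41].iloc[0]
    assert row41["symbols"] == frozenset({"crtE"})
    assert row41["group"] == "IV"
    assert df["genus"].nunique() == 10
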