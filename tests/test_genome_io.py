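"""Coordinate conventions, translation, round-trips, start curation."""

import numpy as np
import pytest

from crtprofiler.genome_io import (
    CdsFeature,
    GenomeRecord,
    curate_start_codon,
    parse_genome,
    translate_cds,
    write_genome,
)


def test_translation_table11_strips_stop():
    assert translate_cds("ATGGCTGCTTAA") == "MAA"
    # GTG start is reported as V unless curated upstream; table 11 direct read
    assert translate_cds("GTGGCT") == "VA"


@pytest.mark.parametrize(
    "start1,end1,strand,exp",
    [
        (1, 6, "+", (0, 6, "+")),   # GenBank "1..6"
        (10, 30, "-", (9, 30, "-")),  # "complement(10..30)"
    ],
)
def test_one_based_inclusive_to_half_open(tmp_path, start1, end1, strand, exp):
    seq = "ACGTACGTAC" * 10
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n##sequence-region repA 1 100\n"
        f"repA\tx\tCDS\t{start1}\t{end1}\t.\t{strand}\t0\tID=g1;translation=MK\n"
    )
    rec = parse_genome(gff)
    f = rec.features[0]
    assert (f.start, f.end, f.strand) == exp
    assert f.nucleotide_length == f.end - f.start


def test_translation_derived_from_sequence_when_absent(tmp_path):
    seq = "ATGGCTGCTTAA" + "A" * 8
    (tmp_path / "g.fasta").write_text(f">repA\n{seq}\n")
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n##sequence-region repA 1 20\n"
        "repA\tx\tCDS\t1\t12\t.\t+\t0\tID=g1\n"
    )
    rec = parse_genome(gff)
    assert rec.features[0].protein == "MAA"


def test_roundtrip_both_dialects(tmp_path, two_gene_record):
    for fmt, name in (("gff3+fasta", "a.gff3"), ("genbank", "a.gbk")):
        write_genome(two_gene_record, tmp_path / name, fmt)
        back = parse_genome(tmp_path / name)
        orig = [
            (f.locus_tag, f.start, f.end, f.strand, f.product, f.protein)
            for f in two_gene_record.sorted_features()
        ]
        rt = [
            (f.locus_tag, f.start, f.end, f.strand, f.product, f.protein)
            for f in back.sorted_features()
        ]
        assert rt == orig, fmt


def test_unknown_strand_written_as_dot_and_readback(tmp_path):
    rec = GenomeRecord(
        "draftish",
        {"ctg1": (300, None)},
        [CdsFeature("u1", "ctg1", 10, 40, "?", protein="MKL")],
    )
    files = write_genome(rec, tmp_path / "d.gff3", "gff3+fasta")
    text = files[0].read_text()
    line = [l for l in text.splitlines() if "\tCDS\t" in l][0]
    assert line.split("\t")[6] == "."
    assert parse_genome(files[0]).features[0].strand == "?"
    with pytest.raises(ValueError):
        write_genome(rec, tmp_path / "d.gbk", "genbank")


def test_empty_feature_list_roundtrip(tmp_path):
    rec = GenomeRecord("empty", {"r": (100, "A" * 100)}, [])
    write_genome(rec, tmp_path / "e.gff3")
    assert parse_genome(tmp_path / "e.gff3").features == []


def test_gff3_write_is_byte_stable(tmp_path, two_gene_record):
    write_genome(two_gene_record, tmp_path / "x.gff3")
    first = (tmp_path / "x.gff3").read_bytes()
    rt = parse_genome(tmp_path / "x.gff3")
    write_genome(rt, tmp_path / "y.gff3")
    assert (tmp_path / "y.gff3").read_bytes() == first


def test_feature_outside_replicon_rejected():
    with pytest.raises(ValueError, match="beyond replicon"):
        GenomeRecord("bad", {"r": (50, None)}, [CdsFeature("f", "r", 10, 80, "+", protein="M")])


def test_duplicate_locus_tags_rejected():
    feats = [
        CdsFeature("f", "r", 0, 9, "+", protein="M"),
        CdsFeature("f", "r", 20, 29, "+", protein="M"),
    ]
    with pytest.raises(ValueError, match="duplicate"):
        GenomeRecord("bad", {"r": (100, None)}, feats)


def test_coordinate_roundtrip_random():
    rng = np.random.default_rng(0)
    for _ in range(200):
        start1 = int(rng.integers(1, 10_000))
        length = int(rng.integers(3, 3000))
        end1 = start1 + length - 1  # 1-based inclusive
        start0, end0 = start1 - 1, end1  # internal half-open
        assert (start0 + 1, end0) == (start1, end1)
        assert end0 - start0 == length


def test_start_codon_curation_prefers_atg_over_nearer_gtg():
    # layout: ATG ... GTG ... annotated start; curation should jump to ATG
    upstream = "ATG" + "CCA" + "GTG" + "CCT"
    cds = "ATGGCTGCTTAA"
    seq = "GG" + upstream + cds + "AAAA"
    rec = GenomeRecord(
        "cur",
        {"r": (len(seq), seq)},
        [CdsFeature("g", "r", 14, 26, "+", protein="MAA")],
    )
    new = curate_start_codon(rec.features[0], rec)
    assert new.start == 2
    assert seq[new.start : new.start + 3] == "ATG"
    assert new.protein.startswith("M")


def test_start_codon_curation_stops_at_inframe_stop():
    seq = "TAA" + "GTG" + "ATGGCTGCTTAA"
    rec = GenomeRecord(
        "cur2",
        {"r": (len(seq), seq)},
        [CdsFeature("g", "r", 6, 18, "+", protein="MAA")],
    )
    new = curate_start_codon(rec.features[0], rec)
    assert new.start == 3  # GTG reachable, TAA blocks anything further
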