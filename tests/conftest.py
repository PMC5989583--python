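import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from crtprofiler.genome_io import CdsFeature, GenomeRecord
from crtprofiler.synthetic_data import reference_panel


@pytest.fixture(scope="session")
def panel():
    return reference_panel()


@pytest.fixture()
def two_gene_record():
    """A minimal two-CDS genome with explicit nucleotide sequence."""
    seq = ("ATGGCTGCTTAA" + "ACGT" * 20 + "ATGAAAGTTCTGTAA" + "ACGT" * 10)
    return GenomeRecord(
        strain_name="mini",
        replicons={"repA": (len(seq), seq)},
        features=[
            CdsFeature("g1", "repA", 0, 12, "+", product="demo1", protein="MAA"),
            CdsFeature("g2", "repA", 92, 107, "+", product="demo2", protein="MKVL"),
        ],
    )


def make_feature(tag, start, end, strand="+", replicon="repA", protein="M" + "A" * 10):
    return CdsFeature(tag, replicon, start, end, strand, protein=protein)


@pytest.fixture()
def feature_factory():
    return make_feature
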