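"""Census of the crtY-crtI junction across a small synthetic cohort.

Plants a mix of reading-frame overlaps (4 bp most common) and short gaps,
then recomputes the per-strain relation from the annotations alone and
summarises it — the same computation the cohort analysis applies to real
genomes, where the junction is a conserved feature of carotenogenic
bacteria.
"""

from crtprofiler import SyntheticSpec, build_synthetic_genome, profile_genome
from crtprofiler.locus_architecture import yi_cooccurrence

planted = [("overlap", 4), ("overlap", 4), ("overlap", 1), ("overlap", 8),
           ("gap", 6), ("gap", 25)]
records = []
for i, (kind, bp) in enumerate(planted):
    spec = SyntheticSpec(
        seed=50 + i,
        yi_overlap_bp=bp if kind == "overlap" else None,
        yi_gap_bp=bp if kind == "gap" else None,
    )
    genome, _ = build_synthetic_genome(spec)
    records.append(profile_genome(genome).yi)

summary = yi_cooccurrence(records)
print(f"strains with both crtY and crtI: {summary['n_both_present']}")
print(f"co-located and co-oriented:      {summary['n_co_oriented']}")
print(f"overlapping pairs:               {summary['n_overlapping']} "
      f"(modal overlap {summary['modal_overlap_bp']} bp)")
print(f"gapped pairs:                    {summary['n_gapped']} "
      f"(gap range {summary['gap_range_bp']} bp)")

# The recovered census equals the planted one: overlaps {4,4,1,8} with mode
# 4 bp, gaps spanning 6-25 bp.
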