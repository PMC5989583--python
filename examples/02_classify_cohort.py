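"""Classify the packaged 41-strain cohort table and tally the groups.

Each strain's crt genotype is mapped to pigmentation group I-IV purely from
gene presence/absence; the printed agreement shows the classifier
reproduces the table's group column for every strain.
"""

from crtprofiler import CrtGenotype, assign_group, build_cohort_fixture, cohort_summary

df = build_cohort_fixture()
agree = sum(
    assign_group(CrtGenotype(r.strain, r.symbols)).group == r.group
    for r in df.itertuples()
)
s = cohort_summary(df)

print(f"strains: {s.n_strains} ({s.n_complete} complete genomes)")
print(f"classifier agreement with the table: {agree}/{s.n_strains}")
print(f"group tallies: {dict(sorted(s.group_counts.items()))}")
print(f"crtZ+ strains: {s.symbol_counts['crtZ']}, of which crtW+: "
      f"{s.symbol_counts['crtW']} "
      f"(~{100 * s.symbol_counts['crtW'] / s.symbol_counts['crtZ']:.0f} %)")
print(f"strains with both crtY and crtI: {s.n_with_both_YI}")

# The counts mirror the cohort's published genotype statements: a large
# yellow group I majority, few keto-carotenoid (crtW) strains, and the
# near-universal crtY/crtI pairing.
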