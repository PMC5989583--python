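"""Per-genome and cohort-level orchestration of the profiling stages."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from crtprofiler.genome_io import GenomeRecord
from crtprofiler.genotype_classifier import (
    CRT_SYMBOLS,
    CrtGenotype,
    GroupAssignment,
    predict_phenotype,
)
from crtprofiler.homology import (
    AlignmentParams,
    OrthologueHit,
    OrthologyCriteria,
    call_orthologues,
    hits_table,
)
from crtprofiler.locus_architecture import (
    LocusArchitecture,
    build_loci,
    classify_architecture,
    pgc_present,
    yi_cooccurrence,
    yi_record,
)
from crtprofiler.motif_scan import motif_report
from crtprofiler.pathway_inference import PathwayGraph


@dataclass
class StrainProfile:
    """Everything the pipeline derives for one genome."""

    strain: str
    genotype: CrtGenotype
    hits: dict[str, OrthologueHit]
    loci: list[LocusArchitecture]
    pattern_label: str
    annotations: dict[str, bool]
    motifs: object  # DataFrame
    assignment: GroupAssignment
    yi: dict[str, object]
    status: str = "complete"

    @property
    def symbols(self) -> frozenset[str]:
        return self.genotype.symbols


def profile_genome(
    genome: GenomeRecord,
    panel: Optional[Mapping[str, str]] = None,
    criteria: Optional[OrthologyCriteria] = None,
    params: Optional[AlignmentParams] = None,
    graph: Optional[PathwayGraph] = None,
    pgc_panel: Optional[Mapping[str, str]] = None,
    max_intervening: int = 3,
    max_span_gap_bp: int = 10_000,
    replicon_ids: Optional[Iterable[str]] = None,
) -> StrainProfile:
    """Run every stage on one genome and cross-check the results.

    ``panel`` defaults to the synthetic reference panel.  ``replicon_ids``
    restricts profiling to the named replicons (e.g. the chromosome of a
    multi-replicon genome, leaving plasmids out); default is all replicons.
    Stage errors propagate with the stage name prefixed.
    """
    if panel is None:
        from crtprofiler.synthetic_data import reference_panel

        panel = reference_panel()
    if replicon_ids is not None:
        keep = set(replicon_ids)
        genome = GenomeRecord(
            genome.strain_name,
            {r: v for r, v in genome.replicons.items() if r in keep},
            [f for f in genome.features if f.replicon_id in keep],
            genome.status,
        )
    stage = "orthologue calling"
    try:
        hits = call_orthologues(panel, genome, criteria, params)
        stage = "locus construction"
        loci = build_loci(hits, genome, max_intervening, max_span_gap_bp)
        crt_symbols = frozenset(s for s in hits if s in CRT_SYMBOLS)
        stage = "architecture classification"
        pattern, annotations = classify_architecture(loci, crt_symbols)
        stage = "motif scan"
        motifs = motif_report(hits, genome.proteome())
        stage = "crtY/crtI relation"
        yi = yi_record(hits, genome)
        stage = "PGC detection"
        accessory = {s for s in ("log", "duf2141") if s in hits}
        if pgc_panel:
            pgc_hits = call_orthologues(pgc_panel, genome, criteria, params)
            if pgc_present(pgc_hits, genome):
                accessory.add("pgc")
        stage = "classification"
        genotype = CrtGenotype(genome.strain_name, crt_symbols, frozenset(accessory))
        assignment = predict_phenotype(genotype, graph)
    except Exception as exc:
        raise RuntimeError(f"profiling stage '{stage}' failed for {genome.strain_name}: {exc}") from exc
    return StrainProfile(
        strain=genome.strain_name,
        genotype=genotype,
        hits=hits,
        loci=loci,
        pattern_label=pattern,
        annotations=annotations,
        motifs=motifs,
        assignment=assignment,
        yi=yi,
        status=genome.status,
    )


def write_profile(profile: StrainProfile, outdir) -> list[Path]:
    """Deterministic TSV/diagram outputs for one strain."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    p = outdir / "hits.tsv"
    hits_table(profile.hits).to_csv(p, sep="\t", index=False)
    written.append(p)
    p = outdir / "loci.txt"
    with open(p, "w") as fh:
        fh.write(f"# strain: {profile.strain}\n")
        fh.write(f"# pattern: {profile.pattern_label}\n")
        for key in sorted(profile.annotations):
            fh.write(f"# {key}: {profile.annotations[key]}\n")
        for locus in profile.loci:
            fh.write(locus.diagram() + "\n")
    written.append(p)
    p = outdir / "motifs.tsv"
    profile.motifs.to_csv(p, sep="\t", index=False)
    written.append(p)
    p = outdir / "loci.tsv"
    import pandas as pd

    rows = []
    for i, locus in enumerate(profile.loci, 1):
        for (sym, tag, strand), rel in zip(
            locus.members, [None] + list(locus.adjacencies)
        ):
            rows.append(
                {
                    "locus": i,
                    "replicon": locus.replicon_id,
                    "symbol": sym,
                    "locus_tag": tag,
                    "strand": strand,
                    "overlap_to_previous_bp": None if rel is None else rel.overlap_bp,
                    "gap_to_previous_bp": None if rel is None else rel.gap_bp,
                    "intervening_orfs": None if rel is None else rel.intervening_orfs,
                }
            )
    pd.DataFrame(
        rows,
        columns=["locus", "replicon", "symbol", "locus_tag", "strand",
                 "overlap_to_previous_bp", "gap_to_previous_bp", "intervening_orfs"],
    ).to_csv(p, sep="\t", index=False)
    written.append(p)
    p = outdir / "profile.tsv"
    a = profile.assignment
    rows = [
        ("strain", profile.strain),
        ("genotype", ",".join(sorted(profile.symbols))),
        ("accessory", ",".join(sorted(profile.genotype.accessory))),
        ("group", a.group),
        ("predicted_colour", a.predicted_colour),
        ("predicted_carotenoids", ",".join(sorted(a.predicted_carotenoids))),
        ("terminal_compounds", ",".join(sorted(a.terminal_compounds))),
        ("caveats", ",".join(sorted(a.caveats))),
        ("pattern", profile.pattern_label),
        ("yi_overlap_bp", profile.yi.get("overlap_bp")),
        ("yi_gap_bp", profile.yi.get("gap_bp")),
    ]
    with open(p, "w") as fh:
        for k, v in rows:
            fh.write(f"{k}\t{'' if v is None else v}\n")
    written.append(p)
    return written


@dataclass
class CohortSummary:
    """Cohort-level tallies mirroring the published per-strain table."""

    n_strains: int
    n_complete: int
    symbol_counts: dict[str, int]
    n_with_both_YI: int
    genus_counts: dict[str, int]
    group_counts: dict[str, int]
    yi_summary: Optional[dict] = None

    def to_dict(self) -> dict:
        out = {
            "n_strains": self.n_strains,
            "n_complete": self.n_complete,
            "n_with_both_YI": self.n_with_both_YI,
        }
        for s in sorted(self.symbol_counts):
            out[f"n_with_{s}"] = self.symbol_counts[s]
        for g in sorted(self.group_counts):
            out[f"n_group_{g}"] = self.group_counts[g]
        for g in sorted(self.genus_counts):
            out[f"n_genus_{g}"] = self.genus_counts[g]
        if self.yi_summary:
            out.update({f"yi_{k}": v for k, v in self.yi_summary.items()})
        return out


def cohort_summary(
    cohort: Union[Sequence[StrainProfile], "pandas.DataFrame"],
) -> CohortSummary:
    """Summarise either a list of profiles or a genotype-table fixture.

    Genus is the first whitespace-delimited token of the species name.
    Empty input yields an all-zero summary.
    """
    import pandas as pd

    if isinstance(cohort, pd.DataFrame):
        if len(cohort) == 0:
            return CohortSummary(0, 0, {}, 0, {}, {})
        symbol_counts = {
            s: int(cohort["symbols"].map(lambda x: s in x).sum()) for s in sorted(CRT_SYMBOLS)
        }
        n_yi = int(cohort["symbols"].map(lambda x: {"crtY", "crtI"} <= x).sum())
        return CohortSummary(
            n_strains=len(cohort),
            n_complete=int((cohort["status"] == "complete").sum()),
            symbol_counts=symbol_counts,
            n_with_both_YI=n_yi,
            genus_counts=dict(Counter(cohort["genus"])),
            group_counts=dict(Counter(cohort["group"])),
        )
    profiles = list(cohort)
    if not profiles:
        return CohortSummary(0, 0, {}, 0, {}, {})
    symbol_counts = {
        s: sum(1 for p in profiles if s in p.symbols) for s in sorted(CRT_SYMBOLS)
    }
    genus_counts = dict(Counter(p.strain.split()[0] for p in profiles))
    group_counts = dict(Counter(p.assignment.group for p in profiles))
    return CohortSummary(
        n_strains=len(profiles),
        n_complete=sum(1 for p in profiles if p.status == "complete"),
        symbol_counts=symbol_counts,
        n_with_both_YI=sum(1 for p in profiles if {"crtY", "crtI"} <= p.symbols),
        genus_counts=genus_counts,
        group_counts=group_counts,
        yi_summary=yi_cooccurrence([p.yi for p in profiles]),
    )
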