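"""Chromosomal organisation of crt genes: loci, adjacency, patterns.

A *locus* is a maximal run of crt-orthologue features on one replicon in
which consecutive members are separated by at most ``max_intervening``
annotated CDS and at most ``max_span_gap_bp``.  The recurring architectures
of the *Sphingomonadales* cohort get symbolic labels:

* ``P1_contiguous``     - crtY/I/B/G in one locus, no intervening decoys
* ``P2_crtG_separated`` - crtY/I/B contiguous, crtG in the same locus but
                          1-3 ORFs away (often on the opposite strand)
* ``P3_atypical``       - crtY/I translocated relative to crtB with mixed
                          strands within the locus
* ``P4_YIB_together``   - crtY/I/B co-located, crtG elsewhere (or absent)
* ``P5_YIG_together``   - crtY/I/G co-located, crtB elsewhere
* ``scattered``         - enough genes, but no qualifying co-location
* ``partial``           - fewer than three of crtB/I/Y/G present

Accessory orthologues (the LOG cytokinin phosphoribohydrolase and DUF2141
genes) count as locus members, never as separating ORFs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from crtprofiler.genome_io import CdsFeature, GenomeRecord, MINUS, PLUS

CLUSTER_SYMBOLS = ("crtB", "crtI", "crtY", "crtG")
ACCESSORY_SYMBOLS = frozenset({"log", "duf2141"})

PATTERN_LABELS = (
    "P1_contiguous",
    "P2_crtG_separated",
    "P3_atypical",
    "P4_YIB_together",
    "P5_YIG_together",
    "scattered",
    "partial",
)


@dataclass(frozen=True)
class AdjacencyRelation:
    """Geometric relation between two features, upstream first by start.

    Exactly one of overlap/gap is nonzero unless the ORFs abut exactly.
    ``gap_bp`` is None when the features sit on different replicons
    (infinite distance).
    """

    upstream_tag: str
    downstream_tag: str
    overlap_bp: int
    gap_bp: Optional[int]
    co_oriented: bool
    intervening_orfs: int
    same_replicon: bool = True


@dataclass
class LocusArchitecture:
    """Ordered crt members on one replicon plus their adjacency relations."""

    replicon_id: str
    members: list[tuple[str, str, str]]  # (symbol, locus_tag, strand), by start
    adjacencies: list[AdjacencyRelation] = field(default_factory=list)
    pattern_label: str = "partial"
    annotations: dict[str, bool] = field(default_factory=dict)

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(m[0] for m in self.members)

    def diagram(self) -> str:
        """One-line text map: symbol(strand) joined by overlap/gap glyphs."""
        if not self.members:
            return ""
        parts = [f"{self.members[0][0]}({self.members[0][2]})"]
        for rel, member in zip(self.adjacencies, self.members[1:]):
            if rel.overlap_bp:
                link = f"={rel.overlap_bp}bp_overlap="
            elif rel.gap_bp is not None:
                link = f"--{rel.gap_bp}bp"
                if rel.intervening_orfs:
                    link += f"/{rel.intervening_orfs}orf"
                link += "--"
            else:
                link = "--?--"
            parts.append(link)
            parts.append(f"{member[0]}({member[2]})")
        return "".join(parts)


def adjacency(a: CdsFeature, b: CdsFeature, genome: Optional[GenomeRecord] = None) -> AdjacencyRelation:
    """Interval arithmetic between two features (upstream = smaller start).

    ``intervening_orfs`` counts annotated CDS lying strictly between the two
    (requires ``genome``; 0 otherwise).  Different replicons yield a relation
    with ``same_replicon=False`` and an undefined (None) gap.
    """
    up, down = (a, b) if (a.start, a.end) <= (b.start, b.end) else (b, a)
    if a.replicon_id != b.replicon_id:
        return AdjacencyRelation(
            upstream_tag=up.locus_tag,
            downstream_tag=down.locus_tag,
            overlap_bp=0,
            gap_bp=None,
            co_oriented=a.strand == b.strand and a.strand != "?",
            intervening_orfs=0,
            same_replicon=False,
        )
    overlap = max(0, min(up.end, down.end) - max(up.start, down.start))
    gap = max(0, down.start - up.end)
    intervening = 0
    if genome is not None and overlap == 0:
        for f in genome.sorted_features(up.replicon_id):
            if f.locus_tag in (up.locus_tag, down.locus_tag):
                continue
            if f.start >= up.end and f.end <= down.start:
                intervening += 1
    return AdjacencyRelation(
        upstream_tag=up.locus_tag,
        downstream_tag=down.locus_tag,
        overlap_bp=overlap,
        gap_bp=gap if overlap == 0 else 0,
        co_oriented=a.strand == b.strand and a.strand != "?",
        intervening_orfs=intervening,
    )


def build_loci(
    hits: Mapping[str, "OrthologueHit"],
    genome: GenomeRecord,
    max_intervening: int = 3,
    max_span_gap_bp: int = 10_000,
) -> list[LocusArchitecture]:
    """Group accepted crt hits into loci.

    Consecutive members stay in one locus when separated by at most
    ``max_intervening`` non-member CDS *and* at most ``max_span_gap_bp``.
    Singleton loci are allowed.  The result is ordered by (replicon, start)
    and is invariant to the input ordering of ``hits``.
    """
    tag_to_symbol = {h.subject: sym for sym, h in hits.items() if getattr(h, "accepted", True)}
    member_feats = [
        (f, tag_to_symbol[f.locus_tag])
        for f in genome.sorted_features()
        if f.locus_tag in tag_to_symbol
    ]
    loci: list[LocusArchitecture] = []
    current: list[tuple[CdsFeature, str]] = []

    def flush() -> None:
        if not current:
            return
        members = [(sym, f.locus_tag, f.strand) for f, sym in current]
        rels = [
            adjacency(current[i][0], current[i + 1][0], genome)
            for i in range(len(current) - 1)
        ]
        loci.append(
            LocusArchitecture(
                replicon_id=current[0][0].replicon_id,
                members=members,
                adjacencies=rels,
            )
        )
        current.clear()

    for feat, sym in member_feats:
        if current:
            prev = current[-1][0]
            rel = adjacency(prev, feat, genome)
            if (
                not rel.same_replicon
                or rel.intervening_orfs > max_intervening
                or (rel.gap_bp is not None and rel.gap_bp > max_span_gap_bp)
            ):
                flush()
        current.append((feat, sym))
    flush()
    return loci


def _chain_decoys(locus: LocusArchitecture, sym_a: str, sym_b: str) -> int:
    """Decoy CDS count between two member symbols, walking the member chain.

    Accessory members passed over contribute their flanking decoy counts but
    not themselves.
    """
    idx = {m[0]: i for i, m in enumerate(locus.members)}
    ia, ib = idx[sym_a], idx[sym_b]
    lo, hi = min(ia, ib), max(ia, ib)
    return sum(locus.adjacencies[i].intervening_orfs for i in range(lo, hi))


def classify_architecture(
    loci: Sequence[LocusArchitecture],
    genotype_symbols: Iterable[str],
) -> tuple[str, dict[str, bool]]:
    """Assign the genome-level architecture pattern and annotation flags.

    Pure function of locus membership, order, strand and intervening counts.
    """
    present = frozenset(genotype_symbols)
    n_cluster = sum(1 for s in CLUSTER_SYMBOLS if s in present)
    label = "scattered"

    def locus_with(syms: frozenset[str]) -> Optional[LocusArchitecture]:
        for locus in loci:
            if syms <= locus.symbols:
                return locus
        return None

    yibg = frozenset({"crtY", "crtI", "crtB", "crtG"})
    yib = frozenset({"crtY", "crtI", "crtB"})
    yig = frozenset({"crtY", "crtI", "crtG"})

    if n_cluster < 3:
        label = "partial"
    elif (locus := locus_with(yibg)) is not None:
        order = [m[0] for m in locus.members if m[0] in yibg]
        seps = {
            (a, b): _chain_decoys(locus, a, b) for a, b in zip(order, order[1:])
        }
        strands = {m[0]: m[2] for m in locus.members}
        yib_strands = {strands[s] for s in ("crtY", "crtI", "crtB")}
        if all(v == 0 for v in seps.values()):
            label = "P1_contiguous"
        else:
            # is the Y/I/B trio contiguous with G set apart by 1-3 ORFs?
            trio = [s for s in order if s in yib]
            trio_contig = all(
                _chain_decoys(locus, a, b) == 0 for a, b in zip(trio, trio[1:])
            )
            g_sep = min(
                _chain_decoys(locus, "crtG", s) for s in trio
            )
            if trio_contig and 1 <= g_sep <= 3:
                label = "P2_crtG_separated"
            elif len(yib_strands) > 1:
                label = "P3_atypical"
            else:
                label = "scattered"
    elif (locus := locus_with(yib)) is not None and "crtG" not in locus.symbols:
        label = "P4_YIB_together"
    elif (locus := locus_with(yig)) is not None and "crtB" not in locus.symbols:
        label = "P5_YIG_together"
    else:
        label = "scattered"

    annotations = {
        "log_between_crtI_crtB": False,
        "duf2141_adjacent_crtG": False,
        "crtW_upstream_of_crtZ": False,
        "crtW_downstream_of_crtZ": False,
        "crtX_downstream_of_crtW": False,
    }
    for locus in loci:
        members = locus.members
        pos = {m[0]: i for i, m in enumerate(members)}
        if "crtI" in pos and "crtB" in pos and abs(pos["crtI"] - pos["crtB"]) == 2:
            mid = members[(pos["crtI"] + pos["crtB"]) // 2]
            lo, hi = sorted((pos["crtI"], pos["crtB"]))
            clean = all(locus.adjacencies[i].intervening_orfs == 0 for i in range(lo, hi))
            if mid[0] == "log" and clean:
                annotations["log_between_crtI_crtB"] = True
        if "duf2141" in pos and "crtG" in pos and abs(pos["duf2141"] - pos["crtG"]) == 1:
            i = min(pos["duf2141"], pos["crtG"])
            if locus.adjacencies[i].intervening_orfs == 0:
                annotations["duf2141_adjacent_crtG"] = True
        # "immediately upstream/downstream" is read along the reference
        # gene's direction of transcription (strand-aware convention); the
        # coordinate-order convention is available via relative_position().
        if "crtW" in pos and "crtZ" in pos and abs(pos["crtW"] - pos["crtZ"]) == 1:
            i = min(pos["crtW"], pos["crtZ"])
            if locus.adjacencies[i].intervening_orfs == 0:
                side = relative_position(members, "crtW", "crtZ", strand_aware=True)
                if side == "upstream":
                    annotations["crtW_upstream_of_crtZ"] = True
                elif side == "downstream":
                    annotations["crtW_downstream_of_crtZ"] = True
        if "crtX" in pos and "crtW" in pos and abs(pos["crtX"] - pos["crtW"]) == 1:
            i = min(pos["crtX"], pos["crtW"])
            if locus.adjacencies[i].intervening_orfs == 0:
                if relative_position(members, "crtX", "crtW", strand_aware=True) == "downstream":
                    annotations["crtX_downstream_of_crtW"] = True
    return label, annotations


def relative_position(
    members: Sequence[tuple[str, str, str]],
    subject_sym: str,
    reference_sym: str,
    strand_aware: bool = True,
) -> Optional[str]:
    """Where does ``subject_sym`` sit relative to ``reference_sym``?

    Returns ``"upstream"`` or ``"downstream"``.  With ``strand_aware`` the
    answer is read along the reference gene's direction of transcription
    (a gene at a smaller coordinate is *downstream* of a minus-strand
    reference); otherwise plain genome-coordinate order is used.  Unknown
    reference strand falls back to coordinate order.
    """
    pos = {m[0]: i for i, m in enumerate(members)}
    if subject_sym not in pos or reference_sym not in pos:
        return None
    before = pos[subject_sym] < pos[reference_sym]
    ref_strand = members[pos[reference_sym]][2]
    if strand_aware and ref_strand == MINUS:
        before = not before
    return "upstream" if before else "downstream"


# --- crtY/crtI co-occurrence --------------------------------------------

def yi_record(
    hits: Mapping[str, "OrthologueHit"], genome: GenomeRecord
) -> dict[str, object]:
    """Per-strain crtY-crtI relation record.

    ``co_located`` means same replicon with no annotated CDS between; the
    overlap/gap is then the interval arithmetic of the two reading frames.
    On draft genomes with crtY and crtI on different contigs, co-location is
    never asserted and the overlap is undefined.
    """
    rec: dict[str, object] = {
        "strain": genome.strain_name,
        "both_present": False,
        "co_located": False,
        "co_oriented": False,
        "overlap_bp": None,
        "gap_bp": None,
    }
    if "crtY" not in hits or "crtI" not in hits:
        return rec
    rec["both_present"] = True
    fy = genome.feature_by_tag(hits["crtY"].subject)
    fi = genome.feature_by_tag(hits["crtI"].subject)
    rel = adjacency(fy, fi, genome)
    rec["co_oriented"] = rel.co_oriented
    if rel.same_replicon and rel.intervening_orfs == 0:
        rec["co_located"] = True
        rec["overlap_bp"] = rel.overlap_bp if rel.overlap_bp else None
        rec["gap_bp"] = rel.gap_bp if rel.overlap_bp == 0 else None
    return rec


def yi_cooccurrence(records: Iterable[Mapping[str, object]]) -> dict[str, object]:
    """Cohort-level crtY/crtI summary (counts, modal overlap, gap range)."""
    records = list(records)
    overlaps = [r["overlap_bp"] for r in records if r.get("overlap_bp")]
    gaps = [
        r["gap_bp"]
        for r in records
        if r.get("co_located") and not r.get("overlap_bp") and r.get("gap_bp") is not None
    ]
    modal = Counter(overlaps).most_common(1)[0][0] if overlaps else None
    return {
        "n_strains": len(records),
        "n_both_present": sum(1 for r in records if r["both_present"]),
        "n_co_located": sum(1 for r in records if r["co_located"]),
        "n_co_oriented": sum(1 for r in records if r["both_present"] and r["co_oriented"]),
        "n_overlapping": len(overlaps),
        "n_gapped": len(gaps),
        "modal_overlap_bp": modal,
        "overlap_range_bp": (min(overlaps), max(overlaps)) if overlaps else None,
        "gap_range_bp": (min(gaps), max(gaps)) if gaps else None,
    }


# --- photosynthesis gene cluster heuristic ------------------------------

def pgc_present(
    pgc_hits: Mapping[str, "OrthologueHit"],
    genome: GenomeRecord,
    window_bp: int = 50_000,
    min_hits: int = 6,
) -> bool:
    """Heuristic PGC detection: >= ``min_hits`` accepted photosynthesis-panel
    orthologues falling within one ``window_bp`` window of a single replicon.
    """
    accepted = [h for h in pgc_hits.values() if getattr(h, "accepted", True)]
    if len(accepted) < min_hits:
        return False
    by_replicon: dict[str, list[int]] = {}
    for h in accepted:
        f = genome.feature_by_tag(h.subject)
        by_replicon.setdefault(f.replicon_id, []).append(f.start)
    for starts in by_replicon.values():
        starts.sort()
        for i in range(len(starts)):
            j = i + min_hits - 1
            if j < len(starts) and starts[j] - starts[i] <= window_bp:
                return True
    return False
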