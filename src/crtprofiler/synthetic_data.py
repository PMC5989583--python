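"""Synthetic annotated genomes with planted crt loci and a truth manifest.

Everything here is synthetic: the reference panel is a set of randomly
generated proteins of family-typical lengths with the family's diagnostic
motifs embedded, so no real sequence is ever required.  The generator
emulates the architectures observed in the *Sphingomonadales* cohort
(contiguous and separated crt loci, the crtY-crtI overlap of 1-8 bp or gap
of 6-25 bp, the LOG gene between crtI and crtB, the DUF2141 gene beside
crtG, decoy ORFs, genome G+C in the 0.56-0.68 range) and emits a
ground-truth manifest that recovery tests treat as the oracle.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from crtprofiler.genome_io import CdsFeature, GenomeRecord, MINUS, PLUS, translate_cds
from crtprofiler.homology import AMINO_ACIDS, AlignmentParams, align_proteins
from crtprofiler.genotype_classifier import CrtGenotype, assign_group

# --- reference panel -----------------------------------------------------

#: family-typical protein lengths (aa); CrtE ~300 aa as in GGPP synthases,
#: LOG ~193 aa, desaturases (CrtI) are the longest of the family
FAMILY_LENGTHS = {
    "crtE": 300,
    "crtB": 310,
    "crtI": 490,
    "crtY": 390,
    "crtZ": 162,
    "crtG": 230,
    "crtW": 242,
    "crtX": 410,
    "log": 193,
    "duf2141": 180,
}

#: (pattern fixed positions as {offset: residue}), anchored N-terminally
#: unless the offset is negative (then counted from the C-terminus)
_MOTIF_STAMPS: dict[str, list[tuple[int, str]]] = {
    # GxGxxG(x)19E at offset 8 (within the first 60 residues)
    "crtY": [(8, "G"), (10, "G"), (13, "G"), (8 + 25, "E")],
    # GxGxxG(x)17E at offset 8
    "crtI": [(8, "G"), (10, "G"), (13, "G"), (8 + 23, "E")],
    # PGGxGTxxE
    "log": [(60, "P"), (61, "G"), (62, "G"), (64, "G"), (65, "T"), (68, "E")],
    # HxxHH near N-terminus, HxLHH near C-terminus
    "crtZ": [(20, "H"), (23, "H"), (24, "H"), (-30, "H"), (-28, "L"), (-27, "H"), (-26, "H")],
    # HDxxH plus two HxxHH
    "crtW": [
        (40, "H"), (41, "D"), (44, "H"),
        (100, "H"), (103, "H"), (104, "H"),
        (160, "H"), (163, "H"), (164, "H"),
    ],
    # GKxxR, DDxxxxD, GQxxD, KT, DDxxx
    "crtE": [
        (30, "G"), (31, "K"), (34, "R"),
        (80, "D"), (81, "D"), (86, "D"),
        (120, "G"), (121, "Q"), (124, "D"),
        (150, "K"), (151, "T"),
        (200, "D"), (201, "D"),
    ],
}

#: robust amino-acid background (roughly SwissProt frequencies)
_AA_FREQ = {
    "A": 8.3, "C": 1.4, "D": 5.5, "E": 6.7, "F": 3.9, "G": 7.1, "H": 2.3,
    "I": 5.9, "K": 5.8, "L": 9.7, "M": 2.4, "N": 4.1, "P": 4.7, "Q": 3.9,
    "R": 5.5, "S": 6.6, "T": 5.4, "V": 6.9, "W": 1.1, "Y": 2.9,
}

_PANEL_SEED = 747_031_461  # fixes the synthetic reference panel


def _random_protein(rng: np.random.Generator, length: int) -> str:
    letters = list(_AA_FREQ)
    probs = np.array(list(_AA_FREQ.values()))
    probs = probs / probs.sum()
    body = rng.choice(letters, size=length - 1, p=probs)
    return "M" + "".join(body)


def _stamp_motifs(protein: str, symbol: str) -> str:
    stamps = _MOTIF_STAMPS.get(symbol, [])
    chars = list(protein)
    for off, res in stamps:
        pos = off if off >= 0 else len(chars) + off
        chars[pos] = res
    return "".join(chars)


def reference_panel() -> dict[str, str]:
    """The synthetic crt query panel (deterministic; motifs embedded)."""
    rng = np.random.default_rng(_PANEL_SEED)
    panel = {}
    for symbol in sorted(FAMILY_LENGTHS):
        prot = _random_protein(rng, FAMILY_LENGTHS[symbol])
        panel[symbol] = _stamp_motifs(prot, symbol)
    return panel


def write_panel_fasta(path, panel: Optional[Mapping[str, str]] = None) -> None:
    panel = panel or reference_panel()
    with open(path, "w") as fh:
        for symbol in sorted(panel):
            fh.write(f">{symbol} synthetic reference\n")
            seq = panel[symbol]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# --- controlled-identity mutation ---------------------------------------

def _blosum_partners() -> dict[str, str]:
    """For each residue, the residues scoring >= 0 against it (excluding itself)."""
    from Bio.Align import substitution_matrices

    sm = substitution_matrices.load("BLOSUM62")
    out = {}
    for a in AMINO_ACIDS:
        out[a] = "".join(b for b in AMINO_ACIDS if b != a and sm[a][b] >= 0)
    return out


_PARTNERS: Optional[dict[str, str]] = None


def _mutate(protein: str, n_sub: int, n_indel: int, rng: np.random.Generator) -> str:
    global _PARTNERS
    if _PARTNERS is None:
        _PARTNERS = _blosum_partners()
    chars = list(protein)
    L = len(chars)
    n_sub = min(n_sub, L - 1)
    if n_sub > 0:
        positions = rng.choice(np.arange(1, L), size=n_sub, replace=False)
        for pos in positions:
            orig = chars[pos]
            partners = _PARTNERS.get(orig, "")
            # BLOSUM-plausible half the time, otherwise any different residue
            if partners and rng.random() < 0.5:
                chars[pos] = partners[rng.integers(len(partners))]
            else:
                choices = [a for a in AMINO_ACIDS if a != orig]
                chars[pos] = choices[rng.integers(len(choices))]
    for _ in range(n_indel):
        pos = int(rng.integers(1, len(chars)))
        if rng.random() < 0.5 and len(chars) > 30:
            del chars[pos]
        else:
            chars.insert(pos, AMINO_ACIDS[rng.integers(20)])
    return "".join(chars)


def mutate_to_identity(
    protein: str,
    target: float,
    seed: int,
    params: Optional[AlignmentParams] = None,
    tolerance: float = 0.02,
    stamp_symbol: Optional[str] = None,
) -> tuple[str, float]:
    """Diverge a protein to a target local-alignment identity.

    Substitutions (BLOSUM-plausible) and a limited number of single-residue
    indels are applied until :func:`crtprofiler.homology.align_proteins`
    reports an identity within ``tolerance`` of ``target`` against the
    original.  Deterministic per ``seed``.  With ``stamp_symbol``, the
    family's diagnostic motifs are re-stamped after mutation so planted
    orthologues keep them.

    Returns ``(mutated_protein, realized_identity)``.
    """
    if not (0.15 <= target <= 1.0):
        raise ValueError(f"target identity {target} outside [0.15, 1.0]")
    params = params or AlignmentParams()
    if target >= 1.0:
        return protein, 1.0
    rng = np.random.default_rng(seed)
    L = len(protein)
    n_indel = min(3, max(0, int((1.0 - target) * 8)))
    n_sub = int(round((1.0 - target) * L))
    best: Optional[tuple[float, str]] = None
    for _ in range(40):
        trial_rng = np.random.default_rng(rng.integers(2**31))
        mutated = _mutate(protein, n_sub, n_indel, trial_rng)
        if stamp_symbol is not None:
            mutated = _stamp_motifs(mutated, stamp_symbol)
        realized = align_proteins(protein, mutated, params).identity_fraction
        err = abs(realized - target)
        if best is None or err < abs(best[0] - target):
            best = (realized, mutated)
        if err <= tolerance:
            break
        step = max(1, int(abs(realized - target) * L * 0.7))
        n_sub = n_sub + step if realized > target else max(0, n_sub - step)
    realized, mutated = best[0], best[1]
    return mutated, realized


# --- DNA synthesis -------------------------------------------------------

_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if _CODONS:
        return _CODONS
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[11]
    for codon, aa in table.forward_table.items():
        _CODONS.setdefault(aa, []).append(codon)
    for aa in _CODONS:
        _CODONS[aa].sort()
    return _CODONS


def back_translate(protein: str, rng: np.random.Generator, start_atg: bool = True) -> str:
    """Protein -> CDS DNA under table 11, random synonymous codons, TGA stop."""
    table = _codon_table()
    codons = []
    for i, aa in enumerate(protein):
        if i == 0 and start_atg and aa == "M":
            codons.append("ATG")
            continue
        options = table[aa]
        codons.append(options[rng.integers(len(options))])
    codons.append("TGA")
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    if length <= 0:
        return ""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(["A", "C", "G", "T"], size=length, p=probs))


# --- synthetic genome spec ----------------------------------------------

TEMPLATES = (
    "P1_contiguous",
    "P2_crtG_separated",
    "P3_atypical",
    "P4_YIB_together",
    "P5_YIG_together",
    "scattered",
)

_TEMPLATE_REQUIRES = {
    "P1_contiguous": {"crtB", "crtI", "crtY", "crtG"},
    "P2_crtG_separated": {"crtB", "crtI", "crtY", "crtG"},
    "P3_atypical": {"crtB", "crtI", "crtY", "crtG"},
    "P4_YIB_together": {"crtB", "crtI", "crtY"},
    "P5_YIG_together": {"crtY", "crtI", "crtG"},
    "scattered": set(),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic genome.

    Exactly one of ``yi_overlap_bp`` (1-8, not a multiple of 3) or
    ``yi_gap_bp`` (6-25) applies to the planted crtY-crtI junction.
    ``target_identity`` is the per-gene local-alignment identity of planted
    orthologues versus the reference panel.
    """

    seed: int
    template: str = "P2_crtG_separated"
    genotype: frozenset = frozenset({"crtE", "crtB", "crtI", "crtY", "crtZ", "crtG"})
    target_identity: float = 0.60
    yi_overlap_bp: Optional[int] = 4
    yi_gap_bp: Optional[int] = None
    crtg_intervening: int = 2  # decoys between the Y/I/B block and crtG (P2)
    include_log: bool = True
    include_duf2141: bool = True
    crtw_position: str = "separate"  # separate | upstream_of_crtZ | downstream_of_crtZ
    n_decoy_genes: int = 6
    genome_length: int = 60_000
    gc: float = 0.62

    def __post_init__(self) -> None:
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        missing = _TEMPLATE_REQUIRES[self.template] - set(self.genotype)
        if missing:
            raise ValueError(
                f"template {self.template} requires genes {sorted(missing)} absent "
                f"from the genotype"
            )
        if (self.yi_overlap_bp is None) == (self.yi_gap_bp is None):
            if {"crtY", "crtI"} <= set(self.genotype):
                raise ValueError("exactly one of yi_overlap_bp / yi_gap_bp must be set")
        if self.yi_overlap_bp is not None:
            if not (1 <= self.yi_overlap_bp <= 8):
                raise ValueError("yi_overlap_bp must be in [1, 8]")
            if self.yi_overlap_bp % 3 == 0:
                raise ValueError(
                    "a crtY-crtI overlap that is a multiple of 3 would put the "
                    "upstream stop codon in frame inside crtI"
                )
        if self.yi_gap_bp is not None and not (6 <= self.yi_gap_bp <= 25):
            raise ValueError("yi_gap_bp must be in [6, 25]")
        if not (0.15 <= self.target_identity <= 1.0):
            raise ValueError("target_identity must be in [0.15, 1.0]")
        if not (0.30 <= self.gc <= 0.80):
            raise ValueError("gc fraction out of range")
        if not (0 <= self.crtg_intervening <= 3):
            raise ValueError("crtg_intervening must be 0-3")
        if self.crtw_position not in ("separate", "upstream_of_crtZ", "downstream_of_crtZ"):
            raise ValueError(f"bad crtw_position {self.crtw_position!r}")


@dataclass
class TruthManifest:
    """Ground truth emitted alongside a synthetic genome."""

    strain_name: str
    template: str
    genotype: frozenset
    expected_group: str
    genes: dict[str, dict] = field(default_factory=dict)  # symbol -> planted facts
    yi_overlap_bp: Optional[int] = None
    yi_gap_bp: Optional[int] = None
    log_between_crtI_crtB: bool = False
    duf2141_adjacent_crtG: bool = False
    decoy_tags: tuple[str, ...] = ()

    def to_frame(self):
        import pandas as pd

        rows = []
        for symbol in sorted(self.genes):
            g = self.genes[symbol]
            rows.append({"symbol": symbol, **g})
        return pd.DataFrame(rows)


# --- genome assembly -----------------------------------------------------

class _Assembler:
    def __init__(self, rng: np.random.Generator, gc: float):
        self.rng = rng
        self.gc = gc
        self.chunks: list[str] = []
        self.cursor = 0
        self.genes: list[dict] = []  # symbol, start, end, strand, protein, product

    def spacer(self, lo: int = 50, hi: int = 300) -> None:
        n = int(self.rng.integers(lo, hi + 1))
        self.chunks.append(_random_dna(self.rng, n, self.gc))
        self.cursor += n

    def exact_gap(self, n: int) -> None:
        if n > 0:
            self.chunks.append(_random_dna(self.rng, n, self.gc))
            self.cursor += n

    def add_gene(self, symbol: str, protein: str, strand: str, product: str = "") -> dict:
        dna = back_translate(protein, self.rng)
        if strand == MINUS:
            placed = str(Seq(dna).reverse_complement())
        else:
            placed = dna
        start = self.cursor
        self.chunks.append(placed)
        self.cursor += len(placed)
        info = {
            "symbol": symbol,
            "start": start,
            "end": self.cursor,
            "strand": strand,
            "protein": protein,
            "product": product or symbol,
        }
        self.genes.append(info)
        return info

    def add_overlapping_pair(
        self, sym_up: str, prot_up: str, sym_down: str, prot_down: str, overlap: int
    ) -> tuple[dict, dict, str]:
        """Plant two plus-strand genes whose reading frames overlap.

        The downstream ORF's first ``overlap`` bases are taken from the
        upstream ORF's tail; its first codons (and hence first residues) are
        re-derived from the genome so that DNA and protein stay consistent.
        Retries upstream codon choices until no stop codon lands in the
        forced region.
        """
        n_forced_codons = -(-overlap // 3)  # ceil
        for _ in range(100):
            sub_rng = np.random.default_rng(self.rng.integers(2**31))
            dna_up = back_translate(prot_up, sub_rng)
            tail = dna_up[-overlap:]
            free = 3 * n_forced_codons - overlap
            filler = _random_dna(sub_rng, free, self.gc) if free else ""
            forced = tail + filler
            head_aa = translate_cds(forced) if forced else ""
            if "*" in head_aa:
                continue
            body = back_translate(prot_down[n_forced_codons:], sub_rng, start_atg=False)
            # body carries its own stop; strip the leading-Met special case
            dna_down = forced + body
            final_down = translate_cds(dna_down)
            start_up = self.cursor
            self.chunks.append(dna_up)
            self.cursor += len(dna_up)
            start_down = self.cursor - overlap
            self.chunks.append(dna_down[overlap:])
            self.cursor += len(dna_down) - overlap
            up = {
                "symbol": sym_up, "start": start_up, "end": start_up + len(dna_up),
                "strand": PLUS, "protein": prot_up, "product": sym_up,
            }
            down = {
                "symbol": sym_down, "start": start_down,
                "end": start_down + len(dna_down),
                "strand": PLUS, "protein": final_down, "product": sym_down,
            }
            self.genes.append(up)
            self.genes.append(down)
            return up, down, final_down
        raise RuntimeError("could not realise a stop-free overlap")

    def pad_to(self, length: int) -> None:
        if self.cursor < length:
            self.exact_gap(length - self.cursor)

    def sequence(self) -> str:
        return "".join(self.chunks)


def build_synthetic_genome(spec: SyntheticSpec) -> tuple[GenomeRecord, TruthManifest]:
    """Emit an annotated synthetic genome plus its ground-truth manifest.

    Same spec (same seed) gives byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    panel = reference_panel()
    genotype = frozenset(spec.genotype)
    strain = f"synthetic-{spec.template}-s{spec.seed}"

    # mutated planted proteins (motifs re-stamped after divergence)
    planted: dict[str, tuple[str, float]] = {}
    accessory = set()
    if spec.include_log and {"crtI", "crtB"} <= genotype and spec.template in (
        "P1_contiguous", "P2_crtG_separated", "P4_YIB_together"
    ):
        accessory.add("log")
    if spec.include_duf2141 and "crtG" in genotype:
        accessory.add("duf2141")
    for symbol in sorted(genotype | accessory):
        sym_key = int.from_bytes(hashlib.sha256(symbol.encode()).digest()[:4], "big")
        gene_seed = int(np.random.default_rng([spec.seed, sym_key]).integers(2**31))
        prot, realized = mutate_to_identity(
            panel[symbol], spec.target_identity, gene_seed, stamp_symbol=symbol
        )
        planted[symbol] = (prot, realized)

    asm = _Assembler(rng, spec.gc)
    asm.spacer(200, 500)

    yi_pair_done = False

    def plant(symbol: str, strand: str = PLUS) -> None:
        asm.add_gene(symbol, planted[symbol][0], strand)

    def plant_yi() -> None:
        nonlocal yi_pair_done
        if spec.yi_overlap_bp is not None:
            _, _, final = asm.add_overlapping_pair(
                "crtY", planted["crtY"][0], "crtI", planted["crtI"][0], spec.yi_overlap_bp
            )
            realized = align_proteins(panel["crtI"], final).identity_fraction
            planted["crtI"] = (final, realized)
        else:
            plant("crtY")
            asm.exact_gap(spec.yi_gap_bp)
            plant("crtI")
        yi_pair_done = True

    def tight_gap() -> None:
        asm.exact_gap(int(rng.integers(10, 60)))

    def decoys(n: int, spread_bp: int) -> None:
        per = max(1, spread_bp // max(n, 1))
        for _ in range(n):
            length = int(rng.integers(100, 400))
            prot = _random_protein(rng, length)
            asm.exact_gap(max(50, per - 3 * length))
            asm.add_gene("decoy", prot, PLUS if rng.random() < 0.5 else MINUS,
                         product="hypothetical protein")

    def separator() -> None:
        # > max_intervening decoys and > max_span_gap_bp of distance
        decoys(4, 12_000)
        asm.exact_gap(2_000)

    template = spec.template
    if template in ("P1_contiguous", "P2_crtG_separated"):
        plant_yi()
        if "log" in accessory:
            tight_gap()
            plant("log")
        tight_gap()
        plant("crtB")
        if template == "P2_crtG_separated":
            for _ in range(spec.crtg_intervening):
                tight_gap()
                length = int(rng.integers(100, 300))
                asm.add_gene("decoy", _random_protein(rng, length), PLUS,
                             product="hypothetical protein")
        tight_gap()
        plant("crtG", MINUS)
        if "duf2141" in accessory:
            tight_gap()
            plant("duf2141", MINUS)
    elif template == "P3_atypical":
        plant("crtG")
        if "duf2141" in accessory:
            tight_gap()
            plant("duf2141")
        tight_gap()
        asm.add_gene("decoy", _random_protein(rng, int(rng.integers(100, 300))), PLUS,
                     product="hypothetical protein")
        tight_gap()
        plant_yi()
        tight_gap()
        asm.add_gene("decoy", _random_protein(rng, int(rng.integers(100, 300))), MINUS,
                     product="hypothetical protein")
        tight_gap()
        plant("crtB", MINUS)
    elif template == "P4_YIB_together":
        plant_yi()
        if "log" in accessory:
            tight_gap()
            plant("log")
        tight_gap()
        plant("crtB")
        if "crtG" in genotype:
            separator()
            plant("crtG", MINUS)
            if "duf2141" in accessory:
                tight_gap()
                plant("duf2141", MINUS)
    elif template == "P5_YIG_together":
        plant_yi()
        tight_gap()
        plant("crtG")
        if "duf2141" in accessory:
            tight_gap()
            plant("duf2141")
        if "crtB" in genotype:
            separator()
            plant("crtB", MINUS)
    elif template == "scattered":
        if {"crtY", "crtI"} <= genotype:
            plant_yi()
        elif "crtY" in genotype:
            plant("crtY")
        elif "crtI" in genotype:
            plant("crtI")
        if "crtB" in genotype:
            separator()
            plant("crtB")
        if "crtG" in genotype:
            separator()
            plant("crtG", MINUS)
            if "duf2141" in accessory:
                tight_gap()
                plant("duf2141", MINUS)

    if "crtZ" in genotype:
        separator()
        if "crtW" in genotype and spec.crtw_position == "upstream_of_crtZ":
            plant("crtW")
            tight_gap()
            plant("crtZ")
        elif "crtW" in genotype and spec.crtw_position == "downstream_of_crtZ":
            plant("crtZ")
            tight_gap()
            plant("crtW")
        else:
            plant("crtZ")
        if "crtX" in genotype and "crtW" in genotype and spec.crtw_position != "separate":
            tight_gap()
            plant("crtX")
    if "crtW" in genotype and spec.crtw_position == "separate":
        separator()
        plant("crtW")
        if "crtX" in genotype:
            tight_gap()
            plant("crtX")
    if "crtE" in genotype:
        separator()
        plant("crtE", MINUS)
    if spec.n_decoy_genes:
        separator()
        decoys(spec.n_decoy_genes, 8_000)
    asm.spacer(500, 1000)
    asm.pad_to(spec.genome_length)

    sequence = asm.sequence()
    replicon_id = f"SYNREP{spec.seed % 100_000:05d}"
    features: list[CdsFeature] = []
    tag_of: dict[str, str] = {}
    decoy_tags: list[str] = []
    for i, g in enumerate(sorted(asm.genes, key=lambda d: d["start"]), 1):
        tag = f"SYN_{i:04d}"
        if g["symbol"] == "decoy":
            decoy_tags.append(tag)
        else:
            tag_of[g["symbol"]] = tag
        features.append(
            CdsFeature(
                locus_tag=tag,
                replicon_id=replicon_id,
                start=g["start"],
                end=g["end"],
                strand=g["strand"],
                product=g["product"],
                protein=g["protein"],
            )
        )
    record = GenomeRecord(
        strain_name=strain,
        replicons={replicon_id: (len(sequence), sequence)},
        features=features,
        status="complete",
    )

    group = assign_group(CrtGenotype(strain, genotype)).group
    manifest = TruthManifest(
        strain_name=strain,
        template=spec.template,
        genotype=genotype,
        expected_group=group,
        yi_overlap_bp=spec.yi_overlap_bp if yi_pair_done and spec.yi_overlap_bp else None,
        yi_gap_bp=spec.yi_gap_bp if yi_pair_done and spec.yi_gap_bp else None,
        log_between_crtI_crtB="log" in accessory,
        duf2141_adjacent_crtG="duf2141" in accessory,
        decoy_tags=tuple(decoy_tags),
    )
    for symbol in sorted(genotype | accessory):
        f = record.feature_by_tag(tag_of[symbol])
        manifest.genes[symbol] = {
            "locus_tag": f.locus_tag,
            "start": f.start,
            "end": f.end,
            "strand": f.strand,
            "realized_identity": round(planted[symbol][1], 4),
        }
    return record, manifest


# --- cohort fixture ------------------------------------------------------

_COHORT_SHA256 = "2cc07f8963a258d1b99807dc162b672cd7c6de83a3ce0f672f8743a9a9a8abfb"


def build_cohort_fixture():
    """Load the packaged 41-strain cohort table (genotype/group/colour).

    The file's checksum is verified so silent edits surface as an integrity
    error.  Returns a pandas DataFrame with columns serial, species, strain,
    status, genotype, group, colour, pgc, plus a parsed ``symbols`` column of
    crt gene sets and a ``genus`` column (first word of the species name).
    """
    import pandas as pd

    ref = importlib.resources.files("crtprofiler").joinpath(
        "data/sphingomonadales_cohort.tsv"
    )
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _COHORT_SHA256:
        raise RuntimeError(
            "cohort fixture checksum mismatch: the packaged table was modified"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t", dtype={"pgc": int})
    from crtprofiler.genotype_classifier import SHORT_TO_SYMBOL

    df["symbols"] = df["genotype"].map(
        lambda s: frozenset(SHORT_TO_SYMBOL[x.strip()] for x in s.split(","))
    )
    df["genus"] = df["species"].str.split().str[0]
    return df
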