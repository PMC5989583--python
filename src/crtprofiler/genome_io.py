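"""Genome parsing and writing with explicit coordinate conventions.

Internal coordinates are 0-based half-open throughout the package; the
1-based inclusive convention of GenBank (and GFF3) is converted exactly once
at the parse/write boundary.  Two on-disk dialects are supported: GenBank
flat files (via Biopython) and a GFF3+FASTA pair in the package's own
documented dialect (CDS lines carrying ``locus_tag``, ``product`` and
``translation`` attributes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence
from urllib.parse import quote, unquote

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

PLUS = "+"
MINUS = "-"
UNKNOWN = "?"

_STRANDS = (PLUS, MINUS, UNKNOWN)


class GenomeFormatError(ValueError):
    """Raised when a genome file cannot be parsed under a supported dialect."""


@dataclass
class CdsFeature:
    """One annotated coding sequence.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    replicon; ``protein`` is the amino-acid sequence without a stop symbol.
    """

    locus_tag: str
    replicon_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein: str = ""
    compound_location: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.locus_tag}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"{self.locus_tag}: strand must be one of {_STRANDS}")

    @property
    def nucleotide_length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """An annotated genome: replicons plus CDS features.

    ``replicons`` maps replicon id -> (length bp, nucleotide sequence or None).
    ``status`` mirrors the "genome status" notion of public genome records:
    ``complete`` or ``draft`` (multi-contig assemblies).
    """

    strain_name: str
    replicons: dict[str, tuple[int, Optional[str]]]
    features: list[CdsFeature] = field(default_factory=list)
    status: str = "complete"

    def __post_init__(self) -> None:
        if self.status not in ("complete", "draft"):
            raise ValueError(f"status must be complete/draft, got {self.status!r}")
        self.validate()

    def validate(self) -> None:
        tags = [f.locus_tag for f in self.features]
        if len(tags) != len(set(tags)):
            dupes = sorted({t for t in tags if tags.count(t) > 1})
            raise ValueError(f"duplicate locus_tags: {dupes}")
        for f in self.features:
            if f.replicon_id not in self.replicons:
                raise ValueError(f"{f.locus_tag}: undeclared replicon {f.replicon_id!r}")
            length = self.replicons[f.replicon_id][0]
            if f.end > length:
                raise ValueError(
                    f"{f.locus_tag}: feature end {f.end} beyond replicon "
                    f"{f.replicon_id} length {length}"
                )

    def sorted_features(self, replicon_id: Optional[str] = None) -> list[CdsFeature]:
        feats = self.features
        if replicon_id is not None:
            feats = [f for f in feats if f.replicon_id == replicon_id]
        return sorted(feats, key=lambda f: (f.replicon_id, f.start, f.end, f.locus_tag))

    def feature_by_tag(self, locus_tag: str) -> CdsFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)

    def proteome(self) -> dict[str, str]:
        """locus_tag -> protein for every feature with a protein sequence."""
        return {f.locus_tag: f.protein for f in self.sorted_features() if f.protein}


# --- translation ---------------------------------------------------------

def translate_cds(nucleotides: str) -> str:
    """Translate a CDS under the bacterial/archaeal code (table 11).

    The trailing stop codon, if present, is removed.  The first residue is
    reported as annotated by the codon itself (no forced Met), matching how
    alternative starts (GTG/TTG) appear in public proteomes after curation.
    """
    prot = str(Seq(nucleotides).translate(table=11))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


# --- GenBank -------------------------------------------------------------

def _strand_from_biopython(s: Optional[int]) -> str:
    if s == 1:
        return PLUS
    if s == -1:
        return MINUS
    return UNKNOWN


def _parse_genbank(path: Path) -> GenomeRecord:
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise GenomeFormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not seq_records:
        raise GenomeFormatError(f"{path}: no GenBank records found")
    replicons: dict[str, tuple[int, Optional[str]]] = {}
    features: list[CdsFeature] = []
    strain = seq_records[0].annotations.get("source", "") or seq_records[0].id
    n_auto = 0
    for rec in seq_records:
        seq = str(rec.seq) if len(rec.seq) and not _is_undefined(rec.seq) else None
        replicons[rec.id] = (len(rec.seq), seq)
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            tag = feat.qualifiers.get("locus_tag", [None])[0]
            if tag is None:
                n_auto += 1
                tag = f"CDS_{rec.id}_{n_auto}"
            product = feat.qualifiers.get("product", [""])[0]
            translation = feat.qualifiers.get("translation", [None])[0]
            compound = len(feat.location.parts) > 1
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = _strand_from_biopython(feat.location.strand)
            protein = translation
            if protein is None:
                if compound:
                    logger.warning("%s: compound CDS without /translation skipped", tag)
                    continue
                if seq is None:
                    logger.warning(
                        "%s: CDS lacks /translation and record lacks sequence; skipped", tag
                    )
                    continue
                cds_nt = seq[start:end]
                if strand == MINUS:
                    cds_nt = str(Seq(cds_nt).reverse_complement())
                protein = translate_cds(cds_nt)
            features.append(
                CdsFeature(
                    locus_tag=tag,
                    replicon_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=product,
                    protein=protein,
                    compound_location=compound,
                )
            )
    status = "draft" if len(replicons) > 1 else "complete"
    return GenomeRecord(strain_name=strain, replicons=replicons, features=features, status=status)


def _is_undefined(seq) -> bool:
    try:
        bytes(seq)
    except Exception:
        return True
    return False


# --- GFF3 + FASTA dialect ------------------------------------------------
#
# One CDS per line; columns per the GFF3 standard; attributes used:
#   ID (= locus_tag), locus_tag, product, translation.
# Strand '.' encodes the unknown-strand case seen in draft genomes.

def _parse_gff3(gff_path: Path, fasta_path: Optional[Path]) -> GenomeRecord:
    replicons: dict[str, tuple[int, Optional[str]]] = {}
    if fasta_path is not None and fasta_path.exists():
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            replicons[rec.id] = (len(rec.seq), str(rec.seq))
    features: list[CdsFeature] = []
    declared: dict[str, int] = {}
    strain = gff_path.stem
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    declared[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                if line.startswith("##strain"):
                    strain = line.split(None, 1)[1].strip()
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(f"{gff_path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start1, end1, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            attr = dict(
                (kv.split("=", 1) + [""])[:2] for kv in attrs.split(";") if kv
            )
            tag = unquote(attr.get("locus_tag") or attr.get("ID") or f"CDS_{lineno}")
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError as exc:
                raise GenomeFormatError(f"{gff_path}:{lineno}: bad coordinates") from exc
            strand_sym = {"+": PLUS, "-": MINUS, ".": UNKNOWN, "?": UNKNOWN}.get(strand)
            if strand_sym is None:
                raise GenomeFormatError(f"{gff_path}:{lineno}: bad strand {strand!r}")
            protein = unquote(attr.get("translation", ""))
            if not protein:
                seq = replicons.get(seqid, (0, None))[1]
                if seq is None:
                    logger.warning("%s: CDS lacks translation and sequence; skipped", tag)
                    continue
                cds_nt = seq[start:end]
                if strand_sym == MINUS:
                    cds_nt = str(Seq(cds_nt).reverse_complement())
                protein = translate_cds(cds_nt)
            features.append(
                CdsFeature(
                    locus_tag=tag,
                    replicon_id=seqid,
                    start=start,
                    end=end,
                    strand=strand_sym,
                    product=unquote(attr.get("product", "")),
                    protein=protein,
                )
            )
    for rid, length in declared.items():
        if rid not in replicons:
            replicons[rid] = (length, None)
    for f in features:
        if f.replicon_id not in replicons:
            replicons[f.replicon_id] = (max(g.end for g in features if g.replicon_id == f.replicon_id), None)
    status = "draft" if len(replicons) > 1 else "complete"
    return GenomeRecord(strain_name=strain, replicons=replicons, features=features, status=status)


def parse_genome(path, format_hint: str = "auto") -> GenomeRecord:
    """Parse an annotated genome into a :class:`GenomeRecord`.

    Parameters
    ----------
    path
        A GenBank flat file, or a GFF3 file with an optional sibling FASTA
        (same stem, ``.fasta``/``.fa``/``.fna`` suffix).
    format_hint
        ``genbank``, ``gff3`` (alias ``gff3+fasta``) or ``auto``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hint = format_hint
    if hint == "auto":
        suffix = path.suffix.lower()
        if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
            hint = "genbank"
        elif suffix in (".gff", ".gff3"):
            hint = "gff3"
        else:
            with open(path) as fh:
                first = fh.readline()
            hint = "genbank" if first.startswith("LOCUS") else "gff3"
    if hint == "genbank":
        return _parse_genbank(path)
    if hint in ("gff3", "gff3+fasta"):
        fasta = None
        for ext in (".fasta", ".fa", ".fna"):
            cand = path.with_suffix(ext)
            if cand.exists():
                fasta = cand
                break
        return _parse_gff3(path, fasta)
    raise ValueError(f"unknown format hint {format_hint!r}")


# --- writing -------------------------------------------------------------

def write_genome(record: GenomeRecord, path, format: str = "gff3+fasta") -> list[Path]:
    """Write a :class:`GenomeRecord` back to disk.

    Round-trip contract: ``parse_genome(write_genome(r))`` reproduces every
    :class:`CdsFeature` field.  For GenBank output, features with unknown
    strand cannot be represented and raise a ``ValueError``.
    Returns the list of files written.
    """
    record.validate()
    path = Path(path)
    if format == "genbank":
        return [_write_genbank(record, path)]
    if format in ("gff3", "gff3+fasta"):
        return _write_gff3(record, path)
    raise ValueError(f"unknown output format {format!r}")


def _write_genbank(record: GenomeRecord, path: Path) -> Path:
    seq_records = []
    for rid, (length, seq) in record.replicons.items():
        if seq is None:
            seq = "N" * length
        rec = SeqRecord(Seq(seq), id=rid, name=rid[:16], description=record.strain_name)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["source"] = record.strain_name
        for f in record.sorted_features(rid):
            if f.strand == UNKNOWN:
                raise ValueError(
                    f"{f.locus_tag}: unknown strand not representable in GenBank; "
                    "use the gff3+fasta dialect"
                )
            loc = FeatureLocation(f.start, f.end, strand=1 if f.strand == PLUS else -1)
            quals = {"locus_tag": [f.locus_tag], "transl_table": ["11"]}
            if f.product:
                quals["product"] = [f.product]
            if f.protein:
                quals["translation"] = [f.protein]
            rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
        seq_records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "genbank")
    return path


def _write_gff3(record: GenomeRecord, path: Path) -> list[Path]:
    path = Path(path)
    if path.suffix.lower() not in (".gff", ".gff3"):
        path = path.with_suffix(".gff3")
    fasta_path = path.with_suffix(".fasta")
    lines = ["##gff-version 3", f"##strain {record.strain_name}"]
    have_seq = False
    for rid, (length, seq) in sorted(record.replicons.items()):
        lines.append(f"##sequence-region {rid} 1 {length}")
        have_seq = have_seq or seq is not None
    strand_out = {PLUS: "+", MINUS: "-", UNKNOWN: "."}
    for f in record.sorted_features():
        attrs = [f"ID={quote(f.locus_tag)}", f"locus_tag={quote(f.locus_tag)}"]
        if f.product:
            attrs.append(f"product={quote(f.product)}")
        if f.protein:
            attrs.append(f"translation={f.protein}")
        lines.append(
            "\t".join(
                [
                    f.replicon_id,
                    "crtprofiler",
                    "CDS",
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    strand_out[f.strand],
                    "0",
                    ";".join(attrs),
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    written = [path]
    if have_seq:
        with open(fasta_path, "w") as fh:
            for rid, (length, seq) in sorted(record.replicons.items()):
                fh.write(f">{rid}\n")
                seq = seq if seq is not None else "N" * length
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        written.append(fasta_path)
    return written


# --- optional start-codon curation --------------------------------------

START_CODON_PREFERENCE = ("ATG", "GTG", "TTG", "CTG")


def curate_start_codon(
    feature: CdsFeature,
    record: GenomeRecord,
    max_extension: int = 90,
    preference: Sequence[str] = START_CODON_PREFERENCE,
) -> CdsFeature:
    """Optionally re-assign a CDS start to an upstream in-frame candidate.

    Mirrors the common manual curation of bacterial gene starts: candidate
    start codons are sought in-frame upstream of the annotated start (within
    ``max_extension`` bp, without crossing an in-frame stop), preferring
    codon types in the given order (default ATG > GTG > TTG > CTG) and, within
    a type, the candidate nearest the annotated start.  Returns a new feature
    (possibly identical).  Requires the replicon nucleotide sequence.
    """
    seq = record.replicons[feature.replicon_id][1]
    if seq is None:
        raise ValueError("start-codon curation requires the nucleotide sequence")
    stops = {"TAA", "TAG", "TGA"}
    candidates: dict[str, int] = {}
    if feature.strand == PLUS:
        for off in range(3, max_extension + 1, 3):
            pos = feature.start - off
            if pos < 0:
                break
            codon = seq[pos : pos + 3].upper()
            if codon in stops:
                break
            if codon in preference and codon not in candidates:
                candidates[codon] = pos
    elif feature.strand == MINUS:
        for off in range(3, max_extension + 1, 3):
            pos = feature.end + off
            if pos > len(seq):
                break
            codon = str(Seq(seq[pos - 3 : pos]).reverse_complement()).upper()
            if codon in stops:
                break
            if codon in preference and codon not in candidates:
                candidates[codon] = pos
    if not candidates:
        return feature
    for codon in preference:
        if codon in candidates:
            pos = candidates[codon]
            if feature.strand == PLUS:
                new_start, new_end = pos, feature.end
                nt = seq[new_start:new_end]
            else:
                new_start, new_end = feature.start, pos
                nt = str(Seq(seq[new_start:new_end]).reverse_complement())
            return CdsFeature(
                locus_tag=feature.locus_tag,
                replicon_id=feature.replicon_id,
                start=new_start,
                end=new_end,
                strand=feature.strand,
                product=feature.product,
                protein=translate_cds(nt),
            )
    return feature
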