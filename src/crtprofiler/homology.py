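"""Orthologue identification by local protein alignment.

The search re-creates a blastp-style screen without heuristics: every
candidate protein is aligned to every query with full Smith-Waterman
dynamic programming (affine gaps, BLOSUM62 by default), raw scores are
converted to bit scores and E-values with Karlin-Altschul statistics, and a
candidate is accepted as an orthologue only if it simultaneously shows

* identity >= 30 % (over all alignment columns, gaps included),
* length difference < 20 % of the query length,
* bit score >= 50, and
* E-value < 1e-10,

with the best accepted candidate per query chosen by highest identity
(ties: higher bit score, then lexicographically smallest locus tag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

try:
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = AMINO_ACIDS + "X"
_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}


def _build_matrix(name: str) -> np.ndarray:
    """21x21 integer score matrix over AMINO_ACIDS + X; X scores 0 vs all."""
    sm = substitution_matrices.load(name)
    n = len(_ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            mat[i, j] = int(sm[a][b])
    return mat


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme plus Karlin-Altschul statistical parameters.

    Defaults are the published constants for gapped BLOSUM62 with gap
    open 11 / extend 1 (lambda = 0.267, K = 0.041).  A gap of length L costs
    ``gap_open + L * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    @property
    def matrix(self) -> np.ndarray:
        key = self.matrix_name
        if key not in _MATRIX_CACHE:
            _MATRIX_CACHE[key] = _build_matrix(key)
        return _MATRIX_CACHE[key]


_MATRIX_CACHE: dict[str, np.ndarray] = {}


@dataclass(frozen=True)
class ProteinAlignment:
    """Result of one local alignment.

    ``identity_fraction`` uses all alignment columns (gap columns included in
    the denominator).  Spans are half-open intervals on query and subject.
    """

    raw_score: int
    bit_score: float
    e_value: float
    identity_fraction: float
    alignment_length: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    query_aligned: str = ""
    subject_aligned: str = ""


@dataclass(frozen=True)
class OrthologyCriteria:
    """The composite acceptance thresholds for an orthologue call.

    ``min_identity`` and ``min_bit_score`` are inclusive bounds;
    ``max_length_difference`` and ``max_e_value`` are strict.
    """

    min_identity: float = 0.30
    max_length_difference: float = 0.20
    min_bit_score: float = 50.0
    max_e_value: float = 1e-10

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if not (0 < self.max_length_difference <= 1):
            raise ValueError("max_length_difference must be in (0, 1]")
        if self.min_bit_score < 0:
            raise ValueError("min_bit_score must be >= 0")
        if self.max_e_value <= 0:
            raise ValueError("max_e_value must be > 0")


@dataclass
class OrthologueHit:
    """A crt gene call on one genome."""

    query_name: str
    subject: str
    alignment: ProteinAlignment
    length_difference: float
    accepted: bool
    rejection_reasons: frozenset[str] = frozenset()


def encode(protein: str) -> np.ndarray:
    """Encode a protein into alphabet indices, validating residues."""
    if not protein:
        raise ValueError("empty protein sequence")
    out = np.empty(len(protein), dtype=np.int8)
    for i, aa in enumerate(protein.upper()):
        idx = _INDEX.get(aa)
        if idx is None:
            raise ValueError(f"unknown residue {aa!r} at position {i}")
        out[i] = idx
    return out


@njit(cache=True)
def _sw_fill(q, s, mat, open_ext, ext):  # pragma: no cover - jit-compiled
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -10**9, dtype=np.int32)  # gap in query (left)
    F = np.full((m + 1, n + 1), -10**9, dtype=np.int32)  # gap in subject (up)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - open_ext
            if E[i, j - 1] - ext > e:
                e = E[i, j - 1] - ext
            E[i, j] = e
            f = H[i - 1, j] - open_ext
            if F[i - 1, j] - ext > f:
                f = F[i - 1, j] - ext
            F[i, j] = f
            h = H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def _sw_fill_py(q, s, mat, open_ext, ext):
    """Pure-Python fallback mirroring :func:`_sw_fill` (used without numba)."""
    m, n = len(q), len(s)
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - open_ext, E[i, j - 1] - ext)
            F[i, j] = max(H[i - 1, j] - open_ext, F[i - 1, j] - ext)
            h = max(0, H[i - 1, j - 1] + int(mat[q[i - 1], s[j - 1]]), E[i, j], F[i, j])
            H[i, j] = h
            if h > best:
                best, bi, bj = h, i, j
    return H, E, F, best, bi, bj


def align_proteins(
    query: str, subject: str, params: Optional[AlignmentParams] = None
) -> ProteinAlignment:
    """Optimal Smith-Waterman local alignment of two proteins.

    Traceback is deterministic; score ties are resolved diagonal > up
    (gap in subject) > left (gap in query).  The identity fraction counts
    identical columns over all alignment columns, gaps included.
    """
    params = params or AlignmentParams()
    q = encode(query)
    s = encode(subject)
    mat = params.matrix
    open_ext = params.gap_open + params.gap_extend
    ext = params.gap_extend
    fill = _sw_fill if _HAVE_NUMBA else _sw_fill_py
    H, E, F, best, bi, bj = fill(q, s, mat, open_ext, ext)
    best = int(best)
    m, n = len(q), len(s)
    bit, ev = evalue(best, params, m, n)
    if best == 0:
        return ProteinAlignment(0, bit, ev, 0.0, 0, (0, 0), (0, 0), "", "")
    # traceback from (bi, bj) until H == 0
    i, j = int(bi), int(bj)
    qa: list[str] = []
    sa: list[str] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            diag = H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]
            if h == diag:
                qa.append(query[i - 1])
                sa.append(subject[j - 1])
                i -= 1
                j -= 1
                continue
            if h == F[i, j]:
                state = "F"
                continue
            state = "E"
            continue
        if state == "F":  # gap in subject: consume query residue
            qa.append(query[i - 1])
            sa.append("-")
            if F[i, j] == H[i - 1, j] - open_ext:
                state = "H"
            i -= 1
            continue
        # state == "E": gap in query: consume subject residue
        qa.append("-")
        sa.append(subject[j - 1])
        if E[i, j] == H[i, j - 1] - open_ext:
            state = "H"
        j -= 1
    qa.reverse()
    sa.reverse()
    q_aln = "".join(qa)
    s_aln = "".join(sa)
    length = len(q_aln)
    ident = sum(1 for a, b in zip(q_aln, s_aln) if a == b and a != "-")
    return ProteinAlignment(
        raw_score=best,
        bit_score=bit,
        e_value=ev,
        identity_fraction=ident / length if length else 0.0,
        alignment_length=length,
        query_span=(i, int(bi)),
        subject_span=(j, int(bj)),
        query_aligned=q_aln,
        subject_aligned=s_aln,
    )


def evalue(
    raw_score: int, params: Optional[AlignmentParams] = None, m: int = 1, n: int = 1
) -> tuple[float, float]:
    """Karlin-Altschul bit score and E-value for a raw alignment score.

    bit = (lambda * S - ln K) / ln 2;  E = m * n * 2**(-bit), with m the
    query length and n the search-space (summed database) length.
    """
    params = params or AlignmentParams()
    if m < 1 or n < 1:
        raise ValueError("sequence/search-space lengths must be >= 1")
    bit = (params.lam * raw_score - math.log(params.K)) / math.log(2.0)
    # compute in log space to avoid overflow for huge scores
    log2_e = math.log2(float(m)) + math.log2(float(n)) - bit
    ev = 2.0 ** log2_e if log2_e > -1000 else 0.0
    return bit, ev


def apply_criteria(
    alignment: ProteinAlignment,
    query_length: int,
    subject_length: int,
    criteria: Optional[OrthologyCriteria] = None,
) -> tuple[float, frozenset[str]]:
    """Evaluate the four orthology criteria; returns (length_difference, reasons).

    An empty reason set means the candidate passes.
    """
    criteria = criteria or OrthologyCriteria()
    reasons = set()
    if alignment.identity_fraction < criteria.min_identity:
        reasons.add("min_identity")
    length_difference = abs(query_length - subject_length) / query_length
    if length_difference >= criteria.max_length_difference:
        reasons.add("max_length_difference")
    if alignment.bit_score < criteria.min_bit_score:
        reasons.add("min_bit_score")
    if alignment.e_value >= criteria.max_e_value:
        reasons.add("max_e_value")
    return length_difference, frozenset(reasons)


def load_panel(path) -> dict[str, str]:
    """Read a query panel multi-FASTA; the header's first token is the gene symbol."""
    panel: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        symbol = rec.id.split()[0]
        if symbol in panel:
            raise ValueError(f"duplicate panel symbol {symbol!r}")
        panel[symbol] = str(rec.seq)
    if not panel:
        raise ValueError(f"{path}: empty query panel")
    return panel


def call_orthologues(
    panel: Mapping[str, str],
    genome,
    criteria: Optional[OrthologyCriteria] = None,
    params: Optional[AlignmentParams] = None,
    keep_rejected: bool = False,
) -> dict[str, OrthologueHit]:
    """Screen a genome's proteome against a named query panel.

    Returns a mapping gene symbol -> best accepted :class:`OrthologueHit`;
    symbols with no accepted candidate are absent.  With ``keep_rejected``,
    the best rejected candidate (by identity) is returned for absent symbols,
    carrying its rejection reasons.

    The E-value search space is the summed proteome length, mirroring a
    database search over one proteome.
    """
    if not panel:
        raise ValueError("empty query panel")
    criteria = criteria or OrthologyCriteria()
    params = params or AlignmentParams()
    proteome = genome.proteome() if hasattr(genome, "proteome") else dict(genome)
    hits: dict[str, OrthologueHit] = {}
    if not proteome:
        return hits
    search_space = sum(len(p) for p in proteome.values())
    for symbol in sorted(panel):
        query = panel[symbol]
        best_accepted: Optional[OrthologueHit] = None
        best_rejected: Optional[OrthologueHit] = None
        for tag in sorted(proteome):
            subject = proteome[tag]
            if not subject:
                continue
            aln = align_proteins(query, subject, params)
            # E-value against the whole proteome as the search space
            bit, ev = evalue(aln.raw_score, params, len(query), search_space)
            aln = ProteinAlignment(
                aln.raw_score, bit, ev, aln.identity_fraction, aln.alignment_length,
                aln.query_span, aln.subject_span, aln.query_aligned, aln.subject_aligned,
            )
            ldiff, reasons = apply_criteria(aln, len(query), len(subject), criteria)
            hit = OrthologueHit(
                query_name=symbol,
                subject=tag,
                alignment=aln,
                length_difference=ldiff,
                accepted=not reasons,
                rejection_reasons=reasons,
            )
            if hit.accepted:
                if best_accepted is None or _better(hit, best_accepted):
                    best_accepted = hit
            else:
                if best_rejected is None or _better(hit, best_rejected):
                    best_rejected = hit
        if best_accepted is not None:
            hits[symbol] = best_accepted
        elif keep_rejected and best_rejected is not None:
            hits[symbol] = best_rejected
    return hits


def _better(a: OrthologueHit, b: OrthologueHit) -> bool:
    """Candidate ordering: identity desc, bit score desc, locus tag asc."""
    ka = (-a.alignment.identity_fraction, -a.alignment.bit_score, a.subject)
    kb = (-b.alignment.identity_fraction, -b.alignment.bit_score, b.subject)
    return ka < kb


def hits_table(hits: Mapping[str, OrthologueHit]):
    """Per-genome hit table as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for symbol in sorted(hits):
        h = hits[symbol]
        rows.append(
            {
                "symbol": symbol,
                "locus_tag": h.subject,
                "identity": round(h.alignment.identity_fraction, 4),
                "bit_score": round(h.alignment.bit_score, 2),
                "e_value": f"{h.alignment.e_value:.3e}",
                "length_difference": round(h.length_difference, 4),
                "accepted": h.accepted,
                "reasons": ",".join(sorted(h.rejection_reasons)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "symbol", "locus_tag", "identity", "bit_score",
            "e_value", "length_difference", "accepted", "reasons",
        ],
    )
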