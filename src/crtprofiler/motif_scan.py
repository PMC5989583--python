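"""Diagnostic protein motif compilation and scanning.

Motif notation follows the compact style used in the carotenogenesis
literature: fixed residue letters, ``x`` for any residue, and ``(x)19`` (or
``(x)_19``) for an exact run of wildcards.  Examples from the Crt families:

* CrtY: ``GxGxxG(x)19E``  (FAD-binding, N-terminal)
* CrtI: ``GxGxxG(x)17E``  (FAD-binding, N-terminal)
* LOG:  ``PGGxGTxxE``
* CrtZ: ``HxxHH`` (N-terminal) and ``HxLHH`` (C-terminal)
* CrtW: ``HDxxH``, ``HxxHH`` (x2) -- all three required for ketolase activity
* CrtE: ``GKxxR``, ``DDxxxxD``, ``GQxxD``, ``KT``, ``DDxxx``

Motif presence is reported as corroboration only; it never vetoes an
orthologue call.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

ANYWHERE = "anywhere"
N_TERMINAL = "n_terminal"
C_TERMINAL = "c_terminal"

#: default width of the "near the terminus" window, in residues
DEFAULT_TERMINAL_WINDOW = 60


class MotifSyntaxError(ValueError):
    """Malformed motif pattern; carries the offending position."""

    def __init__(self, pattern: str, pos: int, message: str):
        super().__init__(f"{pattern!r}: {message} at position {pos}")
        self.pattern = pattern
        self.pos = pos


@dataclass(frozen=True)
class Motif:
    """A compiled motif: per-position residue constraints plus a region."""

    name: str
    pattern: str
    positions: tuple[Optional[str], ...]  # fixed residue or None for wildcard
    region: str = ANYWHERE
    window: int = DEFAULT_TERMINAL_WINDOW

    @property
    def compiled_length(self) -> int:
        return len(self.positions)

    def to_text(self) -> str:
        """Round-trip the compiled positions back to pattern text."""
        out: list[str] = []
        run = 0
        for p in self.positions:
            if p is None:
                run += 1
                continue
            if run:
                out.append("x" * run if run < 3 else f"(x){run}")
                run = 0
            out.append(p)
        if run:
            out.append("x" * run if run < 3 else f"(x){run}")
        return "".join(out)


@dataclass(frozen=True)
class MotifMatch:
    motif_name: str
    locus_tag: str
    start: int  # 0-based offset into the protein
    matched: str


_RUN_RE = re.compile(r"\(x\)_?(\d+)")


def compile_motif(
    pattern: str,
    name: Optional[str] = None,
    region: str = ANYWHERE,
    window: int = DEFAULT_TERMINAL_WINDOW,
) -> Motif:
    """Compile a motif pattern into a position-wise matcher.

    ``(x)n`` and ``(x)_n`` are both accepted for a run of exactly *n*
    wildcards; a bare ``x`` is a single wildcard.  ``GxGxxG(x)17E`` compiles
    to length 6 + 17 + 1 = 24.
    """
    if region not in (ANYWHERE, N_TERMINAL, C_TERMINAL):
        raise ValueError(f"unknown region constraint {region!r}")
    positions: list[Optional[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "(":
            m = _RUN_RE.match(pattern, i)
            if not m:
                raise MotifSyntaxError(pattern, i, "expected '(x)n'")
            n = int(m.group(1))
            if n < 1:
                raise MotifSyntaxError(pattern, i, "wildcard run must be >= 1")
            positions.extend([None] * n)
            i = m.end()
        elif ch == "x":
            positions.append(None)
            i += 1
        elif ch.isalpha() and ch.isupper():
            positions.append(ch)
            i += 1
        else:
            raise MotifSyntaxError(pattern, i, f"unexpected character {ch!r}")
    if not positions:
        raise MotifSyntaxError(pattern, 0, "empty pattern")
    return Motif(
        name=name or pattern,
        pattern=pattern,
        positions=tuple(positions),
        region=region,
        window=window,
    )


def scan(protein: str, motif: Motif) -> list[MotifMatch]:
    """All (possibly overlapping) matches of a motif, left to right.

    The region constraint requires the whole match to lie within the first
    (``n_terminal``) or last (``c_terminal``) ``motif.window`` residues.
    """
    if not protein:
        raise ValueError("empty protein")
    L = motif.compiled_length
    n = len(protein)
    if motif.region == N_TERMINAL:
        lo, hi = 0, min(n, motif.window) - L
    elif motif.region == C_TERMINAL:
        lo, hi = max(0, n - motif.window), n - L
    else:
        lo, hi = 0, n - L
    matches: list[MotifMatch] = []
    for start in range(lo, hi + 1):
        ok = True
        for off, fixed in enumerate(motif.positions):
            if fixed is not None and protein[start + off] != fixed:
                ok = False
                break
        if ok:
            matches.append(MotifMatch(motif.name, "", start, protein[start : start + L]))
    return matches


# --- family motif panel --------------------------------------------------

def default_motif_panel(window: int = DEFAULT_TERMINAL_WINDOW) -> dict[str, list[Motif]]:
    """Diagnostic motifs per crt gene family.

    CrtW carries two HxxHH entries (distinct names) because the family
    requires two occurrences besides HDxxH; their spacing is not constrained,
    only the count.
    """
    return {
        "crtY": [compile_motif("GxGxxG(x)19E", "FAD_binding_Y", N_TERMINAL, window)],
        "crtI": [compile_motif("GxGxxG(x)17E", "FAD_binding_I", N_TERMINAL, window)],
        "log": [compile_motif("PGGxGTxxE", "PGGxGTxxE")],
        "crtZ": [
            compile_motif("HxxHH", "HxxHH_N", N_TERMINAL, window),
            compile_motif("HxLHH", "HxLHH_C", C_TERMINAL, window),
        ],
        "crtW": [
            compile_motif("HDxxH", "HDxxH"),
            compile_motif("HxxHH", "HxxHH_1"),
            compile_motif("HxxHH", "HxxHH_2"),
        ],
        "crtE": [
            compile_motif("GKxxR", "GKxxR"),
            compile_motif("DDxxxxD", "DDxxxxD"),
            compile_motif("GQxxD", "GQxxD"),
            compile_motif("KT", "KT"),
            compile_motif("DDxxx", "DDxxx"),
        ],
    }


def motif_report(
    hits: Mapping[str, "OrthologueHit"],
    proteins: Mapping[str, str],
    panel: Optional[Mapping[str, Sequence[Motif]]] = None,
):
    """Per-gene motif presence table for accepted orthologue hits.

    Returns a DataFrame with one row per accepted gene that has assigned
    motifs; ``motif_complete`` is True when every assigned motif is found
    (for CrtW: HDxxH plus at least two HxxHH occurrences).
    """
    import pandas as pd

    panel = panel if panel is not None else default_motif_panel()
    rows = []
    for symbol in sorted(hits):
        hit = hits[symbol]
        if not getattr(hit, "accepted", True):
            continue
        motifs = panel.get(symbol)
        if not motifs:
            continue
        protein = proteins[hit.subject]
        found: dict[str, bool] = {}
        if symbol == "crtW":
            hd = compile_motif("HDxxH", "HDxxH")
            hxx = compile_motif("HxxHH", "HxxHH")
            n_hxx = len(scan(protein, hxx))
            found["HDxxH"] = bool(scan(protein, hd))
            found["HxxHH_1"] = n_hxx >= 1
            found["HxxHH_2"] = n_hxx >= 2
        else:
            for motif in motifs:
                found[motif.name] = bool(scan(protein, motif))
        row = {"symbol": symbol, "locus_tag": hit.subject}
        row.update(found)
        row["motif_complete"] = all(found.values())
        rows.append(row)
    return pd.DataFrame(rows)
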