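"""Genotype -> pigmentation group classification.

Strains are grouped by their crt gene complement relative to the core
biosynthetic chain ``crtE, crtB, crtI, crtY, crtZ`` (GGPP -> ... ->
zeaxanthin):

* group I   : core + crtG, no crtW  -> yellow, nostoxanthin accumulators
* group II  : core + crtG + crtW    -> orange, keto-xanthophyll producers
* group III : core + crtW, no crtG  -> red, astaxanthin producers
* group IV  : incomplete core       -> non-pigmented
* unassigned: complete core only    -> zeaxanthin-only, yellow-orange

crtX (carotenoid glycosyltransferase) never changes the group; it only
extends the predicted product list with glycosides.  The photosynthesis
gene cluster (PGC) flag adds a caveat (spirilloxanthin/Bchl a can shift the
observed colour) without changing the group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import AbstractSet, Iterable, Optional

from crtprofiler.pathway_inference import PathwayGraph, coloured, producible

CRT_SYMBOLS = frozenset({"crtE", "crtB", "crtI", "crtY", "crtZ", "crtG", "crtW", "crtX"})
ACCESSORY_FLAGS = frozenset({"log", "duf2141", "pgc"})
CORE = frozenset({"crtE", "crtB", "crtI", "crtY", "crtZ"})

#: shorthand used in cohort tables: E == crtE etc.
SHORT_TO_SYMBOL = {s[-1].upper(): s for s in CRT_SYMBOLS}

GROUP_COLOURS = {
    "I": "yellow",
    "II": "orange",
    "III": "red",
    "IV": "colourless",
    "unassigned": "yellow-orange",
}


class ConsistencyError(RuntimeError):
    """Group label and pathway output disagree (should never fire on defaults)."""


@dataclass(frozen=True)
class CrtGenotype:
    """A strain's crt gene complement plus accessory flags."""

    strain_name: str
    symbols: frozenset[str]
    accessory: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = self.symbols - CRT_SYMBOLS
        if unknown:
            raise ValueError(f"unknown crt symbols: {sorted(unknown)}")
        bad = self.accessory - ACCESSORY_FLAGS
        if bad:
            raise ValueError(f"unknown accessory flags: {sorted(bad)}")

    @classmethod
    def from_short(cls, strain_name: str, letters: Iterable[str], accessory: Iterable[str] = ()):
        """Build from single-letter shorthand (E, B, I, Y, Z, G, W, X)."""
        symbols = frozenset(SHORT_TO_SYMBOL[l.strip().upper()] for l in letters if l.strip())
        return cls(strain_name, symbols, frozenset(accessory))

    def enzymes(self) -> frozenset[str]:
        """Enzyme complement for pathway inference.

        The IPP/DMAPP isomerase (IDI) is treated as housekeeping and always
        present; MiaA and LOG enter only via the ``log`` accessory flag.
        """
        enz = {"IDI"}
        for s in self.symbols:
            enz.add("Crt" + s[-1].upper())
        if "log" in self.accessory:
            enz.update({"LOG", "MiaA"})
        return frozenset(enz)


@dataclass
class GroupAssignment:
    group: str
    predicted_colour: str
    predicted_carotenoids: frozenset[str] = frozenset()
    producible_compounds: frozenset[str] = frozenset()
    terminal_compounds: frozenset[str] = frozenset()
    caveats: frozenset[str] = frozenset()


def assign_group(genotype: CrtGenotype) -> GroupAssignment:
    """Pure genotype -> group mapping (no pathway run; colour is canonical).

    Every subset of the eight crt symbols maps to exactly one of
    I/II/III/IV/unassigned.
    """
    s = genotype.symbols
    caveats: set[str] = set()
    if not CORE <= s:
        group = "IV"
    elif "crtG" in s and "crtW" in s:
        group = "II"
    elif "crtG" in s:
        group = "I"
    elif "crtW" in s:
        group = "III"
    else:
        group = "unassigned"
        caveats.add("zeaxanthin_only")
    if group != "IV":
        # strains with a full colour genotype can still appear colourless
        # (dysfunctional or repressed crtB/crtI)
        caveats.add("possible_cryptic_colourless")
    if "pgc" in genotype.accessory:
        caveats.add("pgc_present")
    return GroupAssignment(
        group=group,
        predicted_colour=GROUP_COLOURS[group],
        caveats=frozenset(caveats),
    )


def predict_phenotype(
    genotype: CrtGenotype,
    graph: Optional[PathwayGraph] = None,
    assignment: Optional[GroupAssignment] = None,
) -> GroupAssignment:
    """Full phenotype prediction: group, colour and producible carotenoids.

    Runs pathway reachability with the genotype's enzyme complement and
    cross-checks the group label against it.  Predicted carotenoids are the
    coloured terminal compounds, augmented with the co-accumulating
    intermediates the cohort literature reports (caloxanthin alongside
    nostoxanthin; adonixanthin alongside astaxanthin).
    """
    assignment = assignment or assign_group(genotype)
    prod, terminals = producible(genotype.enzymes(), graph)
    carotenoids = set(coloured(terminals))
    if "nostoxanthin" in terminals:
        carotenoids.add("caloxanthin")
    if "astaxanthin" in prod:
        # keto-pathway intermediates co-accumulate with the end product
        carotenoids.update({"astaxanthin", "adonixanthin"})
    caveats = set(assignment.caveats)
    group = assignment.group

    if group == "I" and "nostoxanthin" not in prod:
        raise ConsistencyError("group I without producible nostoxanthin")
    if group in ("II", "III") and "astaxanthin" not in prod:
        raise ConsistencyError(f"group {group} without producible astaxanthin")
    if group == "unassigned" and CORE <= genotype.symbols and "zeaxanthin" not in prod:
        raise ConsistencyError("complete core without producible zeaxanthin")

    colour = GROUP_COLOURS[group]
    if group == "IV":
        if carotenoids:
            # hypothetical core-incomplete genotypes (e.g. missing crtZ only)
            # can still reach coloured intermediates; no such strain is known
            caveats.add("coloured_intermediates_possible")
        else:
            carotenoids = set()
    return GroupAssignment(
        group=group,
        predicted_colour=colour,
        predicted_carotenoids=frozenset(carotenoids),
        producible_compounds=prod,
        terminal_compounds=terminals,
        caveats=frozenset(caveats),
    )
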