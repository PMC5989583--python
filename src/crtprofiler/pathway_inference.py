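"""Carotenoid biosynthesis pathway reachability.

The default graph encodes the presumptive carotenogenesis network of
*Sphingomonadales*: from the isoprenoid precursors IPP/DMAPP through GGPP
(CrtE), phytoene (CrtB), lycopene (CrtI) and beta-carotene (CrtY) to the
xanthophylls.  Zeaxanthin is the branchpoint toward nostoxanthin (CrtG, via
caloxanthin), astaxanthin (CrtW, via adonixanthin) and erythroxanthin
(CrtW + CrtG); beta-carotene additionally branches toward canthaxanthin
(CrtW, via echinenone) and 2,2'-dihydroxycanthaxanthin (CrtW + CrtG).
DMAPP also feeds cytokinin production through MiaA and LOG.

A compound is *producible* for a given enzyme complement iff it is reachable
from the precursors using only edges whose full enzyme requirement is
present; *terminal* compounds (the proxy for what a strain accumulates) are
producible non-precursors with no applicable outgoing edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

DEFAULT_PRECURSORS = frozenset({"IPP", "DMAPP"})

#: compounds that carry no colour (plus the non-carotenoid cytokinin branch)
COLOURLESS = frozenset({"IPP", "DMAPP", "GGPP", "phytoene", "cytokinin"})


@dataclass(frozen=True)
class PathwayEdge:
    substrate: str
    product: str
    enzymes: frozenset[str]
    reversible: bool = False


def _e(substrate: str, product: str, enzymes: str, reversible: bool = False) -> PathwayEdge:
    return PathwayEdge(substrate, product, frozenset(enzymes.split("+")), reversible)


#: the 16 default reactions (the IPP<->DMAPP isomerisation is one reversible edge)
DEFAULT_EDGES: tuple[PathwayEdge, ...] = (
    _e("IPP", "DMAPP", "IDI", reversible=True),
    _e("DMAPP", "GGPP", "CrtE"),
    _e("GGPP", "phytoene", "CrtB"),
    _e("phytoene", "lycopene", "CrtI"),
    _e("lycopene", "beta-carotene", "CrtY"),
    _e("beta-carotene", "zeaxanthin", "CrtZ"),
    _e("beta-carotene", "echinenone", "CrtW"),
    _e("echinenone", "canthaxanthin", "CrtW"),
    _e("zeaxanthin", "caloxanthin", "CrtG"),
    _e("caloxanthin", "nostoxanthin", "CrtG"),
    _e("zeaxanthin", "adonixanthin", "CrtW"),
    _e("adonixanthin", "astaxanthin", "CrtW"),
    _e("zeaxanthin", "erythroxanthin", "CrtW+CrtG"),
    _e("beta-carotene", "2,2'-dihydroxycanthaxanthin", "CrtW+CrtG"),
    _e("astaxanthin", "astaxanthin dideoxyglycoside", "CrtX"),
    _e("DMAPP", "cytokinin", "MiaA+LOG"),
)

KNOWN_ENZYMES = frozenset(
    {"IDI", "CrtE", "CrtB", "CrtI", "CrtY", "CrtZ", "CrtG", "CrtW", "CrtX", "MiaA", "LOG"}
)


@dataclass
class PathwayGraph:
    """An enzyme-gated compound graph."""

    edges: tuple[PathwayEdge, ...] = DEFAULT_EDGES
    precursors: frozenset[str] = DEFAULT_PRECURSORS

    @property
    def compounds(self) -> frozenset[str]:
        out = set(self.precursors)
        for e in self.edges:
            out.add(e.substrate)
            out.add(e.product)
        return frozenset(out)

    @property
    def enzymes(self) -> frozenset[str]:
        out: set[str] = set()
        for e in self.edges:
            out |= e.enzymes
        return frozenset(out)

    def validate(self) -> None:
        # enzyme-free cycles would make reachability ill-defined beyond the
        # declared reversible isomerisation
        for e in self.edges:
            if not e.enzymes:
                raise ValueError(f"edge {e.substrate}->{e.product} requires no enzyme")


def load_graph(config: Optional[object] = None) -> PathwayGraph:
    """Build the pathway graph, optionally extended/overridden by an edge list.

    ``config`` is a TSV file with columns ``substrate<TAB>product<TAB>enzymes``
    (enzymes comma-separated); lines starting with ``#`` are comments.  Listed
    edges are appended to the defaults, so an auxiliary branch (for example
    the spirilloxanthin route through CrtC/CrtD/CrtF of photosynthesis gene
    clusters) can be declared without re-stating the core pathway.
    """
    edges = list(DEFAULT_EDGES)
    if config is not None:
        path = Path(config)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'substrate<TAB>product<TAB>enzymes'"
                    )
                substrate, product, enz = parts
                enzymes = frozenset(x.strip() for x in enz.split(",") if x.strip())
                if not enzymes:
                    raise ValueError(f"{path}:{lineno}: edge requires at least one enzyme")
                edges.append(PathwayEdge(substrate, product, enzymes))
    graph = PathwayGraph(edges=tuple(edges))
    graph.validate()
    return graph


def producible(
    enzymes: Iterable[str],
    graph: Optional[PathwayGraph] = None,
    precursors: Optional[Iterable[str]] = None,
) -> tuple[frozenset[str], frozenset[str]]:
    """Fixed-point closure of compound producibility.

    Returns ``(producible_compounds, terminal_compounds)``.  A compound is
    producible iff reachable from the precursors using only edges whose full
    enzyme set is present.  Terminals are producible non-precursor compounds
    with no applicable outgoing edge; they approximate what accumulates.
    """
    graph = graph or PathwayGraph()
    enzyme_set = frozenset(enzymes)
    precursor_set = frozenset(precursors) if precursors is not None else graph.precursors
    applicable = [e for e in graph.edges if e.enzymes <= enzyme_set]
    reached = set(precursor_set)
    changed = True
    while changed:
        changed = False
        for e in applicable:
            if e.substrate in reached and e.product not in reached:
                reached.add(e.product)
                changed = True
            if e.reversible and e.product in reached and e.substrate not in reached:
                reached.add(e.substrate)
                changed = True
    has_out = set()
    for e in applicable:
        if e.substrate in reached:
            has_out.add(e.substrate)
        if e.reversible and e.product in reached:
            has_out.add(e.product)
    terminals = frozenset(c for c in reached - precursor_set if c not in has_out)
    return frozenset(reached), terminals


def coloured(compounds: Iterable[str]) -> frozenset[str]:
    """Subset of compounds expected to contribute colour."""
    return frozenset(c for c in compounds if c not in COLOURLESS)
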