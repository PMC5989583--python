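"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own algorithms: the alignment oracle
enumerates alignments recursively, the motif oracle is a naive sliding
window over a regex-free position check, and the pathway oracle is a plain
breadth-first search.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

_SM = substitution_matrices.load("BLOSUM62")


def global_affine_score(x: str, y: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Best global alignment score of two (short) peptides, by recursion."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> int:
        if i == len(x) and j == len(y):
            return 0
        best = -(10**9)
        if i < len(x) and j < len(y):
            best = max(best, int(_SM[x[i]][y[j]]) + rec(i + 1, j + 1, 0))
        if i < len(x):
            cost = gap_extend if state == 1 else gap_open + gap_extend
            best = max(best, -cost + rec(i + 1, j, 1))
        if j < len(y):
            cost = gap_extend if state == 2 else gap_open + gap_extend
            best = max(best, -cost + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


def local_score_bruteforce(a: str, b: str) -> int:
    """Max over all substring pairs of their best global alignment score."""
    best = 0
    for i1 in range(len(a)):
        for i2 in range(i1, len(a)):
            for j1 in range(len(b)):
                for j2 in range(j1, len(b)):
                    s = global_affine_score(a[i1 : i2 + 1], b[j1 : j2 + 1])
                    if s > best:
                        best = s
    return best


def motif_matches_bruteforce(protein: str, fixed: dict[int, str], length: int,
                             lo: int, hi: int) -> list[int]:
    """Sliding-window match offsets for a motif given as {offset: residue}."""
    out = []
    for start in range(max(0, lo), min(hi, len(protein) - length) + 1):
        window = protein[start : start + length]
        if all(window[k] == v for k, v in fixed.items()):
            out.append(start)
    return out


def producible_bruteforce(enzymes: frozenset, edges, precursors: frozenset) -> frozenset:
    """BFS closure over the edge list (reversible edges expanded)."""
    directed = []
    for e in edges:
        directed.append((e.substrate, e.product, e.enzymes))
        if e.reversible:
            directed.append((e.product, e.substrate, e.enzymes))
    frontier = list(precursors)
    seen = set(precursors)
    while frontier:
        node = frontier.pop()
        for s, p, req in directed:
            if s == node and req <= enzymes and p not in seen:
                seen.add(p)
                frontier.append(p)
    return frozenset(seen)
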