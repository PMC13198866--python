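"""Independent brute-force oracles.

Everything here recomputes alignment-space quantities by exhaustive
enumeration of move strings, with its own scoring walk and its own
move-to-edge conversion, so that it shares no dynamic-programming code
with the package internals it cross-checks.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache

from alnsafe.core_dag import DagEdge  # container only

M, D, I = 0, 1, 2
_MOVE_STATE = {"D": M, "V": D, "H": I}
_MOVE_KIND = {"D": "diagonal", "V": "vertical", "H": "horizontal"}


@lru_cache(maxsize=None)
def move_strings(la: int, lb: int) -> tuple[str, ...]:
    if la == 0 and lb == 0:
        return ("",)
    out: list[str] = []
    if la and lb:
        out.extend("D" + t for t in move_strings(la - 1, lb - 1))
    if la:
        out.extend("V" + t for t in move_strings(la - 1, lb))
    if lb:
        out.extend("H" + t for t in move_strings(la, lb - 1))
    return tuple(out)


def score_path(a: str, b: str, go: int, ge: int, scores, moves: str) -> int:
    i = j = 0
    prev = ""
    total = 0
    for mv in moves:
        if mv == "D":
            total += scores[a[i], b[j]]
            i += 1
            j += 1
        elif mv == "V":
            total -= ge + (go if prev != "V" else 0)
            i += 1
        else:
            total -= ge + (go if prev != "H" else 0)
            j += 1
        prev = mv
    return total


def suboptimal_paths(a: str, b: str, params) -> list[str]:
    """All move strings scoring within params.delta of the best score."""
    go, ge = params.gap_open, params.gap_extend
    scores = params.matrix.scores
    scored = [
        (mv, score_path(a, b, go, ge, scores, mv)) for mv in move_strings(len(a), len(b))
    ]
    best = max(s for _, s in scored)
    return sorted(mv for mv, s in scored if s >= best - params.delta)


def step(v: tuple[int, int, int], mv: str) -> tuple[int, int, int]:
    i, j, _ = v
    if mv == "D":
        return (i + 1, j + 1, M)
    if mv == "V":
        return (i + 1, j, D)
    return (i, j + 1, I)


def vertex_walk(moves: str) -> list[tuple[int, int, int]]:
    """Vertices (i, j, state) visited along a move string, source first."""
    out = [(0, 0, M)]
    for mv in moves:
        out.append(step(out[-1], mv))
    return out


def edges_of(a: str, b: str, go: int, ge: int, scores, moves: str) -> tuple[DagEdge, ...]:
    verts = vertex_walk(moves)
    out = []
    for k, mv in enumerate(moves):
        u, v = verts[k], verts[k + 1]
        if mv == "D":
            w = scores[a[u[0]], b[u[1]]]
        elif mv == "V":
            w = -(ge + (go if u[2] != D else 0))
        else:
            w = -(ge + (go if u[2] != I else 0))
        out.append(DagEdge(u, v, _MOVE_KIND[mv], w))
    return tuple(out)


def edge_counts(a: str, b: str, params, paths: list[str]) -> dict[DagEdge, int]:
    go, ge = params.gap_open, params.gap_extend
    scores = params.matrix.scores
    counts: dict[DagEdge, int] = {}
    for mv in paths:
        for e in edges_of(a, b, go, ge, scores, mv):
            counts[e] = counts.get(e, 0) + 1
    return counts


def maximal_safe_windows(
    a: str, b: str, params, paths: list[str], alpha: Fraction
) -> dict[tuple[DagEdge, ...], Fraction]:
    """Maximal α-safe contiguous subpaths, by counting every contiguous
    subpath of every enumerated alignment.

    A subpath is keyed by its start vertex plus its move substring,
    which identifies the edge sequence uniquely.  Returns
    ``{edge_path: support}``.
    """
    total = len(paths)
    p, q = alpha.numerator, alpha.denominator
    counts: dict[tuple[tuple[int, int, int], str], int] = {}
    for moves in paths:
        verts = vertex_walk(moves)
        n = len(moves)
        for s in range(n):
            start = verts[s]
            sub = ""
            for e in range(s + 1, n + 1):
                sub += moves[e - 1]
                key = (start, sub)
                counts[key] = counts.get(key, 0) + 1
    safe = {k for k, c in counts.items() if c * q >= p * total}
    by_len: dict[int, list] = {}
    for k in safe:
        by_len.setdefault(len(k[1]), []).append(k)

    def extendable(k) -> bool:
        start, sub = k
        for s2, sub2 in by_len.get(len(sub) + 1, ()):
            if s2 == start and sub2[:-1] == sub:
                return True  # right extension
            if sub2[1:] == sub and step(s2, sub2[0]) == start:
                return True  # left extension
        return False

    go, ge = params.gap_open, params.gap_extend
    scores = params.matrix.scores
    out: dict[tuple[DagEdge, ...], Fraction] = {}
    for k in safe:
        if extendable(k):
            continue
        start, sub = k
        # rebuild the edge path by walking the moves from the start vertex
        verts = [start]
        for mv in sub:
            verts.append(step(verts[-1], mv))
        edges = []
        for idx, mv in enumerate(sub):
            u, v = verts[idx], verts[idx + 1]
            if mv == "D":
                w = scores[a[u[0]], b[u[1]]]
            elif mv == "V":
                w = -(ge + (go if u[2] != D else 0))
            else:
                w = -(ge + (go if u[2] != I else 0))
            edges.append(DagEdge(u, v, _MOVE_KIND[mv], w))
        out[tuple(edges)] = Fraction(counts[k], total)
    return out
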