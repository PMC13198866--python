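"""Affine-gap global alignment and the Δ-suboptimal alignment graph.

The alignment model is Needleman–Wunsch with affine gap penalties over a
three-state lattice: state M (the last step consumed one symbol of each
sequence), state D (inside a gap consuming sequence A — drawn vertically)
and state I (inside a gap consuming sequence B — drawn horizontally).  A
gap of length k costs ``gap_open + k * gap_extend``; the opening charge is
applied on the first gap symbol, including when switching directly from a
D-gap to an I-gap or vice versa.

Source→sink paths of the full lattice are in bijection with global
alignments, because the state of a vertex is a function of the move that
entered it.  The Δ-suboptimal alignment graph keeps exactly those edges
that lie on at least one path whose total score is within Δ of the
optimum; retention is decided by exact integer arithmetic on best
prefix/suffix scores, so the graph is never approximated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterator, NamedTuple, Sequence

from .matrices import SubstitutionMatrix

__all__ = [
    "M_STATE",
    "D_STATE",
    "I_STATE",
    "DIAGONAL",
    "VERTICAL",
    "HORIZONTAL",
    "DagEdge",
    "AlignmentParams",
    "AlignmentDag",
    "align_optimal",
    "build_suboptimal_dag",
    "enumerate_alignments",
    "edges_from_moves",
    "alignment_rows",
]

# Vertex states: a vertex is (i, j, state) where i, j count consumed
# symbols of A and B.  The distinguished source is (0, 0, M).
M_STATE, D_STATE, I_STATE = 0, 1, 2
STATE_NAMES = ("M", "D", "I")

DIAGONAL = "diagonal"
VERTICAL = "vertical"
HORIZONTAL = "horizontal"
_KIND_ORDER = {DIAGONAL: 0, VERTICAL: 1, HORIZONTAL: 2}

# Sentinel for unreachable DP cells; all real scores are tiny by comparison.
_NEG = -(1 << 60)
_NEG_HALF = _NEG // 2

Vertex = tuple[int, int, int]


class DagEdge(NamedTuple):
    """One scored step of an alignment.

    ``frm``/``to`` are ``(i, j, state)`` vertices; ``kind`` is diagonal
    (aligns A[i] with B[j]), vertical (gap symbol consuming A[i]) or
    horizontal (gap symbol consuming B[j]); ``weight`` is the exact
    integer score contribution of the step.
    """

    frm: Vertex
    to: Vertex
    kind: str
    weight: int


def as_fraction(value) -> Fraction:
    """Coerce a threshold to an exact rational.

    Floats are interpreted via their shortest decimal representation, so
    ``0.6`` means exactly 3/5 rather than the nearest binary float.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, float):
        return Fraction(str(value))
    return Fraction(value)


@dataclass
class AlignmentParams:
    """Tunables of the alignment-safety method.

    ``delta`` is the maximum score shortfall from the optimal alignment
    defining the suboptimal space; ``alpha`` is the minimum fraction of
    suboptimal alignments that must share an interval for it to be safe.
    """

    matrix: SubstitutionMatrix
    gap_open: int = 11
    gap_extend: int = 1
    delta: int = 0
    alpha: Fraction = Fraction(3, 4)

    def __post_init__(self) -> None:
        for attr in ("gap_open", "gap_extend", "delta"):
            v = getattr(self, attr)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{attr} must be a non-negative integer, got {v!r}")
        self.alpha = as_fraction(self.alpha)
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


def _check_sequences(seq_a: str, seq_b: str, matrix: SubstitutionMatrix) -> None:
    for label, seq in (("A", seq_a), ("B", seq_b)):
        for pos, ch in enumerate(seq):
            if ch not in matrix:
                raise ValueError(
                    f"residue {ch!r} at position {pos + 1} of sequence {label} "
                    f"is not in the alphabet of matrix {matrix.name}"
                )


def _score_table(seq_a: str, seq_b: str, matrix: SubstitutionMatrix) -> list[list[int]]:
    cols = {c: [matrix.scores[a, c] for a in seq_a] for c in set(seq_b)}
    return [[cols[b][i] for b in seq_b] for i in range(len(seq_a))]


def _forward(seq_a: str, seq_b: str, params: AlignmentParams, s: list[list[int]]):
    """Best-prefix scores F_S[i][j] for paths from the source ending at
    (i, j) in state S."""
    m, n = len(seq_a), len(seq_b)
    go, ge = params.gap_open, params.gap_extend
    fm = [[_NEG] * (n + 1) for _ in range(m + 1)]
    fd = [[_NEG] * (n + 1) for _ in range(m + 1)]
    fi = [[_NEG] * (n + 1) for _ in range(m + 1)]
    fm[0][0] = 0
    for i in range(m + 1):
        fm_i, fd_i, fi_i = fm[i], fd[i], fi[i]
        if i:
            fm_p, fd_p, fi_p = fm[i - 1], fd[i - 1], fi[i - 1]
            s_p = s[i - 1]
        for j in range(n + 1):
            if i and j:
                best = max(fm_p[j - 1], fd_p[j - 1], fi_p[j - 1])
                if best > _NEG_HALF:
                    fm_i[j] = best + s_p[j - 1]
            if i:
                fd_i[j] = max(fm_p[j] - go - ge, fd_p[j] - ge, fi_p[j] - go - ge)
            if j:
                fi_i[j] = max(fm_i[j - 1] - go - ge, fi_i[j - 1] - ge, fd_i[j - 1] - go - ge)
    return fm, fd, fi


def _backward(seq_a: str, seq_b: str, params: AlignmentParams, s: list[list[int]]):
    """Best-suffix scores B_S[i][j] for completing from (i, j, S) to the
    corner (|A|, |B|)."""
    m, n = len(seq_a), len(seq_b)
    go, ge = params.gap_open, params.gap_extend
    bm = [[_NEG] * (n + 1) for _ in range(m + 1)]
    bd = [[_NEG] * (n + 1) for _ in range(m + 1)]
    bi = [[_NEG] * (n + 1) for _ in range(m + 1)]
    bm[m][n] = bd[m][n] = bi[m][n] = 0
    for i in range(m, -1, -1):
        bm_i, bd_i, bi_i = bm[i], bd[i], bi[i]
        if i < m:
            bm_nx, bd_nx = bm[i + 1], bd[i + 1]
            s_i = s[i]
        for j in range(n, -1, -1):
            if i == m and j == n:
                continue
            diag = s_i[j] + bm_nx[j + 1] if (i < m and j < n) else _NEG
            vert = bd_nx[j] if i < m else _NEG
            horz = bi_i[j + 1] if j < n else _NEG
            bm_i[j] = max(diag, vert - go - ge, horz - go - ge)
            bd_i[j] = max(diag, vert - ge, horz - go - ge)
            bi_i[j] = max(diag, vert - go - ge, horz - ge)
    return bm, bd, bi


_POS = 1 << 60


def _min_full_score(seq_a: str, seq_b: str, params: AlignmentParams, s) -> int:
    """Minimum achievable full-path score (min-plus analogue of the
    forward DP)."""
    m, n = len(seq_a), len(seq_b)
    if m == 0 and n == 0:
        return 0
    go, ge = params.gap_open, params.gap_extend
    fm = [[_POS] * (n + 1) for _ in range(m + 1)]
    fd = [[_POS] * (n + 1) for _ in range(m + 1)]
    fi = [[_POS] * (n + 1) for _ in range(m + 1)]
    fm[0][0] = 0
    for i in range(m + 1):
        fm_i, fd_i, fi_i = fm[i], fd[i], fi[i]
        if i:
            fm_p, fd_p, fi_p = fm[i - 1], fd[i - 1], fi[i - 1]
            s_p = s[i - 1]
        for j in range(n + 1):
            if i and j:
                worst = min(fm_p[j - 1], fd_p[j - 1], fi_p[j - 1])
                if worst < _POS // 2:
                    fm_i[j] = worst + s_p[j - 1]
            if i:
                fd_i[j] = min(fm_p[j] - go - ge, fd_p[j] - ge, fi_p[j] - go - ge)
            if j:
                fi_i[j] = min(fm_i[j - 1] - go - ge, fi_i[j - 1] - ge, fd_i[j - 1] - go - ge)
    return min(fm[m][n], fd[m][n], fi[m][n])


class AlignmentDag:
    """The Δ-suboptimal alignment graph.

    Vertices are ``(i, j, state)`` triples; the single source is
    ``(0, 0, M)`` and the sink role is played by the vertices at cell
    ``(|A|, |B|)`` (conceptually merged into one sink).  Every retained
    edge lies on at least one source→sink path scoring at least
    ``opt_score - delta``.
    """

    def __init__(
        self,
        seq_a: str,
        seq_b: str,
        params: AlignmentParams,
        opt_score: int,
        edges: Sequence[DagEdge],
    ) -> None:
        self.seq_a = seq_a
        self.seq_b = seq_b
        self.params = params
        self.opt_score = opt_score
        self.edges: tuple[DagEdge, ...] = tuple(
            sorted(
                edges,
                key=lambda e: (
                    e.frm[0] + e.frm[1],
                    e.frm[0],
                    e.frm[2],
                    _KIND_ORDER[e.kind],
                ),
            )
        )
        self.edge_set = frozenset(self.edges)
        self.source: Vertex = (0, 0, M_STATE)
        out: dict[Vertex, list[DagEdge]] = {}
        inc: dict[Vertex, list[DagEdge]] = {}
        verts = {self.source}
        for e in self.edges:
            out.setdefault(e.frm, []).append(e)
            inc.setdefault(e.to, []).append(e)
            verts.add(e.frm)
            verts.add(e.to)
        self.out_edges = {v: tuple(es) for v, es in out.items()}
        self.in_edges = {v: tuple(es) for v, es in inc.items()}
        self.vertices = frozenset(verts)
        m, n = len(seq_a), len(seq_b)
        self.end_vertices: tuple[Vertex, ...] = tuple(
            sorted(v for v in verts if v[0] == m and v[1] == n)
        )

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.seq_a), len(self.seq_b)

    def dp_tables(self):
        """Forward/backward best-score tables (per state), cached."""
        if getattr(self, "_dp_tables", None) is None:
            s = _score_table(self.seq_a, self.seq_b, self.params.matrix)
            self._dp_tables = _forward(self.seq_a, self.seq_b, self.params, s) + _backward(
                self.seq_a, self.seq_b, self.params, s
            )
        return self._dp_tables

    def worst_path_score(self) -> int:
        """Minimum total score over all lattice paths (a lower bound for
        every path in the graph); cached."""
        if getattr(self, "_worst", None) is None:
            s = _score_table(self.seq_a, self.seq_b, self.params.matrix)
            self._worst = _min_full_score(self.seq_a, self.seq_b, self.params, s)
        return self._worst

    def has_edge(self, edge: DagEdge) -> bool:
        return edge in self.edge_set

    def find_edge(self, frm: Vertex, to: Vertex) -> DagEdge | None:
        for e in self.out_edges.get(frm, ()):
            if e.to == to:
                return e
        return None

    def iter_paths(self, limit: int | None = 200_000) -> Iterator[tuple[DagEdge, ...]]:
        """DFS over all source→sink edge paths (testing/small graphs only)."""
        if not self.edges:
            return
        ends = set(self.end_vertices)
        stack: list[DagEdge] = []
        count = 0

        def walk(v: Vertex) -> Iterator[tuple[DagEdge, ...]]:
            nonlocal count
            if v in ends:
                count += 1
                if limit is not None and count > limit:
                    raise RuntimeError("path iteration limit exceeded")
                yield tuple(stack)
                return
            for e in self.out_edges.get(v, ()):
                stack.append(e)
                yield from walk(e.to)
                stack.pop()

        yield from walk(self.source)


def align_optimal(
    seq_a: str, seq_b: str, params: AlignmentParams
) -> tuple[int, list[DagEdge]]:
    """Optimal global alignment score and one optimal path.

    Ties are broken deterministically, preferring diagonal, then
    vertical, then horizontal moves, resolved left-to-right from the
    source.
    """
    _check_sequences(seq_a, seq_b, params.matrix)
    m, n = len(seq_a), len(seq_b)
    if m == 0 and n == 0:
        return 0, []
    s = _score_table(seq_a, seq_b, params.matrix)
    fm, fd, fi = _forward(seq_a, seq_b, params, s)
    bm, bd, bi = _backward(seq_a, seq_b, params, s)
    opt = max(fm[m][n], fd[m][n], fi[m][n])
    go, ge = params.gap_open, params.gap_extend

    path: list[DagEdge] = []
    i = j = 0
    st = M_STATE
    acc = 0
    while (i, j) != (m, n):
        if i < m and j < n:
            w = s[i][j]
            if acc + w + bm[i + 1][j + 1] == opt:
                path.append(DagEdge((i, j, st), (i + 1, j + 1, M_STATE), DIAGONAL, w))
                i, j, st, acc = i + 1, j + 1, M_STATE, acc + w
                continue
        if i < m:
            w = -(ge + (go if st != D_STATE else 0))
            if acc + w + bd[i + 1][j] == opt:
                path.append(DagEdge((i, j, st), (i + 1, j, D_STATE), VERTICAL, w))
                i, st, acc = i + 1, D_STATE, acc + w
                continue
        if j < n:
            w = -(ge + (go if st != I_STATE else 0))
            if acc + w + bi[i][j + 1] == opt:
                path.append(DagEdge((i, j, st), (i, j + 1, I_STATE), HORIZONTAL, w))
                j, st, acc = j + 1, I_STATE, acc + w
                continue
        raise AssertionError("optimal-path reconstruction left the optimum")
    return opt, path


def build_suboptimal_dag(
    seq_a: str, seq_b: str, params: AlignmentParams
) -> AlignmentDag:
    """Construct the graph of all edges used by some alignment scoring
    within ``params.delta`` of the optimum.

    An edge ``u -> v`` with weight ``w`` is retained iff
    ``forwardBest(u) + w + backwardBest(v) >= opt_score - delta``, with
    forward/backward bests taken per affine state.
    """
    _check_sequences(seq_a, seq_b, params.matrix)
    m, n = len(seq_a), len(seq_b)
    if m == 0 and n == 0:
        return AlignmentDag(seq_a, seq_b, params, 0, [])
    s = _score_table(seq_a, seq_b, params.matrix)
    fm, fd, fi = _forward(seq_a, seq_b, params, s)
    bm, bd, bi = _backward(seq_a, seq_b, params, s)
    opt = max(fm[m][n], fd[m][n], fi[m][n])
    thr = opt - params.delta
    go, ge = params.gap_open, params.gap_extend
    fwd = (fm, fd, fi)

    edges: list[DagEdge] = []
    for i in range(m + 1):
        for j in range(n + 1):
            if i and j:
                w = s[i - 1][j - 1]
                tail = w + bm[i][j]
                for st in (M_STATE, D_STATE, I_STATE):
                    f = fwd[st][i - 1][j - 1]
                    if f > _NEG_HALF and f + tail >= thr:
                        edges.append(
                            DagEdge((i - 1, j - 1, st), (i, j, M_STATE), DIAGONAL, w)
                        )
            if i:
                b = bd[i][j]
                for st in (M_STATE, D_STATE, I_STATE):
                    f = fwd[st][i - 1][j]
                    if f <= _NEG_HALF:
                        continue
                    w = -(ge + (go if st != D_STATE else 0))
                    if f + w + b >= thr:
                        edges.append(
                            DagEdge((i - 1, j, st), (i, j, D_STATE), VERTICAL, w)
                        )
            if j:
                b = bi[i][j]
                for st in (M_STATE, D_STATE, I_STATE):
                    f = fwd[st][i][j - 1]
                    if f <= _NEG_HALF:
                        continue
                    w = -(ge + (go if st != I_STATE else 0))
                    if f + w + b >= thr:
                        edges.append(
                            DagEdge((i, j - 1, st), (i, j, I_STATE), HORIZONTAL, w)
                        )
    dag = AlignmentDag(seq_a, seq_b, params, opt, edges)
    dag._dp_tables = (fm, fd, fi, bm, bd, bi)
    return dag


@lru_cache(maxsize=None)
def _move_strings(la: int, lb: int) -> tuple[str, ...]:
    """Every monotone move string (D=diagonal, V=vertical, H=horizontal)
    from (0,0) to (la,lb)."""
    if la == 0 and lb == 0:
        return ("",)
    out: list[str] = []
    if la and lb:
        out.extend("D" + t for t in _move_strings(la - 1, lb - 1))
    if la:
        out.extend("V" + t for t in _move_strings(la - 1, lb))
    if lb:
        out.extend("H" + t for t in _move_strings(la, lb - 1))
    return tuple(out)


def score_moves(seq_a: str, seq_b: str, params: AlignmentParams, moves: str) -> int:
    """Score of the alignment spelled by a move string, by direct walk."""
    go, ge = params.gap_open, params.gap_extend
    scores = params.matrix.scores
    i = j = 0
    prev = ""
    total = 0
    for mv in moves:
        if mv == "D":
            total += scores[seq_a[i], seq_b[j]]
            i += 1
            j += 1
        elif mv == "V":
            total -= ge + (go if prev != "V" else 0)
            i += 1
        elif mv == "H":
            total -= ge + (go if prev != "H" else 0)
            j += 1
        else:
            raise ValueError(f"illegal move character {mv!r}")
        prev = mv
    if i != len(seq_a) or j != len(seq_b):
        raise ValueError("move string does not span both sequences")
    return total


def edges_from_moves(
    seq_a: str, seq_b: str, params: AlignmentParams, moves: str
) -> tuple[DagEdge, ...]:
    """Convert a move string into the corresponding lattice edge path."""
    go, ge = params.gap_open, params.gap_extend
    scores = params.matrix.scores
    i = j = 0
    st = M_STATE
    out: list[DagEdge] = []
    for mv in moves:
        if mv == "D":
            w = scores[seq_a[i], seq_b[j]]
            out.append(DagEdge((i, j, st), (i + 1, j + 1, M_STATE), DIAGONAL, w))
            i, j, st = i + 1, j + 1, M_STATE
        elif mv == "V":
            w = -(ge + (go if st != D_STATE else 0))
            out.append(DagEdge((i, j, st), (i + 1, j, D_STATE), VERTICAL, w))
            i, st = i + 1, D_STATE
        elif mv == "H":
            w = -(ge + (go if st != I_STATE else 0))
            out.append(DagEdge((i, j, st), (i, j + 1, I_STATE), HORIZONTAL, w))
            j, st = j + 1, I_STATE
        else:
            raise ValueError(f"illegal move character {mv!r}")
    return tuple(out)


def enumerate_alignments(
    seq_a: str,
    seq_b: str,
    params: AlignmentParams,
    oracle_bound: int = 64,
) -> list[tuple[tuple[DagEdge, ...], int]]:
    """Exhaustively enumerate every global alignment scoring within
    ``params.delta`` of the optimum.

    Intended as a brute-force cross-check on small inputs; the optimum is
    taken from the enumeration itself, independently of the DP.  Raises
    when ``|A| * |B|`` exceeds ``oracle_bound`` cells.
    """
    _check_sequences(seq_a, seq_b, params.matrix)
    la, lb = len(seq_a), len(seq_b)
    if la * lb > oracle_bound:
        raise ValueError(
            f"oracle bound exceeded ({la}x{lb} > {oracle_bound} cells); "
            "use build_suboptimal_dag for inputs of this size"
        )
    scored = [
        (moves, score_moves(seq_a, seq_b, params, moves))
        for moves in _move_strings(la, lb)
    ]
    opt = max(sc for _, sc in scored)
    keep = sorted(
        (moves, sc) for moves, sc in scored if sc >= opt - params.delta
    )
    return [
        (edges_from_moves(seq_a, seq_b, params, moves), sc) for moves, sc in keep
    ]


def alignment_rows(seq_a: str, seq_b: str, path: Sequence[DagEdge]) -> tuple[str, str]:
    """Render an edge path as the two gapped rows of a pairwise alignment."""
    row_a: list[str] = []
    row_b: list[str] = []
    for e in path:
        i, j, _ = e.frm
        if e.kind == DIAGONAL:
            row_a.append(seq_a[i])
            row_b.append(seq_b[j])
        elif e.kind == VERTICAL:
            row_a.append(seq_a[i])
            row_b.append("-")
        else:
            row_a.append("-")
            row_b.append(seq_b[j])
    return "".join(row_a), "".join(row_b)
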