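"""Exact path counting and α-safe alignment windows.

Path counts over the Δ-suboptimal graph are exact arbitrary-precision
integers; supports are exact rationals reduced to lowest terms.  A safety
window is a maximal contiguous edge subpath contained in at least an α
proportion of all source→sink paths, projected back onto 0-based
half-open intervals of both sequences.

For α > 1/2 windows are found by a chain sweep: any two subpaths with
support above one half share a full path, so all α-safe subpaths lie
along a single chain of α-safe vertices, and maximal windows fall out of
a two-pointer scan over that chain.  For α ≤ 1/2 safe subpaths need not
lie on one chain, and extraction falls back to exhaustive enumeration
(guarded by the oracle size bound).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

from .core_dag import (
    AlignmentDag,
    DagEdge,
    Vertex,
    as_fraction,
    enumerate_alignments,
)

__all__ = [
    "PathCounts",
    "SafetyWindow",
    "SafetyResult",
    "count_paths",
    "containing_path_count",
    "edge_support",
    "subpath_support",
    "extract_safety_windows",
    "project_window",
    "safe_coverage",
    "compute_safety",
    "analyze_pair",
]


@dataclass(frozen=True)
class PathCounts:
    """Exact path counts over the Δ-suboptimal alignment space.

    The counted universe is the set of full alignments scoring at least
    ``threshold = opt_score - delta``.  Because the union graph of their
    edges also admits crossover paths below the threshold, counts are
    kept score-stratified: ``forward_dist[v][k]`` is the number of
    source→v prefixes whose score falls short of the best prefix score
    ``fbest[v]`` by exactly ``k`` (entries that cannot participate in any
    admissible full path are pruned), and symmetrically for
    ``backward_dist``.  The scalar ``forward[v]``/``backward[v]`` views
    count prefixes/suffixes usable by at least one admissible full path.
    ``total`` is the exact number of admissible alignments, identical
    whether accumulated forward or backward.
    """

    forward: Mapping[Vertex, int]
    backward: Mapping[Vertex, int]
    total: int
    forward_dist: Mapping[Vertex, tuple[int, ...]]
    backward_dist: Mapping[Vertex, tuple[int, ...]]
    backward_cum: Mapping[Vertex, tuple[int, ...]]
    fbest: Mapping[Vertex, int]
    bbest: Mapping[Vertex, int]
    threshold: int


@dataclass(frozen=True)
class SafetyWindow:
    """A maximal α-safe subpath with its sequence projections.

    ``support`` is the exact fraction of full alignment paths containing
    the subpath.  Intervals are 0-based half-open; an indel-only window
    projects to a zero-length interval on one sequence.
    """

    path: tuple[DagEdge, ...]
    support: Fraction
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]


@dataclass(frozen=True)
class SafetyResult:
    """Summary of one alignment-safety computation."""

    opt_score: int
    total: int
    windows: tuple[SafetyWindow, ...]
    edge_fractions: Mapping[DagEdge, Fraction] | None
    safe_coverage_a: float
    safe_coverage_b: float
    len_a: int
    len_b: int
    alpha: Fraction
    delta: int


def count_paths(dag: AlignmentDag) -> PathCounts:
    """Count admissible source→sink paths through every vertex by
    topological accumulation of shortfall distributions in both
    directions."""
    if not dag.edges:
        # Only the empty-vs-empty alignment has no edges at all.
        one = {dag.source: 1}
        dist = {dag.source: (1,)}
        zero = {dag.source: 0}
        return PathCounts(one, dict(one), 1, dist, dict(dist), dict(dist), zero, dict(zero), 0)

    fm, fd, fi, bm, bd, bi = dag.dp_tables()
    ftab, btab = (fm, fd, fi), (bm, bd, bi)
    # Scores below the worst achievable path are unreachable; capping the
    # threshold there keeps shortfall arrays short even for huge delta.
    thr = max(dag.opt_score - dag.params.delta, dag.worst_path_score())

    fbest = {v: ftab[v[2]][v[0]][v[1]] for v in dag.vertices}
    bbest = {v: btab[v[2]][v[0]][v[1]] for v in dag.vertices}
    maxk = {v: fbest[v] + bbest[v] - thr for v in dag.vertices}

    fdist: dict[Vertex, list[int]] = {
        v: [0] * (maxk[v] + 1) for v in dag.vertices if maxk[v] >= 0
    }
    fdist[dag.source][0] = 1
    # dag.edges are already sorted by the topological key frm.i + frm.j.
    for e in dag.edges:
        du = fdist.get(e.frm)
        dv = fdist.get(e.to)
        if du is None or dv is None:
            continue
        off = fbest[e.to] - fbest[e.frm] - e.weight
        cap = len(dv) - off
        for k1 in range(min(len(du), cap)):
            c = du[k1]
            if c:
                dv[k1 + off] += c

    bdist: dict[Vertex, list[int]] = {
        v: [0] * (maxk[v] + 1) for v in dag.vertices if maxk[v] >= 0
    }
    for v in dag.end_vertices:
        bdist[v][0] = 1
    for e in reversed(dag.edges):
        dv = bdist.get(e.to)
        du = bdist.get(e.frm)
        if du is None or dv is None:
            continue
        off = bbest[e.frm] - e.weight - bbest[e.to]
        cap = len(du) - off
        for k2 in range(min(len(dv), cap)):
            c = dv[k2]
            if c:
                du[k2 + off] += c

    total = sum(bdist.get(dag.source, (0,)))
    total_fwd = sum(sum(fdist.get(v, (0,))) for v in dag.end_vertices)
    if total != total_fwd:
        raise AssertionError(
            f"path-count mismatch: backward {total} vs forward {total_fwd}"
        )
    if total < 1:
        raise AssertionError("alignment graph admits no admissible path")

    fdist_t = {v: tuple(d) for v, d in fdist.items()}
    bdist_t = {v: tuple(d) for v, d in bdist.items()}
    bcum = {}
    for v, d in bdist_t.items():
        acc, out = 0, []
        for x in d:
            acc += x
            out.append(acc)
        bcum[v] = tuple(out)
    forward = {v: sum(d) for v, d in fdist_t.items()}
    backward = {v: sum(d) for v, d in bdist_t.items()}
    return PathCounts(
        forward, backward, total, fdist_t, bdist_t, bcum, fbest, bbest, thr
    )


def containing_path_count(
    counts: PathCounts, u: Vertex, v: Vertex, weight: int
) -> int:
    """Number of admissible full paths containing a fixed contiguous
    subpath from ``u`` to ``v`` of total edge weight ``weight``.

    A containing path is a prefix to ``u`` plus the subpath plus a
    suffix from ``v``; it is admissible when prefix + weight + suffix
    reaches the score threshold, which the shortfall distributions
    resolve exactly.
    """
    fb = counts.fbest.get(u)
    bb = counts.bbest.get(v)
    if fb is None or bb is None:
        return 0
    slack = fb + weight + bb - counts.threshold
    if slack < 0:
        return 0
    fd = counts.forward_dist.get(u, ())
    bc = counts.backward_cum.get(v, ())
    if not fd or not bc:
        return 0
    total = 0
    top = len(bc) - 1
    for k1 in range(min(len(fd), slack + 1)):
        c = fd[k1]
        if c:
            total += c * bc[min(slack - k1, top)]
    return total


def edge_support(dag: AlignmentDag, counts: PathCounts, edge: DagEdge) -> Fraction:
    """Exact fraction of all admissible alignment paths that use
    ``edge``."""
    if edge not in dag.edge_set:
        raise ValueError(f"edge {edge} is not in the alignment graph")
    return Fraction(
        containing_path_count(counts, edge.frm, edge.to, edge.weight), counts.total
    )


def _check_contiguous(path: Sequence[DagEdge]) -> None:
    for prev, nxt in zip(path, path[1:]):
        if prev.to != nxt.frm:
            raise ValueError("subpath is not contiguous")


def subpath_support(
    dag: AlignmentDag,
    counts: PathCounts,
    path: Sequence[DagEdge],
    anchor: Vertex | None = None,
) -> Fraction:
    """Exact fraction of full paths containing a contiguous subpath.

    A path containing the subpath is one that reaches its first vertex,
    follows its edges exactly, then continues to the sink; it counts
    only if its total score is admissible.  An empty subpath must be
    anchored at a vertex and yields that vertex's support.
    """
    if not path:
        if anchor is None:
            raise ValueError("empty subpath requires an anchor vertex")
        if anchor not in dag.vertices:
            raise ValueError(f"vertex {anchor} is not in the alignment graph")
        return Fraction(
            containing_path_count(counts, anchor, anchor, 0), counts.total
        )
    for e in path:
        if e not in dag.edge_set:
            raise ValueError(f"edge {e} is not in the alignment graph")
    _check_contiguous(path)
    weight = sum(e.weight for e in path)
    return Fraction(
        containing_path_count(counts, path[0].frm, path[-1].to, weight),
        counts.total,
    )


def project_window(
    window: SafetyWindow | Sequence[DagEdge], dag: AlignmentDag
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Project a window (or raw subpath) onto 0-based half-open sequence
    intervals: the spans of consumed symbols between its endpoints."""
    path = window.path if isinstance(window, SafetyWindow) else tuple(window)
    if not path:
        raise ValueError("cannot project an empty subpath")
    for e in path:
        if e not in dag.edge_set:
            raise ValueError(f"edge {e} is not in the alignment graph")
    _check_contiguous(path)
    i0, j0, _ = path[0].frm
    i1, j1, _ = path[-1].to
    return (i0, i1), (j0, j1)


def _chain_windows(
    dag: AlignmentDag, counts: PathCounts, alpha: Fraction
) -> list[SafetyWindow]:
    """Maximal α-safe windows for α > 1/2 via the safe-vertex chain.

    All vertices of an α-safe subpath have vertex support ≥ α; with
    α > 1/2 those vertices pairwise co-occur on a full path and hence
    form a single chain, consecutive chain members being joined by the
    unique edge between them.  Subpath supports shrink monotonically
    under extension on either side, so maximal windows fall out of a
    two-pointer sweep along each edge-connected chain segment.
    """
    p, q = alpha.numerator, alpha.denominator
    bound = p * counts.total
    safe = [
        v
        for v in dag.vertices
        if containing_path_count(counts, v, v, 0) * q >= bound
    ]
    safe.sort(key=lambda v: (v[0] + v[1], v[0], v[2]))
    if len(safe) < 2:
        return []

    # Split the chain where consecutive safe vertices are not joined by an
    # edge: no window can span the break, since any intermediate vertex of
    # a safe subpath would itself be safe.
    segments: list[list[Vertex]] = [[safe[0]]]
    links: list[list[DagEdge]] = [[]]
    for v in safe[1:]:
        e = dag.find_edge(segments[-1][-1], v)
        if e is None:
            segments.append([v])
            links.append([])
        else:
            segments[-1].append(v)
            links[-1].append(e)

    windows: list[SafetyWindow] = []
    for verts, edges in zip(segments, links):
        if len(verts) < 2:
            continue
        cw = [0]  # cumulative chain-edge weight
        for e in edges:
            cw.append(cw[-1] + e.weight)

        def count(l: int, r: int) -> int:
            return containing_path_count(counts, verts[l], verts[r], cw[r] - cw[l])

        r = 0
        prev_r = -1
        for l in range(len(verts) - 1):
            if r < l:
                r = l
            while r + 1 < len(verts) and count(l, r + 1) * q >= bound:
                r += 1
            if r > l and r > prev_r:
                path = tuple(edges[l:r])
                support = Fraction(count(l, r), counts.total)
                (a0, a1), (b0, b1) = project_window(path, dag)
                windows.append(SafetyWindow(path, support, (a0, a1), (b0, b1)))
                prev_r = r
    windows.sort(key=lambda w: (w.a_interval[0], w.b_interval[0]))
    return windows


def _enumeration_windows(
    dag: AlignmentDag, counts: PathCounts, alpha: Fraction, oracle_bound: int
) -> list[SafetyWindow]:
    """Brute-force maximal α-safe subpath search over every enumerated
    alignment; used only for α ≤ 1/2 on small inputs."""
    paths = [
        path
        for path, _ in enumerate_alignments(
            dag.seq_a, dag.seq_b, dag.params, oracle_bound=oracle_bound
        )
    ]
    if len(paths) != counts.total:
        raise AssertionError(
            f"enumeration found {len(paths)} paths but the graph counts "
            f"{counts.total}"
        )
    p, q = alpha.numerator, alpha.denominator
    sub_counts: dict[tuple[DagEdge, ...], int] = {}
    for path in paths:
        n = len(path)
        for s in range(n):
            for e in range(s + 1, n + 1):
                key = path[s:e]
                sub_counts[key] = sub_counts.get(key, 0) + 1
    safe = {sp for sp, c in sub_counts.items() if c * q >= p * counts.total}
    maximal = [
        sp
        for sp in safe
        if not any(
            (other[1:] == sp or other[:-1] == sp) for other in safe if len(other) == len(sp) + 1
        )
    ]
    windows = []
    for sp in maximal:
        support = Fraction(sub_counts[sp], counts.total)
        (a0, a1), (b0, b1) = project_window(sp, dag)
        windows.append(SafetyWindow(sp, support, (a0, a1), (b0, b1)))
    windows.sort(key=lambda w: (w.a_interval[0], w.b_interval[0], w.path))
    return windows


def extract_safety_windows(
    dag: AlignmentDag,
    counts: PathCounts,
    alpha: Fraction | float | str | None = None,
    oracle_bound: int = 64,
) -> list[SafetyWindow]:
    """All maximal contiguous subpaths with support ≥ α, sorted by start
    coordinate.  Windows contain at least one edge; single safe vertices
    (zero-length intervals) are not reported."""
    alpha = dag.params.alpha if alpha is None else as_fraction(alpha)
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if not dag.edges:
        return []
    if 2 * alpha > 1:
        return _chain_windows(dag, counts, alpha)
    warnings.warn(
        f"alpha={alpha} <= 1/2: falling back to exhaustive enumeration, "
        "which is limited to small inputs",
        stacklevel=2,
    )
    return _enumeration_windows(dag, counts, alpha, oracle_bound)


def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(intervals):
        if e <= end:
            continue
        total += e - max(s, end)
        end = e
    return total


def safe_coverage(
    result_or_windows: "SafetyResult | Sequence[SafetyWindow]", dag: AlignmentDag
) -> tuple[float, float]:
    """Fraction of each sequence's residues covered by the union of
    projected window intervals."""
    windows = (
        result_or_windows.windows
        if isinstance(result_or_windows, SafetyResult)
        else tuple(result_or_windows)
    )
    m, n = dag.shape
    cov_a = _union_length([w.a_interval for w in windows]) / m if m else 0.0
    cov_b = _union_length([w.b_interval for w in windows]) / n if n else 0.0
    return cov_a, cov_b


def compute_safety(
    dag: AlignmentDag,
    counts: PathCounts | None = None,
    alpha: Fraction | float | None = None,
    with_edge_track: bool = True,
    oracle_bound: int = 64,
) -> SafetyResult:
    """Run the full safety computation on a built alignment graph."""
    counts = counts if counts is not None else count_paths(dag)
    alpha_f = dag.params.alpha if alpha is None else as_fraction(alpha)
    windows = tuple(extract_safety_windows(dag, counts, alpha_f, oracle_bound))
    cov_a, cov_b = safe_coverage(windows, dag)
    track = (
        {e: edge_support(dag, counts, e) for e in dag.edges}
        if with_edge_track
        else None
    )
    return SafetyResult(
        opt_score=dag.opt_score,
        total=counts.total,
        windows=windows,
        edge_fractions=track,
        safe_coverage_a=cov_a,
        safe_coverage_b=cov_b,
        len_a=len(dag.seq_a),
        len_b=len(dag.seq_b),
        alpha=alpha_f,
        delta=dag.params.delta,
    )


def analyze_pair(seq_a: str, seq_b: str, params, with_edge_track: bool = True):
    """Convenience wrapper: build the Δ-suboptimal graph, count paths and
    extract windows in one call.  Returns ``(dag, counts, result)``."""
    from .core_dag import build_suboptimal_dag

    dag = build_suboptimal_dag(seq_a, seq_b, params)
    counts = count_paths(dag)
    result = compute_safety(dag, counts, with_edge_track=with_edge_track)
    return dag, counts, result
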