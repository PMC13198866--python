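from fractions import Fraction

import numpy as np
import pytest

import _oracle
from alnsafe import (
    AlignmentParams,
    build_suboptimal_dag,
    compute_safety,
    count_paths,
    edge_support,
    extract_safety_windows,
    project_window,
    safe_coverage,
    subpath_support,
)
from alnsafe.core_dag import DIAGONAL, VERTICAL
from alnsafe.safety import SafetyWindow
from conftest import random_seq


class TestCountPaths:
    def test_single_path(self, single_path_dag):
        counts = count_paths(single_path_dag)
        assert counts.total == 1
        assert all(v == 1 for v in counts.forward.values())

    def test_detour_graph_counts_three_paths(self, detour_dag):
        assert count_paths(detour_dag).total == 3

    def test_forward_and_backward_totals_agree(self, blosum62):
        rng = np.random.default_rng(3)
        for _ in range(15):
            a = random_seq(rng, "ACDEFGHIKLMNPQ", 3, 20)
            b = random_seq(rng, "ACDEFGHIKLMNPQ", 3, 20)
            dag = build_suboptimal_dag(
                a, b, AlignmentParams(matrix=blosum62, gap_open=5, gap_extend=1, delta=6)
            )
            counts = count_paths(dag)  # raises internally on any mismatch
            assert counts.total >= 1
            assert sum(
                counts.forward.get(v, 0) for v in dag.end_vertices
            ) == counts.total

    def test_flow_conservation(self, detour_dag):
        counts = count_paths(detour_dag)
        for v in detour_dag.vertices:
            if v == detour_dag.source:
                continue
            incoming = detour_dag.in_edges.get(v, ())
            assert counts.forward.get(v, 0) == sum(
                counts.forward.get(e.frm, 0) for e in incoming
            )


class TestSupports:
    def test_every_edge_of_a_single_path_has_full_support(self, single_path_dag):
        counts = count_paths(single_path_dag)
        for e in single_path_dag.edges:
            assert edge_support(single_path_dag, counts, e) == 1

    def test_detour_edges_each_carry_a_third(self, detour_dag):
        counts = count_paths(detour_dag)
        for e in detour_dag.edges:
            assert edge_support(detour_dag, counts, e) == Fraction(1, 3)

    def test_foreign_edge_rejected(self, single_path_dag, detour_dag):
        counts = count_paths(single_path_dag)
        with pytest.raises(ValueError, match="not in the alignment graph"):
            edge_support(single_path_dag, counts, detour_dag.edges[1])

    def test_empty_subpath_gives_vertex_support(self, detour_dag):
        counts = count_paths(detour_dag)
        assert subpath_support(detour_dag, counts, [], anchor=detour_dag.source) == 1
        assert subpath_support(
            detour_dag, counts, [], anchor=(1, 1, 0)
        ) == Fraction(1, 3)

    def test_full_path_support_in_single_path_graph(self, single_path_dag):
        counts = count_paths(single_path_dag)
        assert subpath_support(single_path_dag, counts, single_path_dag.edges) == 1

    def test_non_contiguous_subpath_rejected(self, single_path_dag):
        counts = count_paths(single_path_dag)
        sub = [single_path_dag.edges[0], single_path_dag.edges[2]]
        with pytest.raises(ValueError, match="contiguous"):
            subpath_support(single_path_dag, counts, sub)

    def test_supports_match_enumeration_counts(self, blosum62):
        rng = np.random.default_rng(17)
        for _ in range(20):
            a = random_seq(rng, "ACDE", 1, 6)
            b = random_seq(rng, "ACDE", 1, 6)
            params = AlignmentParams(
                matrix=blosum62, gap_open=2, gap_extend=1, delta=int(rng.choice([1, 3]))
            )
            dag = build_suboptimal_dag(a, b, params)
            counts = count_paths(dag)
            paths = _oracle.suboptimal_paths(a, b, params)
            assert counts.total == len(paths)
            oracle_counts = _oracle.edge_counts(a, b, params, paths)
            for e in dag.edges:
                assert edge_support(dag, counts, e) == Fraction(
                    oracle_counts[e], len(paths)
                )


class TestWindows:
    def test_alpha_one_single_path_yields_whole_path_window(self, single_path_dag):
        counts = count_paths(single_path_dag)
        windows = extract_safety_windows(single_path_dag, counts, 1)
        assert len(windows) == 1
        w = windows[0]
        assert w.path == single_path_dag.edges
        assert w.support == 1
        assert w.a_interval == (0, 3) and w.b_interval == (0, 3)

    def test_alpha_one_detour_graph_has_no_windows(self, detour_dag):
        counts = count_paths(detour_dag)
        assert extract_safety_windows(detour_dag, counts, 1) == []

    def test_alpha_validation(self, single_path_dag):
        counts = count_paths(single_path_dag)
        for bad in (0, -1, Fraction(3, 2)):
            with pytest.raises(ValueError, match="alpha"):
                extract_safety_windows(single_path_dag, counts, bad)

    def test_float_alpha_thresholds_are_decimal_exact(self, single_path_dag):
        counts = count_paths(single_path_dag)
        windows = extract_safety_windows(single_path_dag, counts, 0.6)
        assert windows and windows[0].support >= Fraction(3, 5)

    @pytest.mark.parametrize("alpha", [Fraction(3, 5), Fraction(3, 4), Fraction(1)])
    def test_windows_match_exhaustive_search(self, blosum62, alpha):
        rng = np.random.default_rng(int(alpha * 60))
        for _ in range(25):
            a = random_seq(rng, "ACDE", 1, 6)
            b = random_seq(rng, "ACDE", 1, 6)
            params = AlignmentParams(
                matrix=blosum62,
                gap_open=int(rng.choice([0, 2])),
                gap_extend=1,
                delta=int(rng.choice([0, 1, 3])),
            )
            dag = build_suboptimal_dag(a, b, params)
            counts = count_paths(dag)
            got = {w.path: w.support for w in extract_safety_windows(dag, counts, alpha)}
            paths = _oracle.suboptimal_paths(a, b, params)
            expected = _oracle.maximal_safe_windows(a, b, params, paths, alpha)
            assert got == expected

    def test_low_alpha_falls_back_to_enumeration(self, blosum62):
        a, b = "ACDA", "ACA"
        params = AlignmentParams(matrix=blosum62, gap_open=2, gap_extend=1, delta=4)
        dag = build_suboptimal_dag(a, b, params)
        counts = count_paths(dag)
        with pytest.warns(UserWarning, match="exhaustive enumeration"):
            got = {w.path: w.support for w in extract_safety_windows(dag, counts, Fraction(1, 3))}
        paths = _oracle.suboptimal_paths(a, b, params)
        expected = _oracle.maximal_safe_windows(a, b, params, paths, Fraction(1, 3))
        assert got == expected

    def test_windows_are_pairwise_non_nested(self, blosum62):
        rng = np.random.default_rng(31)
        for _ in range(10):
            a = random_seq(rng, "ACDEFGHIKL", 8, 16)
            b = random_seq(rng, "ACDEFGHIKL", 8, 16)
            params = AlignmentParams(matrix=blosum62, gap_open=4, gap_extend=1, delta=6)
            dag = build_suboptimal_dag(a, b, params)
            windows = extract_safety_windows(dag, count_paths(dag), Fraction(3, 4))
            for wi in windows:
                for wj in windows:
                    if wi is not wj:
                        assert not _contains(wj.path, wi.path)


def _contains(big, small):
    n, k = len(big), len(small)
    return any(big[off : off + k] == tuple(small) for off in range(n - k + 1))


class TestProjectionAndCoverage:
    def test_whole_path_projection(self, single_path_dag):
        counts = count_paths(single_path_dag)
        w = extract_safety_windows(single_path_dag, counts, 1)[0]
        assert project_window(w, single_path_dag) == ((0, 3), (0, 3))

    def test_indel_window_projects_to_zero_length_interval(self, identity):
        params = AlignmentParams(matrix=identity, gap_open=2, gap_extend=1, delta=0)
        dag = build_suboptimal_dag("AC", "C", params)
        counts = count_paths(dag)
        windows = extract_safety_windows(dag, counts, 1)
        assert len(windows) == 1
        (a0, a1), (b0, b1) = windows[0].a_interval, windows[0].b_interval
        assert (a1 - a0, b1 - b0) == (2, 1)
        vertical = [e for e in windows[0].path if e.kind == VERTICAL]
        assert len(vertical) == 1
        assert project_window([vertical[0]], dag)[1][0] == project_window(
            [vertical[0]], dag
        )[1][1]

    def test_full_coverage_and_no_coverage(self, single_path_dag):
        counts = count_paths(single_path_dag)
        result = compute_safety(single_path_dag, counts, alpha=1)
        assert (result.safe_coverage_a, result.safe_coverage_b) == (1.0, 1.0)
        assert safe_coverage([], single_path_dag) == (0.0, 0.0)

    def test_overlapping_windows_cover_their_union(self, identity):
        params = AlignmentParams(matrix=identity, gap_open=2, gap_extend=1, delta=0)
        dag = build_suboptimal_dag("ACDE", "ACDE", params)
        fake = [
            SafetyWindow((), Fraction(1), (0, 2), (0, 2)),
            SafetyWindow((), Fraction(1), (1, 3), (1, 3)),
        ]
        assert safe_coverage(fake, dag) == (0.75, 0.75)


class TestMonotonicity:
    def test_coverage_never_increases_with_alpha(self, blosum62):
        rng = np.random.default_rng(41)
        for _ in range(8):
            a = random_seq(rng, "ACDEFGHIKLMNPQRSTVWY", 10, 14)
            b = random_seq(rng, "ACDEFGHIKLMNPQRSTVWY", 10, 14)
            params = AlignmentParams(matrix=blosum62, gap_open=4, gap_extend=1, delta=8)
            dag = build_suboptimal_dag(a, b, params)
            counts = count_paths(dag)
            prev_cov = None
            prev_windows = None
            for alpha in (Fraction(3, 5), Fraction(3, 4), Fraction(9, 10), Fraction(1)):
                windows = extract_safety_windows(dag, counts, alpha)
                cov = sum(safe_coverage(windows, dag))
                if prev_cov is not None:
                    assert cov <= prev_cov + 1e-12
                    for w in windows:
                        assert any(_contains(pw.path, w.path) for pw in prev_windows)
                prev_cov, prev_windows = cov, windows

    def test_total_paths_never_decrease_with_delta(self, blosum62):
        rng = np.random.default_rng(43)
        for _ in range(8):
            a = random_seq(rng, "ACDEFGHIKL", 8, 14)
            b = random_seq(rng, "ACDEFGHIKL", 8, 14)
            prev = None
            for delta in (0, 1, 3, 6, 12):
                params = AlignmentParams(
                    matrix=blosum62, gap_open=4, gap_extend=1, delta=delta
                )
                dag = build_suboptimal_dag(a, b, params)
                total = count_paths(dag).total
                if prev is not None:
                    assert total >= prev
                prev = total
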