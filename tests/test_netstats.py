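"""Projections, co-occurrence, clustering, NODF, driver summaries."""

import math
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rsnet
from rsnet import netstats
from rsnet.errors import UndefinedStatisticError

from conftest import make_network
from _oracles import (
    cooccurrence_count_naive,
    mean_shared_per_connected_pair_naive,
    nodf_naive,
    random_binary_matrix,
    squares_and_three_paths_naive,
)


def net_from_matrix(A):
    A = np.asarray(A)
    return rsnet.BipartiteNetwork(
        [f"s{i}" for i in range(A.shape[0])],
        [f"d{j}" for j in range(A.shape[1])],
        A,
    )


binary_matrices = st.integers(0, 10_000).map(
    lambda s: random_binary_matrix(np.random.default_rng(s), 5, 6, 0.4)
)


class TestProjection:
    def test_single_shift_three_drivers_is_unit_triangle(self):
        net = make_network([("A", "x"), ("A", "y"), ("A", "z")])
        proj = rsnet.project_one_mode(net, "driver")
        W = proj.weights
        assert W.shape == (3, 3)
        assert (W[np.triu_indices(3, 1)] == 1).all()
        assert (np.diag(W) == 0).all()

    def test_fixture_climate_and_greenhouse_share_two_shifts(self, table1_canonical):
        net, _ = table1_canonical
        proj = rsnet.project_one_mode(net, "driver")
        i = proj.node_names.index("climate change")
        j = proj.node_names.index("greenhouse gases")
        assert proj.weights[i, j] == 2

    def test_weight_bounded_by_min_degree(self, table1_canonical):
        net, _ = table1_canonical
        W = rsnet.project_one_mode(net, "driver").weights
        deg = net.driver_degrees
        bound = np.minimum.outer(deg, deg)
        np.fill_diagonal(bound, 0)
        assert (W <= bound).all()

    @pytest.mark.parametrize(
        "edges,expected",
        [
            ([("A", "x"), ("A", "y"), ("A", "z")], 2.0),  # triangle
            ([("A", "x"), ("B", "y")], 0.0),  # no co-occurrence
            ([("A", "x"), ("A", "y"), ("B", "z"), ("B", "w")], 1.0),  # two dyads
        ],
    )
    def test_projection_mean_degree(self, edges, expected):
        net = make_network(edges)
        assert rsnet.mean_degree(rsnet.project_one_mode(net, "driver")) == expected


class TestCoOccurrence:
    def test_one_shift_with_three_drivers(self):
        net = make_network([("A", "x"), ("A", "y"), ("A", "z")])
        index, count = rsnet.co_occurrence_index(net, "driver")
        assert count == 3 and index == 1.0

    @pytest.mark.parametrize("k", [2, 4, 7])
    def test_one_shift_with_k_drivers_closed_form(self, k):
        net = make_network([("A", f"d{i}") for i in range(k)])
        _, count = rsnet.co_occurrence_index(net, "driver")
        assert count == math.comb(k, 2)

    def test_fixture_matches_exhaustive_pair_enumeration(self, table1_canonical):
        net, _ = table1_canonical
        for side in ("driver", "shift"):
            _, count = rsnet.co_occurrence_index(net, side)
            assert count == cooccurrence_count_naive(net.incidence, side)

    def test_connected_pair_mean_matches_enumeration(self, table1_canonical):
        net, _ = table1_canonical
        for side in ("driver", "shift"):
            got = netstats.co_occurrence_per_connected_pair(net, side)
            assert got == pytest.approx(
                mean_shared_per_connected_pair_naive(net.incidence, side)
            )

    def test_single_node_side_is_undefined(self):
        net = make_network([("A", "x")])
        with pytest.raises(UndefinedStatisticError):
            rsnet.co_occurrence_index(net, "driver")

    def test_projection_weight_sum_equals_open_triangles(self, rsdb_like):
        net, _, _ = rsdb_like
        for side in ("driver", "shift"):
            W = rsnet.project_one_mode(net, side).weights
            _, count = rsnet.co_occurrence_index(net, side)
            assert W[np.triu_indices_from(W, 1)].sum() == count


class TestClusteringCoefficient:
    def test_complete_2x2_is_one(self):
        cc, squares, paths = rsnet.bipartite_clustering_coefficient(
            net_from_matrix([[1, 1], [1, 1]])
        )
        assert (cc, squares, paths) == (1.0, 1, 4)

    def test_star_has_no_three_paths(self):
        cc, squares, paths = rsnet.bipartite_clustering_coefficient(
            net_from_matrix([[1], [1], [1]])
        )
        assert squares == 0 and paths == 0 and math.isnan(cc)

    def test_random_6x6_matches_subgraph_enumeration(self):
        for seed in range(50):
            A = random_binary_matrix(np.random.default_rng(seed), 6, 6, 0.35)
            cc, squares, paths = rsnet.bipartite_clustering_coefficient(net_from_matrix(A))
            sq_o, pa_o = squares_and_three_paths_naive(A)
            assert (squares, paths) == (sq_o, pa_o)
            if pa_o:
                assert cc == pytest.approx(4 * sq_o / pa_o)

    @given(binary_matrices, st.data())
    def test_adding_a_link_never_decreases_squares_or_triangles(self, A, data):
        empty = np.argwhere(A == 0)
        if len(empty) == 0:
            return
        i, j = empty[data.draw(st.integers(0, len(empty) - 1))]
        before = rsnet.bipartite_clustering_coefficient(net_from_matrix(A))
        _, c_before = rsnet.co_occurrence_index(net_from_matrix(A), "driver")
        A2 = A.copy()
        A2[i, j] = 1
        after = rsnet.bipartite_clustering_coefficient(net_from_matrix(A2))
        _, c_after = rsnet.co_occurrence_index(net_from_matrix(A2), "driver")
        assert after[1] >= before[1]
        assert c_after >= c_before


class TestNodf:
    def test_perfect_staircase_is_100(self):
        res = rsnet.nodf_nestedness(net_from_matrix([[1, 1, 1], [1, 1, 0], [1, 0, 0]]))
        assert res.total == pytest.approx(100.0)

    def test_identity_matrix_is_0(self):
        res = rsnet.nodf_nestedness(net_from_matrix(np.eye(3, dtype=int)))
        assert res.total == 0.0

    def test_random_8x8_matches_double_loop_oracle(self):
        for seed in range(50):
            A = random_binary_matrix(np.random.default_rng(100 + seed), 8, 8, 0.4)
            res = rsnet.nodf_nestedness(net_from_matrix(A))
            assert res.total == pytest.approx(nodf_naive(A))

    @given(binary_matrices)
    def test_range_and_contribution_consistency(self, A):
        res = rsnet.nodf_nestedness(net_from_matrix(A))
        assert 0.0 <= res.total <= 100.0
        assert 0.0 <= res.rows <= 100.0 and 0.0 <= res.cols <= 100.0
        assert ((res.row_contributions >= 0) & (res.row_contributions <= 100)).all()

    def test_matches_vegan_reference_implementation(self, tmp_path):
        A = random_binary_matrix(np.random.default_rng(42), 8, 10, 0.4)
        np.savetxt(tmp_path / "m.csv", A, fmt="%d", delimiter=",")
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            m <- as.matrix(read.csv('{tmp_path / "m.csv"}', header=FALSE))
            r <- nestednodf(m, order=TRUE)
            cat(sprintf('%.12f', c(r$statistic[['NODF']], r$statistic[['N.rows']], r$statistic[['N.columns']])), sep=',')
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.strip()
        total_r, rows_r, cols_r = map(float, out.split(","))
        res = rsnet.nodf_nestedness(net_from_matrix(A))
        assert res.total == pytest.approx(total_r, abs=1e-6)
        assert res.rows == pytest.approx(rows_r, abs=1e-6)
        assert res.cols == pytest.approx(cols_r, abs=1e-6)


class TestDriverSummary:
    def test_degree_one_share_uses_truncated_percentages(self, rsdb_like):
        net, _, _ = rsdb_like
        ds = rsnet.driver_summary(net)
        assert ds.n_drivers == 57
        assert len(ds.idiosyncratic_drivers) == 14
        assert ds.idiosyncratic_pct == 24  # floor(100 * 14/57)

    def test_half_coverage_strictly_exceeds_half(self):
        # degrees {5,1,1,1}: 8 links, the top driver alone holds 5 > 4
        net = make_network(
            [(f"s{i}", "big") for i in range(5)]
            + [("s0", "a"), ("s1", "b"), ("s2", "c")]
        )
        ds = rsnet.driver_summary(net)
        assert ds.half_coverage_drivers == ["big"]
        assert ds.half_coverage_pct == 25

    def test_half_coverage_thirteen_of_57_is_22_pct(self):
        # 13 drivers of degree 11 carry 143 of 275 links (> half);
        # 12 carry 132 (not more than half)
        edges = []
        for j in range(13):
            edges += [(f"s{i}", f"top{j:02d}") for i in range(11)]
        for j in range(44):
            edges += [(f"s{i}", f"tail{j:02d}") for i in range(3)]
        ds = rsnet.driver_summary(make_network(edges))
        assert ds.n_drivers == 57
        assert len(ds.half_coverage_drivers) == 13
        assert ds.half_coverage_pct == 22

    def test_shift_degree_range_reported(self, table1_raw):
        net, _ = table1_raw
        ds = rsnet.driver_summary(net)
        assert ds.shift_degree_min[1] == 3 and ds.shift_degree_max[1] == 3


class TestSharedPairs:
    def test_threshold_one_returns_all_cooccurring_pairs(self):
        net = make_network([("A", "x"), ("A", "y"), ("A", "z")])
        pairs = rsnet.shared_driver_pairs(net, "driver", 1)
        assert len(pairs) == 3

    def test_threshold_above_max_weight_is_empty(self, table1_canonical):
        net, _ = table1_canonical
        assert len(rsnet.shared_driver_pairs(net, "driver", 26)) == 0

    def test_fixture_contains_climate_greenhouse_pair_at_2(self, table1_canonical):
        net, _ = table1_canonical
        pairs = rsnet.shared_driver_pairs(net, "driver", 2)
        hit = pairs[
            (pairs.node_a == "climate change") & (pairs.node_b == "greenhouse gases")
        ]
        assert len(hit) == 1 and hit.iloc[0]["shared"] == 2

    def test_sorted_by_count_then_name(self, table1_canonical):
        net, _ = table1_canonical
        pairs = rsnet.shared_driver_pairs(net, "driver", 1)
        counts = pairs["shared"].to_numpy()
        assert (np.diff(counts) <= 0).all()
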