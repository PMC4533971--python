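"""Distances, UPGMA clustering, classical MDS, vector fitting, blocks."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

import rsnet
from rsnet import ordination, synth
from rsnet.errors import FormatError, UndefinedStatisticError

from conftest import make_network


def dm(names, condensed, metric="test"):
    return ordination.DistanceMatrix(list(names), squareform(condensed), metric)


class TestPairwiseDistance:
    def test_identical_neighbour_sets_distance_zero(self):
        net = make_network([("A", "x"), ("A", "y"), ("B", "x"), ("B", "y")])
        for metric in ("sorensen_dice", "jaccard"):
            D = rsnet.pairwise_distance(net, "shift", metric).distances
            assert D[0, 1] == 0.0

    def test_disjoint_sets_distance_one(self):
        net = make_network([("A", "x"), ("B", "y")])
        for metric in ("sorensen_dice", "jaccard"):
            assert rsnet.pairwise_distance(net, "shift", metric).distances[0, 1] == 1.0

    def test_fixture_climate_vs_greenhouse(self, table1_canonical):
        net, _ = table1_canonical
        for metric, expected in [("jaccard", 7 / 9), ("sorensen_dice", 7 / 11)]:
            D = rsnet.pairwise_distance(net, "driver", metric)
            i = D.node_names.index("climate change")
            j = D.node_names.index("greenhouse gases")
            assert D.distances[i, j] == pytest.approx(expected)

    def test_empty_neighbour_set_reported_by_name(self):
        net = rsnet.BipartiteNetwork(
            ["A", "B"], ["x", "lonely"], np.array([[1, 0], [1, 0]])
        )
        with pytest.raises(UndefinedStatisticError, match="lonely"):
            rsnet.pairwise_distance(net, "driver", "jaccard")

    def test_jaccard_triangle_inequality_on_random_triples(self, rng):
        net, _, _ = rsnet.generate_rsdb_like(5)
        D = rsnet.pairwise_distance(net, "driver", "jaccard").distances
        n = D.shape[0]
        for _ in range(1000):
            i, j, k = rng.choice(n, 3, replace=False)
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestUpgma:
    def test_closed_form_two_then_one(self):
        d = dm(["A", "B", "C"], [1.0, 4.0, 4.0])
        dend = rsnet.upgma_cluster(d)
        assert dend.linkage[0, 2] == pytest.approx(1.0)
        assert dend.linkage[1, 2] == pytest.approx(4.0)

    def test_ultrametric_input_reproduced_exactly(self):
        # heights 1, 2, 3 over four leaves
        D = np.array(
            [
                [0, 1, 3, 3],
                [1, 0, 3, 3],
                [3, 3, 0, 2],
                [3, 3, 2, 0],
            ],
            dtype=float,
        )
        d = ordination.DistanceMatrix(list("abcd"), D, "ultra")
        dend = rsnet.upgma_cluster(d)
        C = dend.cophenetic().distances
        assert np.allclose(C, D)

    def test_matches_scipy_on_tie_free_instances(self, rng):
        for _ in range(10):
            n = 10
            cond = rng.random(n * (n - 1) // 2) + 0.01
            d = dm([f"L{i}" for i in range(n)], cond)
            dend = rsnet.upgma_cluster(d)
            ours = cophenet(dend.linkage)
            scipys = cophenet(linkage(cond, method="average"))
            assert np.allclose(np.sort(ours), np.sort(scipys))
            # same pairwise cophenetic structure, not just the same heights
            assert np.allclose(ours, scipys)

    def test_lexical_tie_break(self):
        # all distances equal: the lexically smallest pair merges first
        d = dm(["zeta", "alpha", "beta"], [1.0, 1.0, 1.0])
        dend = rsnet.upgma_cluster(d)
        first = sorted(
            dend.leaf_names[int(k)] for k in dend.linkage[0, :2]
        )
        assert first == ["alpha", "beta"]

    def test_nan_rejected(self):
        with pytest.raises(FormatError):
            rsnet.upgma_cluster(dm("ab", [np.nan]))

    def test_newick_round_trips_through_skbio(self, table1_canonical):
        skbio = pytest.importorskip("skbio")
        net, _ = table1_canonical
        dend = rsnet.upgma_cluster(rsnet.pairwise_distance(net, "driver", "jaccard"))
        tree = skbio.TreeNode.read([dend.to_newick()])
        tips = {t.name for t in tree.tips()}
        assert tips == set(dend.leaf_names)

    def test_heights_non_decreasing(self, table1_canonical):
        net, _ = table1_canonical
        for side, metric in (("shift", "sorensen_dice"), ("driver", "jaccard")):
            dend = rsnet.upgma_cluster(rsnet.pairwise_distance(net, side, metric))
            assert (np.diff(dend.heights()) >= -1e-12).all()


class TestClassicalMds:
    def test_three_collinear_points(self):
        d = dm(["a", "b", "c"], [1.0, 2.0, 1.0])  # a-b 1, a-c 2, b-c 1
        ordn = rsnet.classical_mds(d, k=1)
        x = ordn.coordinates[:, 0]
        assert np.allclose(sorted(x), [-1, 0, 1], atol=1e-9)
        assert ordn.eigenvalues[0] == pytest.approx(2.0)
        assert abs(ordn.eigenvalues[1]) < 1e-9

    def test_planted_point_cloud_recovered(self, rng):
        pts = rng.normal(size=(12, 2))
        D = squareform(pdist(pts))
        ordn = rsnet.classical_mds(
            ordination.DistanceMatrix([f"p{i}" for i in range(12)], D, "euclid"), k=2
        )
        D2 = squareform(pdist(ordn.coordinates))
        assert np.allclose(D, D2, atol=1e-8)

    def test_duplicate_points_coincide(self):
        d = dm(["a", "b", "c"], [0.0, 1.0, 1.0])
        ordn = rsnet.classical_mds(d, k=1)
        assert ordn.coordinates[0, 0] == pytest.approx(ordn.coordinates[1, 0])

    def test_requesting_too_many_axes_warns_and_truncates(self):
        d = dm(["a", "b", "c"], [1.0, 2.0, 1.0])
        with pytest.warns(UserWarning):
            ordn = rsnet.classical_mds(d, k=3)
        assert ordn.coordinates.shape[1] == 1

    def test_axes_ordered_and_centered(self, table1_canonical):
        net, _ = table1_canonical
        d = rsnet.pairwise_distance(net, "shift", "sorensen_dice")
        ordn = rsnet.classical_mds(d, k=3)
        assert (np.diff(ordn.eigenvalues) <= 1e-9).all()
        assert np.allclose(ordn.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_agrees_with_skbio_pcoa(self, table1_canonical):
        skbio = pytest.importorskip("skbio")
        net, _ = table1_canonical
        d = rsnet.pairwise_distance(net, "shift", "sorensen_dice")
        ours = rsnet.classical_mds(d, k=2)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.distances, ids=d.node_names)
        )
        for k in range(2):
            a = ours.coordinates[:, k]
            b = ref.samples[f"PC{k+1}"].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)


class TestFitVariables:
    def _ordination(self, rng, n=25):
        pts = rng.normal(size=(n, 2))
        pts -= pts.mean(axis=0)
        names = [f"p{i}" for i in range(n)]
        return ordination.Ordination(
            names, pts, np.array([2.0, 1.0]), np.array([0.6, 0.3])
        )

    def test_variable_equal_to_axis_one(self, rng):
        ordn = self._ordination(rng)
        variables = pd.DataFrame({"v": ordn.coordinates[:, 0]}, index=ordn.node_names)
        fit = rsnet.fit_variables(ordn, variables, n_perm=99, rng=rng)[0]
        assert fit.r_squared == pytest.approx(1.0)
        assert abs(fit.direction[0]) == pytest.approx(1.0, abs=1e-9)
        assert fit.permutation_p == pytest.approx(1 / 100)

    def test_constant_variable_flagged_and_skipped(self, rng):
        ordn = self._ordination(rng)
        variables = pd.DataFrame({"c": np.ones(25)}, index=ordn.node_names)
        fit = rsnet.fit_variables(ordn, variables, n_perm=99, rng=rng)[0]
        assert fit.skipped
        assert ordination.significant_variables([fit]) == []

    def test_planted_signal_detected_at_moderate_noise(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ordn = self._ordination(rng)
            y = ordn.coordinates[:, 0] + rng.normal(
                scale=ordn.coordinates[:, 0].std() / 3, size=25
            )
            variables = pd.DataFrame({"v": y}, index=ordn.node_names)
            fit = rsnet.fit_variables(ordn, variables, n_perm=199, rng=rng)[0]
            hits += fit.permutation_p < 0.05
        assert hits >= 8

    def test_misaligned_variables_rejected(self, rng):
        ordn = self._ordination(rng)
        variables = pd.DataFrame({"v": [1.0]}, index=["nope"])
        with pytest.raises(FormatError):
            rsnet.fit_variables(ordn, variables, n_perm=99, rng=rng)


class TestCategoricalBlocks:
    def test_block_sizes_accepted_and_distances_valid(self, rsdb_like):
        _, attrs, _ = rsdb_like
        blocks = synth.shift_block_columns()
        dists = rsnet.categorical_block_distance(attrs, blocks)
        assert set(dists) == set(blocks)
        for d in dists.values():
            assert (d.distances >= 0).all() and (d.distances <= 1).all()

    def test_identical_profiles_zero_complementary_one(self):
        df = pd.DataFrame(
            {
                "node": ["A", "B", "C"],
                "side": "shift",
                "v1": [1, 1, 0],
                "v2": [0, 0, 1],
                "v3": [1, 1, 0],
            }
        )
        attrs = rsnet.AttributeTable(df)
        d = rsnet.categorical_block_distance(attrs, {"blk": ["v1", "v2", "v3"]})["blk"]
        assert d.distances[0, 1] == 0.0  # identical
        assert d.distances[0, 2] == 1.0  # complementary

    def test_zero_columns_dropped_before_computing(self):
        df = pd.DataFrame(
            {"node": ["A", "B"], "side": "shift", "v1": [1, 1], "dead": [0, 0]}
        )
        attrs = rsnet.AttributeTable(df)
        d = rsnet.categorical_block_distance(attrs, {"blk": ["v1", "dead"]})["blk"]
        assert d.distances[0, 1] == 0.0

    def test_all_zero_profile_raises(self):
        df = pd.DataFrame({"node": ["A", "B"], "side": "shift", "v1": [1, 0]})
        attrs = rsnet.AttributeTable(df)
        with pytest.raises(UndefinedStatisticError, match="B"):
            rsnet.categorical_block_distance(attrs, {"blk": ["v1"]})

    def test_unknown_variable_rejected(self):
        df = pd.DataFrame({"node": ["A"], "side": "shift", "v1": [1]})
        with pytest.raises(FormatError):
            rsnet.categorical_block_distance(
                rsnet.AttributeTable(df), {"blk": ["v1", "ghost"]}
            )
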