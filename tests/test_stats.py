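import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import to_tree
from scipy.spatial.distance import pdist

from virotyper import stats

from _oracles import naive_linkage_order, stress1_oracle


class TestDiversity:
    def test_shannon_maximum_entropy(self):
        d = stats.diversity([10, 10, 10, 10])
        assert d.shannon == pytest.approx(np.log(4))

    def test_simpson_closed_forms(self):
        assert stats.diversity([7]).simpson == pytest.approx(0.0)
        assert stats.diversity([5, 5]).simpson == pytest.approx(0.5)

    def test_chao1_hand_example(self):
        d = stats.diversity([1, 1, 2, 3])
        assert d.species_richness == 4
        assert d.chao1 == pytest.approx(4.5)

    def test_chao1_equals_richness_without_singletons(self):
        d = stats.diversity([2, 3, 4, 100])
        assert d.chao1 == d.species_richness

    def test_invariants(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 50, int(rng.integers(2, 40)))
            d = stats.diversity(counts)
            assert d.shannon <= np.log(d.species_richness) + 1e-12
            assert d.chao1 >= d.species_richness
            assert 0 <= d.simpson < 1
            scaled = stats.diversity(counts * 3)
            assert scaled.simpson == pytest.approx(d.simpson)

    def test_matches_independent_estimators(self, rng):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        counts = rng.integers(0, 30, 50)
        counts[0] = 1  # ensure a singleton
        d = stats.diversity(counts)
        assert d.shannon == pytest.approx(skbio_alpha.shannon(counts, base=np.e))
        assert d.simpson == pytest.approx(skbio_alpha.simpson(counts))
        assert d.chao1 == pytest.approx(skbio_alpha.chao1(counts, bias_corrected=True))

    def test_all_zero_sample_is_error(self):
        with pytest.raises(ValueError):
            stats.diversity([0, 0])


class TestRange01:
    def test_hand_example(self):
        table = pd.DataFrame({"a": [10], "b": [20], "c": [30]}, index=["v"])
        assert stats.range01(table).loc["v"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_maps_to_zero(self):
        table = pd.DataFrame({"a": [5], "b": [5], "c": [5]}, index=["v"])
        assert stats.range01(table).loc["v"].tolist() == [0.0, 0.0, 0.0]

    def test_binary_unchanged(self):
        table = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]}, index=["v", "w"])
        pd.testing.assert_frame_equal(stats.range01(table), table)


class TestNMDS:
    def test_collinear_configuration_has_zero_stress(self):
        table = pd.DataFrame(
            [[0.0, 1.0, 2.0], [0.0, 2.0, 4.0]], index=["v1", "v2"],
            columns=["a", "b", "c"],
        )
        result = stats.nmds(table, seed=1, n_starts=5)
        assert result.stress <= 1e-6

    def test_deterministic_for_fixed_seed(self, rng):
        table = pd.DataFrame(rng.random((20, 5)), columns=list("abcde"))
        r1 = stats.nmds(table, seed=42)
        r2 = stats.nmds(table, seed=42)
        pd.testing.assert_frame_equal(r1.coordinates, r2.coordinates)
        assert r1.stress == r2.stress

    def test_stress_agrees_with_independent_recomputation(self, rng):
        table = pd.DataFrame(rng.random((50, 10)),
                             columns=[f"s{i}" for i in range(10)])
        result = stats.nmds(table, seed=7, n_starts=10)
        dissim = pdist(table.T.to_numpy())
        oracle = stress1_oracle(dissim, result.coordinates.to_numpy())
        assert result.stress == pytest.approx(oracle, abs=1e-6)

    def test_too_few_samples_is_error(self):
        table = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["v"])
        with pytest.raises(ValueError, match="3 samples"):
            stats.nmds(table)


class TestFitVectors:
    @pytest.fixture()
    def ordination(self, rng):
        coords = pd.DataFrame(rng.normal(size=(10, 2)),
                              index=[f"s{i}" for i in range(10)],
                              columns=["NMDS1", "NMDS2"])
        return stats.OrdinationResult(coordinates=coords, stress=0.1)

    def test_axis_aligned_variable(self, ordination):
        variables = pd.DataFrame({"x": ordination.coordinates["NMDS1"]})
        fitted = stats.fit_vectors(ordination, variables, n_permutations=99, seed=0)
        assert fitted.loc["x", "r_squared"] == pytest.approx(1.0)
        assert abs(fitted.loc["x", "axis1"]) == pytest.approx(1.0)
        assert abs(fitted.loc["x", "axis2"]) == pytest.approx(0.0, abs=1e-8)

    def test_constant_variable_flagged_unreliable(self, ordination):
        variables = pd.DataFrame({"c": np.ones(10)},
                                 index=ordination.coordinates.index)
        fitted = stats.fit_vectors(ordination, variables, n_permutations=49, seed=0)
        assert not fitted.loc["c", "reliable"]
        assert np.isnan(fitted.loc["c", "r_squared"])

    def test_permutation_null_type_one_error(self, rng):
        """Independent variables should be 'reliable' ~5% of the time."""
        coords = pd.DataFrame(rng.normal(size=(10, 2)),
                              index=[f"s{i}" for i in range(10)],
                              columns=["NMDS1", "NMDS2"])
        ordination = stats.OrdinationResult(coordinates=coords, stress=0.1)
        n_reps, hits = 1000, 0
        for rep in range(n_reps):
            y = pd.DataFrame({"y": rng.normal(size=10)}, index=coords.index)
            fitted = stats.fit_vectors(ordination, y, n_permutations=199, seed=rep)
            hits += int(fitted.loc["y", "p_value"] <= 0.05)
        # binomial 99.9% interval around 0.05
        from scipy.stats import binom
        lo, hi = binom.interval(0.999, n_reps, 0.05)
        assert lo <= hits <= hi


class TestClustering:
    def test_upgma_hand_example(self):
        # d(A,B)=1, d(A,C)=d(B,C)=10 by placing points on a line
        table = pd.DataFrame({"A": [0.0], "B": [1.0], "C": [10.5]}, index=["v"])
        z, labels, newick = stats.cluster_samples(table, method="average")
        assert z[0, 2] == pytest.approx(1.0)       # first merge (A, B) at height 1
        assert z[1, 2] == pytest.approx(10.0)      # then C joins at mean(10.5, 9.5)
        assert "(A:1,B:1)" in newick or "(B:1,A:1)" in newick

    def test_duplicate_samples_merge_at_zero(self):
        table = pd.DataFrame({"A": [1.0, 2.0], "B": [1.0, 2.0], "C": [9.0, 9.0]})
        z, _, _ = stats.cluster_samples(table)
        assert z[0, 2] == pytest.approx(0.0)

    def test_merge_heights_nondecreasing(self, rng):
        table = pd.DataFrame(rng.random((6, 7)), columns=[f"s{i}" for i in range(7)])
        z, _, _ = stats.cluster_samples(table)
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_upgma_equals_brute_force(self, rng, n):
        points = rng.random((n, 3))
        table = pd.DataFrame(points.T, columns=[f"s{i}" for i in range(n)])
        z, labels, _ = stats.cluster_samples(table, method="average")
        history, heights = naive_linkage_order(points, "average")
        tree = to_tree(z)

        def members(node):
            return sorted(leaf.id for leaf in _leaves(node))

        def _leaves(node):
            if node.is_leaf():
                return [node]
            return _leaves(node.left) + _leaves(node.right)

        scipy_merges = []
        def collect(node):
            if node.is_leaf():
                return
            collect(node.left)
            collect(node.right)
            scipy_merges.append((node.dist, tuple(members(node))))
        collect(tree)
        scipy_merges.sort()
        oracle = sorted(zip(heights, [tuple(h) for h in history]))
        for (h1, m1), (h2, m2) in zip(scipy_merges, oracle):
            assert h1 == pytest.approx(h2)
            assert m1 == m2


class TestHeatmapOrder:
    def test_log_transform_of_zero(self):
        table = pd.DataFrame({"a": [0.0, 9.0], "b": [0.0, 99.0]}, index=["v", "w"])
        _, _, logged = stats.heatmap_order(table)
        assert logged.loc["v"].tolist() == [0.0, 0.0]
        assert logged.loc["w"].tolist() == [1.0, 2.0]

    def test_identical_rows_adjacent(self, rng):
        base = rng.random(4)
        table = pd.DataFrame(
            [base, rng.random(4) * 10, base, rng.random(4) * 10 + 5],
            index=["dup1", "x", "dup2", "y"],
            columns=[f"s{i}" for i in range(4)],
        )
        row_order, _, _ = stats.heatmap_order(table)
        positions = {name: i for i, name in enumerate(row_order)}
        assert abs(positions["dup1"] - positions["dup2"]) == 1

    def test_leaf_order_matches_brute_force_complete_link(self, rng):
        points = rng.random((5, 4)) * 3
        table = pd.DataFrame(points, index=[f"v{i}" for i in range(5)],
                             columns=[f"s{i}" for i in range(4)])
        row_order, _, logged = stats.heatmap_order(table)
        history, heights = naive_linkage_order(logged.to_numpy(), "complete")
        # every cluster the oracle dendrogram forms must be contiguous in the
        # leaf order (the defining property of a dendrogram leaf ordering)
        order_idx = [int(v[1:]) for v in row_order]
        pos = {i: p for p, i in enumerate(order_idx)}
        for cluster in history:
            ps = sorted(pos[i] for i in cluster)
            assert ps == list(range(ps[0], ps[0] + len(ps)))


class TestPairwiseChisq:
    def test_perfect_independence(self):
        table = pd.DataFrame({"a": [10, 10], "b": [10, 10]}, index=["x", "y"])
        res = stats.pairwise_chisq(table)
        assert res.loc[0, "chi2"] == pytest.approx(0.0)
        assert res.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_closed_form_pearson(self):
        table = pd.DataFrame({"a": [20, 10], "b": [10, 20]}, index=["x", "y"])
        res = stats.pairwise_chisq(table)
        assert res.loc[0, "chi2"] == pytest.approx(6.6667, abs=1e-4)
        assert res.loc[0, "df"] == 1
        assert res.loc[0, "p_raw"] == pytest.approx(0.00982, abs=1e-5)

    def test_bonferroni_multiplies_by_pair_count(self, rng):
        table = pd.DataFrame(rng.integers(1, 50, (10, 3)), columns=list("abc"))
        res = stats.pairwise_chisq(table)
        assert len(res) == 3
        np.testing.assert_allclose(
            res["p_bonferroni"], np.minimum(1.0, res["p_raw"] * 3)
        )

    def test_zero_sum_sample_is_error(self):
        table = pd.DataFrame({"a": [1, 2], "b": [0, 0]}, index=["x", "y"])
        with pytest.raises(ValueError, match="zero-sum"):
            stats.pairwise_chisq(table)
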