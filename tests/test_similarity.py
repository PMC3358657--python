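import numpy as np
import pytest
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from covbias import (
    ExperimentMeta,
    correlation_to_distance,
    lab_comparison,
    pearson,
    rank_sum_test,
    similarity_matrix,
    upgma,
)
from covbias.similarity import SimilarityMatrix
from _oracles import ranksum_enumeration, upgma_brute_force


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson([1, 5, 3], [1, 5, 3]) == pytest.approx(1.0)

    def test_worked_example(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_constant_vector_is_undefined_not_zero(self):
        assert pearson([2, 2, 2], [1, 2, 3]) is None

    def test_scaling_invariance(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert pearson(x, 3 * x) == pytest.approx(1.0)

    @given(
        x=st.lists(st.integers(-50, 50), min_size=3, max_size=12),
        a=st.floats(0.01, 100.0),
        b=st.floats(-10, 10),
    )
    def test_affine_invariance(self, x, a, b):
        x = np.array(x, dtype=float)
        r = pearson(x, a * x + b)
        if np.ptp(x) == 0:
            assert r is None
        else:
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])

    def test_nan_positions_excluded_pairwise(self):
        x = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        y = np.array([2.0, 9.0, 6.0, 8.0, 10.0])
        assert pearson(x, y) == pytest.approx(pearson([1, 3, 4, 5], [2, 6, 8, 10]))


class TestSimilarityMatrix:
    def test_single_gene_matrix_equals_pairwise_correlations(self, profile_set_factory):
        pset = profile_set_factory(
            {"g": {"a": [1, 2, 3, 4], "b": [1, 3, 2, 4], "c": [4, 3, 2, 1]}}
        )
        sim = similarity_matrix(pset)
        assert sim.entry("a", "b") == pytest.approx(0.8)
        assert sim.entry("a", "c") == pytest.approx(-1.0)
        assert np.allclose(np.diag(sim.values), 1.0)
        assert np.allclose(sim.values, sim.values.T, equal_nan=True)

    def test_mean_over_genes(self, profile_set_factory):
        # entry (a, b) must be the arithmetic mean of the per-gene correlations
        g1 = {"a": [1.0, 2, 3], "b": [2.2, 1, 2.7]}
        g2 = {"a": [1.0, 2, 3], "b": [1, 2.2, 2.5]}
        r1 = pearson(g1["a"], g1["b"])
        r2 = pearson(g2["a"], g2["b"])
        pset = profile_set_factory({"g1": g1, "g2": g2})
        sim = similarity_matrix(pset)
        assert sim.entry("a", "b") == pytest.approx((r1 + r2) / 2)

    def test_undefined_genes_skipped_in_average(self, profile_set_factory):
        pset = profile_set_factory(
            {
                "flat": {"a": [5, 5, 5], "b": [1, 2, 3]},
                "ok": {"a": [1, 2, 3], "b": [1, 2, 3]},
            }
        )
        sim = similarity_matrix(pset)
        assert sim.entry("a", "b") == pytest.approx(1.0)

    def test_all_constant_experiment_propagates_undefined(self, profile_set_factory):
        pset = profile_set_factory(
            {"g": {"a": [1, 1, 1], "b": [1, 2, 3], "c": [3, 1, 2]}}
        )
        sim = similarity_matrix(pset)
        assert np.isnan(sim.entry("a", "b"))
        assert not np.isnan(sim.entry("b", "c"))

    def test_permutation_equivariance(self, profile_set_factory):
        data = {"g": {"a": [1, 2, 3, 1], "b": [2, 1, 3, 4], "c": [5, 1, 2, 2]}}
        sim1 = similarity_matrix(profile_set_factory(data))
        pset2 = profile_set_factory(data)
        perm = [2, 0, 1]
        pset2.experiments = [pset2.experiments[i] for i in perm]
        sim2 = similarity_matrix(pset2)
        for a in "abc":
            for b in "abc":
                assert sim2.entry(a, b) == pytest.approx(sim1.entry(a, b))

    def test_fewer_than_two_experiments_rejected(self, profile_set_factory):
        pset = profile_set_factory({"g": {"a": [1, 2, 3]}})
        with pytest.raises(ValueError):
            similarity_matrix(pset)


class TestCorrelationToDistance:
    @pytest.mark.parametrize("r,expected", [(1.0, 0.0), (0.0, 1.0), (-0.5, 1.5)])
    def test_affine_map(self, r, expected):
        sim = SimilarityMatrix(["a", "b"], np.array([[1.0, r], [r, 1.0]]))
        d = correlation_to_distance(sim)
        assert d[0, 1] == pytest.approx(expected)
        assert d[0, 0] == d[1, 1] == 0.0

    def test_halved_transform(self):
        sim = SimilarityMatrix(["a", "b"], np.array([[1.0, -1.0], [-1.0, 1.0]]))
        assert correlation_to_distance(sim, "(1-r)/2")[0, 1] == pytest.approx(1.0)


class TestUpgma:
    def test_two_leaves_merge_at_half_distance(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        dendro = upgma(d, ["A", "B"])
        assert len(dendro.merges) == 1
        assert dendro.merges[0][2] == pytest.approx(1.5)

    def test_three_leaf_hand_example(self):
        # d(A,B)=2, d(A,C)=8, d(B,C)=8: merge (A,B) at 1, then with C at 4
        d = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        dendro = upgma(d, ["A", "B", "C"])
        heights = [m[2] for m in dendro.merges]
        assert heights == pytest.approx([1.0, 4.0])
        assert dendro.merges[0][:2] == (0, 1)

    def test_oracle_equivalence_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(5, 9))
            m = rng.uniform(0.1, 2.0, size=(n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            heights = sorted(h for _a, _b, h, _s in upgma(d).merges)
            assert np.allclose(heights, upgma_brute_force(d), atol=1e-12)

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            m = rng.uniform(0.1, 2.0, size=(n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            ours = sorted(2 * h for _a, _b, h, _s in upgma(d).merges)
            Z = scipy.cluster.hierarchy.linkage(
                scipy.spatial.distance.squareform(d), method="average"
            )
            assert np.allclose(ours, sorted(Z[:, 2]), atol=1e-10)

    def test_heights_non_decreasing_and_cophenetic_ultrametric(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0.5, 2.0, size=(7, 7))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        dendro = upgma(d)
        heights = [h for _a, _b, h, _s in dendro.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))
        coph = dendro.cophenetic()
        n = 7
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if len({i, j, k}) == 3:
                        assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-12

    def test_undefined_entries_rejected_with_guidance(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="impute|drop"):
            upgma(d)

    def test_newick_round_trips_leaf_set(self):
        d = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        nwk = upgma(d, ["A", "B", "C"]).to_newick()
        assert nwk.endswith(";")
        for leaf in "ABC":
            assert leaf in nwk


class TestRankSum:
    def test_exact_worked_example(self):
        u, p, method = rank_sum_test([0.9, 0.8], [0.1, 0.2], "greater")
        assert u == pytest.approx(4.0)  # maximal U for 2x2
        assert p == pytest.approx(1 / 6, abs=1e-12)
        assert method == "exact"

    def test_identical_multisets_two_sided_p_is_one(self):
        _u, p, _m = rank_sum_test([0.3, 0.5], [0.5, 0.3], "two-sided")
        assert p == pytest.approx(1.0)

    @given(
        within=st.lists(st.integers(0, 8), min_size=2, max_size=5),
        between=st.lists(st.integers(0, 8), min_size=2, max_size=5),
        alternative=st.sampled_from(["greater", "less", "two-sided"]),
    )
    @settings(max_examples=40)
    def test_dp_agrees_with_literal_enumeration(self, within, between, alternative):
        """The subset-sum DP must match brute-force enumeration of every
        label assignment, ties included."""
        _u, p, method = rank_sum_test(within, between, alternative)
        assert method == "exact"
        assert p == pytest.approx(ranksum_enumeration(within, between, alternative), abs=1e-12)

    def test_asymptotic_branch_matches_scipy(self):
        rng = np.random.default_rng(5)
        within = rng.normal(0.5, 0.1, 120)
        between = rng.normal(0.3, 0.1, 120)
        u, p, method = rank_sum_test(within, between, "greater")
        assert method == "asymptotic"
        ref = scipy.stats.mannwhitneyu(within, between, alternative="greater")
        assert p == pytest.approx(float(ref.pvalue))
        assert u == pytest.approx(float(ref.statistic))


class TestLabComparison:
    @staticmethod
    def _sim(values, ids):
        return SimilarityMatrix(ids, np.asarray(values, dtype=float))

    def test_pair_partition_two_labs_of_two(self):
        ids = ["a1", "a2", "b1", "b2"]
        meta = [ExperimentMeta(e, e[0]) for e in ids]
        vals = np.ones((4, 4))
        vals[0, 1] = vals[1, 0] = 0.9
        vals[2, 3] = vals[3, 2] = 0.8
        for i, j in [(0, 2), (0, 3), (1, 2), (1, 3)]:
            vals[i, j] = vals[j, i] = 0.1
        comp = lab_comparison(self._sim(vals, ids), meta)
        assert len(comp.within) == 2 and len(comp.between) == 4
        assert comp.within_mean == pytest.approx(0.85)
        assert comp.between_mean == pytest.approx(0.1)
        assert comp.method == "exact"

    def test_all_one_lab_rejected(self):
        ids = ["a1", "a2"]
        meta = [ExperimentMeta(e, "a") for e in ids]
        with pytest.raises(ValueError, match="between"):
            lab_comparison(self._sim([[1, 0.5], [0.5, 1]], ids), meta)

    def test_all_singleton_labs_rejected(self):
        ids = ["a1", "b1"]
        meta = [ExperimentMeta(e, e[0]) for e in ids]
        with pytest.raises(ValueError, match="within"):
            lab_comparison(self._sim([[1, 0.5], [0.5, 1]], ids), meta)

    def test_undefined_entry_rejected(self):
        ids = ["a1", "a2", "b1"]
        meta = [ExperimentMeta(e, e[0]) for e in ids]
        vals = np.array([[1, 0.5, np.nan], [0.5, 1, 0.2], [np.nan, 0.2, 1]])
        with pytest.raises(ValueError, match="undefined"):
            lab_comparison(self._sim(vals, ids), meta)
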