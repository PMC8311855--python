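"""Network construction: partial Spearman, permutation check, thresholding."""

import numpy as np
import pytest

from cognet.battery import PROSE_MEMORY_TESTS, canonical_battery
from cognet.netbuild import (
    EdgeStats,
    build_edge_stats,
    changed_edges,
    partial_spearman,
    permutation_p,
    threshold_to_graph,
)
from cognet.metrics import whole_density
from conftest import single_group_cohort
from oracles import partial_spearman_oracle


def make_edge(a, b, rho, p, p_perm=None):
    return EdgeStats(
        test_a=a, test_b=b, rho=rho, p_analytic=p,
        n_used=70, covariates_used=("age", "education"),
        p_permutation=p_perm,
    )


class TestPartialSpearman:
    def test_identity_gives_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        rho, p = partial_spearman(x, x)
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_printed_vectors_match_rank_residual_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        z = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        rho, _ = partial_spearman(x, y, z[:, None])
        assert rho == pytest.approx(partial_spearman_oracle(x, y, z[:, None]), abs=1e-12)
        # closed form: residuals alternate +-1/2 in opposite phase
        assert rho == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("k", [0, 1, 2])
    def test_random_data_matches_oracle(self, k):
        rng = np.random.default_rng(42 + k)
        for _ in range(25):
            n = int(rng.integers(15, 60))
            data = rng.normal(size=(n, 2 + k))
            cov = data[:, 2:] if k else None
            rho, _ = partial_spearman(data[:, 0], data[:, 1], cov)
            assert rho == pytest.approx(
                partial_spearman_oracle(data[:, 0], data[:, 1], cov), abs=1e-12
            )

    def test_no_covariates_equals_plain_spearman(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 40))
        rho, p = partial_spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=0.05)

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, np.nan, 6.0, 7.0])
        rho, _ = partial_spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_constant_variable_raises(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman([1.0] * 10, list(range(10)))

    def test_insufficient_n_raises(self):
        with pytest.raises(ValueError, match="insufficient"):
            partial_spearman([1.0, 2.0], [2.0, 1.0], np.ones((2, 2)))


class TestPermutationP:
    def test_identical_vectors_reach_minimum_p(self):
        x = np.arange(20.0)
        cov = np.random.default_rng(1).normal(size=(20, 2))
        p = permutation_p(x, x, cov, n_perm=500, seed=3)
        assert p == pytest.approx(1.0 / 501.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 40))
        cov = rng.normal(size=(40, 2))
        p1 = permutation_p(x, y, cov, n_perm=1000, seed=11)
        p2 = permutation_p(x, y, cov, n_perm=1000, seed=11)
        assert p1 == p2

    def test_uninformative_n_perm_rejected(self):
        with pytest.raises(ValueError, match="uninformative"):
            permutation_p(np.arange(10.0), np.arange(10.0), n_perm=50)

    def test_tracks_analytic_p_on_null_data(self):
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(20):
            x, y = rng.normal(size=(2, 70))
            cov = rng.normal(size=(70, 2))
            rho, p_a = partial_spearman(x, y, cov)
            if 0.01 < p_a < 0.5:
                p_p = permutation_p(x, y, cov, n_perm=5000, seed=1)
                diffs.append(abs(p_p - p_a))
        assert diffs and max(diffs) < 0.03


class TestBuildEdgeStats:
    def test_sixteen_tests_give_120_pairs(self):
        table = single_group_cohort(seed=1, n=40)
        edges = build_edge_stats(table, validate_band=None)
        assert len(edges) == 120  # C(16, 2)

    def test_missing_columns_drop_to_14_nodes_91_pairs(self):
        table = single_group_cohort(seed=1, n=40)
        for col in PROSE_MEMORY_TESTS:
            table[col] = np.nan
        edges = build_edge_stats(table, validate_band=None)
        assert len(edges) == 91  # C(14, 2)
        present = {e.test_a for e in edges} | {e.test_b for e in edges}
        assert len(present) == 14
        assert not present & set(PROSE_MEMORY_TESTS)

    def test_null_group_has_nominal_positive_rate(self):
        hits = total = 0
        for seed in range(30):
            table = single_group_cohort(seed=seed, n=70)
            edges = build_edge_stats(table, validate_band=None)
            hits += sum(e.p_analytic < 0.05 for e in edges)
            total += len(edges)
        assert 0.03 < hits / total < 0.07

    def test_permutation_only_inside_band(self):
        table = single_group_cohort(seed=3, n=70, r_within=0.4, r_between=0.1)
        edges = build_edge_stats(
            table, validate_band=(0.01, 0.1), n_perm=200, seed=0
        )
        for e in edges:
            in_band = 0.01 < e.p_analytic < 0.1
            assert (e.p_permutation is not None) == in_band

    def test_missing_covariate_column_raises(self):
        table = single_group_cohort(seed=1, n=40).drop(columns=["education"])
        with pytest.raises(KeyError, match="education"):
            build_edge_stats(table)

    def test_pair_order_independent_of_permutation_seeding(self):
        table = single_group_cohort(seed=3, n=70, r_within=0.4)
        e1 = build_edge_stats(table, n_perm=200, seed=9)
        e2 = build_edge_stats(table, n_perm=200, seed=9)
        assert e1 == e2


class TestThresholdToGraph:
    def test_strict_alpha_cut(self):
        edges = [make_edge("a", "b", 0.3, 0.049), make_edge("a", "c", 0.3, 0.051),
                 make_edge("b", "c", 0.3, 0.2)]
        g = threshold_to_graph(edges, alpha=0.05)
        assert set(g.edges()) == {("a", "b")}

    def test_negative_edge_policy(self):
        edges = [make_edge("a", "b", -0.4, 0.001)]
        assert threshold_to_graph(edges, drop_negative=True).n_edges == 0
        kept = threshold_to_graph(edges, drop_negative=False)
        assert set(kept.edges()) == {("a", "b")}

    def test_all_insignificant_gives_empty_graph(self):
        edges = [make_edge("a", "b", 0.1, 1.0), make_edge("b", "c", 0.1, 1.0),
                 make_edge("a", "c", 0.1, 1.0)]
        g = threshold_to_graph(edges)
        assert g.n_edges == 0
        assert whole_density(g) == 0.0

    def test_permutation_p_replaces_analytic_in_band(self):
        edges = [make_edge("a", "b", 0.3, 0.04, p_perm=0.08),
                 make_edge("a", "c", 0.3, 0.08, p_perm=0.04)]
        default = threshold_to_graph(edges, use_permutation_in_band=False)
        swapped = threshold_to_graph(edges, use_permutation_in_band=True)
        assert set(default.edges()) == {("a", "b")}
        assert set(swapped.edges()) == {("a", "c")}

    def test_alpha_monotonicity(self):
        table = single_group_cohort(seed=2, n=70, r_within=0.4, r_between=0.1)
        edges = build_edge_stats(table, validate_band=None)
        strict = set(threshold_to_graph(edges, alpha=0.01).edges())
        loose = set(threshold_to_graph(edges, alpha=0.05).edges())
        assert strict <= loose

    def test_symmetry_and_zero_diagonal(self):
        table = single_group_cohort(seed=2, n=70, r_within=0.4)
        g = threshold_to_graph(build_edge_stats(table, validate_band=None))
        assert np.array_equal(g.adjacency, g.adjacency.T)
        assert np.diag(g.adjacency).sum() == 0

    def test_invalid_alpha(self):
        with pytest.raises(ValueError, match="alpha"):
            threshold_to_graph([], alpha=1.5)


class TestCovariateSensitivity:
    def test_zero_education_effect_changes_few_edges(self):
        # education has no planted influence: dropping it from the
        # regressors should leave the edge set essentially unchanged
        table = single_group_cohort(seed=4, n=75, r_within=0.5, r_between=0.1)
        both = threshold_to_graph(
            build_edge_stats(table, ("age", "education"), validate_band=None)
        )
        age_only = threshold_to_graph(
            build_edge_stats(table, ("age",), validate_band=None)
        )
        assert len(changed_edges(both, age_only)) / 120 <= 0.05

    def test_strong_education_effect_changes_edges(self):
        effects = {
            t: (0.0, 0.25 if i < 8 else 0.0)
            for i, t in enumerate(canonical_battery().names)
        }
        table = single_group_cohort(seed=4, n=75, covariate_effects=effects)
        with_edu = threshold_to_graph(
            build_edge_stats(table, ("age", "education"), validate_band=None)
        )
        without = threshold_to_graph(
            build_edge_stats(table, ("age",), validate_band=None)
        )
        assert len(changed_edges(with_edu, without)) > 0
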