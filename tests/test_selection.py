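"""Subset selection: stepwise, Lasso/LARS, GA, GreedGene, and the planner."""

from itertools import combinations

import numpy as np
import pytest

from s2rqsar import (
    SelectionConfig,
    count_combinations,
    forward_stepwise,
    ga_select,
    greedgene,
    lasso_path_select,
    prune_correlated,
)
from s2rqsar.selection import FitnessCache, SelectionError

from conftest import make_matrix


def exhaustive_optimum(matrix, y, k):
    """Brute-force oracle: best k-subset by LOO Q2 over all C(p, k)."""
    cache = FitnessCache(matrix, y)
    best, best_fit = None, -np.inf
    for comb in combinations(range(matrix.n_descriptors), k):
        f = cache(comb)
        names = cache.name_tuple(comb)
        if f > best_fit or (f == best_fit and best is not None and names < best):
            best, best_fit = names, f
    return set(best), best_fit


class TestCountCombinations:
    @pytest.mark.parametrize(
        "n,k,expected",
        [
            (160, 5, 820_384_032),
            (5, 5, 1),
            (158, 3, 158 * 157 * 156 // 6),  # = 644,956
            (10, 0, 1),
        ],
    )
    def test_exact_values(self, n, k, expected):
        assert count_combinations(n, k) == expected

    def test_errors(self):
        with pytest.raises(SelectionError):
            count_combinations(3, 5)
        with pytest.raises(SelectionError):
            count_combinations(-1, 0)


class TestForwardStepwise:
    def test_exact_column_selected_first(self, small_planted):
        matrix, _ = small_planted
        y = matrix.values[:, 0].copy()  # y == column "A" exactly
        res = forward_stepwise(matrix, y, k=2)
        assert res.descriptor_names[0] == "A"

    def test_planted_pair_matches_exhaustive(self, small_planted):
        matrix, y = small_planted
        oracle, _ = exhaustive_optimum(matrix, y, 2)
        res = forward_stepwise(matrix, y, k=2)
        assert set(res.descriptor_names) == oracle == {"A", "B"}

    def test_k_equals_p_returns_all(self, rng):
        matrix = make_matrix(rng.standard_normal((30, 4)))
        res = forward_stepwise(matrix, rng.standard_normal(30), k=4)
        assert sorted(res.descriptor_names) == sorted(matrix.descriptor_names)

    def test_classic_entry_by_correlation(self, small_planted):
        matrix, y = small_planted
        res = forward_stepwise(matrix, y, k=2, classic=True)
        # B has the larger coefficient (3 vs 2), hence the larger marginal correlation
        assert res.descriptor_names[0] == "B"
        assert set(res.descriptor_names) == {"A", "B"}


class TestLassoPath:
    def test_exact_column_k1(self, small_planted):
        matrix, _ = small_planted
        y = matrix.values[:, 0].copy()
        res = lasso_path_select(matrix, y, k=1)
        assert res.descriptor_names == ["A"]

    def test_orthonormal_entry_order_is_correlation_order(self, rng):
        # on an orthonormal design LARS activates variables in descending |X'y|
        Q, _ = np.linalg.qr(rng.standard_normal((40, 6)))
        matrix = make_matrix(Q * np.sqrt(40), names=list("ABCDEF"))
        beta = np.array([0.0, 3.0, -2.0, 0.5, 0.0, 1.0])
        y = matrix.values @ beta
        Xs = (matrix.values - matrix.values.mean(0)) / matrix.values.std(0)
        expected = [matrix.descriptor_names[j] for j in np.argsort(-np.abs(Xs.T @ (y - y.mean())))[:3]]
        res = lasso_path_select(matrix, y, k=3)
        assert res.descriptor_names == expected

    def test_planted_support_recovered(self, small_planted):
        matrix, y = small_planted
        res = lasso_path_select(matrix, y, k=2)
        assert set(res.descriptor_names) == {"A", "B"}

    def test_too_few_activations_raises(self, rng):
        x = rng.standard_normal(30)
        matrix = make_matrix(np.column_stack([x, x, x]), names=["a", "b", "c"])
        with pytest.raises(SelectionError, match="entered"):
            lasso_path_select(matrix, x.copy(), k=3)


class TestGA:
    def test_p_equals_k_trivial(self, rng):
        matrix = make_matrix(rng.standard_normal((30, 3)))
        res = ga_select(matrix, rng.standard_normal(30), SelectionConfig(k=3, seed=0))
        assert sorted(res.descriptor_names) == sorted(matrix.descriptor_names)

    def test_planted_support_equals_exhaustive_oracle(self, rng):
        X = rng.standard_normal((80, 15))
        y = 2 * X[:, 3] + 1.5 * X[:, 7] + X[:, 11] + 0.35 * rng.standard_normal(80)
        matrix = make_matrix(X)
        oracle, oracle_fit = exhaustive_optimum(matrix, y, 3)
        res = ga_select(matrix, y, SelectionConfig(k=3, seed=1))
        assert set(res.descriptor_names) == oracle
        assert res.fitness_value == pytest.approx(oracle_fit, abs=1e-12)

    def test_two_seeds_agree_on_easy_instance(self, rng):
        X = rng.standard_normal((80, 15))
        y = 2 * X[:, 3] + 1.5 * X[:, 7] + X[:, 11] + 0.35 * rng.standard_normal(80)
        matrix = make_matrix(X)
        r1 = ga_select(matrix, y, SelectionConfig(k=3, seed=11))
        r2 = ga_select(matrix, y, SelectionConfig(k=3, seed=99))
        assert r1.descriptor_names == r2.descriptor_names

    def test_deterministic_per_seed(self, rng):
        X = rng.standard_normal((50, 12))
        y = rng.standard_normal(50)
        matrix = make_matrix(X)
        r1 = ga_select(matrix, y, SelectionConfig(k=4, seed=5))
        r2 = ga_select(matrix, y, SelectionConfig(k=4, seed=5))
        assert r1.descriptor_names == r2.descriptor_names
        assert r1.trace == r2.trace

    def test_population_too_small(self, rng):
        matrix = make_matrix(rng.standard_normal((30, 5)))
        with pytest.raises(SelectionError, match="population"):
            ga_select(matrix, rng.standard_normal(30), SelectionConfig(k=2, ga_population=1))


class TestGreedGene:
    def test_easy_instance_hits_global_optimum(self, rng):
        X = rng.standard_normal((100, 20))
        y = 2 * X[:, 2] + 1.5 * X[:, 9] + X[:, 17] + 0.3 * rng.standard_normal(100)
        matrix = make_matrix(X)
        oracle, oracle_fit = exhaustive_optimum(matrix, y, 3)
        res = greedgene(matrix, y, SelectionConfig(k=3, seed=4))
        assert set(res.descriptor_names) == oracle
        assert res.fitness_value == pytest.approx(oracle_fit, abs=1e-12)

    def test_exhaustive_accounting(self, rng):
        X = rng.standard_normal((100, 20))
        y = 2 * X[:, 2] + 1.5 * X[:, 9] + X[:, 17] + 0.3 * rng.standard_normal(100)
        matrix = make_matrix(X)
        res = greedgene(matrix, y, SelectionConfig(k=3, seed=4))
        assert res.exhaustive_evaluations == count_combinations(
            20 - len(res.core_names), 3 - len(res.core_names)
        )
        # a complete consensus core means a single (trivial) completion
        if len(res.core_names) == 3:
            assert res.exhaustive_evaluations == 1

    def test_fitness_at_least_every_ga_repeat(self, rng):
        X = rng.standard_normal((60, 25))
        y = X[:, 1] - X[:, 5] + 0.8 * X[:, 20] + 1.0 * rng.standard_normal(60)
        matrix = make_matrix(X)
        res = greedgene(matrix, y, SelectionConfig(k=3, seed=21))
        assert res.fitness_value >= max(res.trace) - 1e-12

    def test_budget_refusal_reports_count(self, rng):
        matrix = make_matrix(rng.standard_normal((40, 30)))
        y = rng.standard_normal(40)
        # one-generation GA repeats disagree, leaving a small core and a
        # large completion space that must be refused under a tiny budget
        cfg = SelectionConfig(
            k=5, seed=0, exhaustive_budget=10, ga_population=10, ga_generations=1
        )
        with pytest.raises(SelectionError, match="budget"):
            greedgene(matrix, y, cfg)

    def test_swap_refinement_recovers_pruned_group_member(self, rng):
        # the true support column "zz_true" is pruned away in favor of its
        # noisier near-duplicate "aa_dup" (lexicographic representative);
        # the swap stage must reach back into the correlation group
        n = 120
        true = rng.standard_normal(n)
        dup = true + 0.3 * rng.standard_normal(n)
        others = rng.standard_normal((n, 6))
        names = ["aa_dup", "bb1", "bb2", "bb3", "bb4", "bb5", "bb6", "zz_true"]
        full = make_matrix(np.column_stack([dup, others, true]), names=names)
        y = 2.0 * true + others[:, 0] + 0.4 * rng.standard_normal(n)
        pruned, groups = prune_correlated(full, threshold=0.9)
        assert "zz_true" not in pruned.descriptor_names
        assert sorted(groups["aa_dup"]) == ["aa_dup", "zz_true"]
        with_swap = greedgene(
            pruned, y, SelectionConfig(k=2, seed=3),
            correlation_groups=groups, swap_candidates=full,
        )
        without = greedgene(pruned, y, SelectionConfig(k=2, seed=3))
        assert "zz_true" in with_swap.descriptor_names
        assert with_swap.fitness_value > without.fitness_value


def test_all_selectors_return_k_distinct_pruned_names(small_planted):
    matrix, y = small_planted
    cfg = SelectionConfig(k=3, seed=0)
    results = [
        forward_stepwise(matrix, y, k=3),
        lasso_path_select(matrix, y, k=3),
        ga_select(matrix, y, cfg),
        greedgene(matrix, y, cfg),
    ]
    for res in results:
        assert len(res.descriptor_names) == 3
        assert len(set(res.descriptor_names)) == 3
        assert set(res.descriptor_names) <= set(matrix.descriptor_names)
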