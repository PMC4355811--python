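"""Fusion-operator semantics and the GP engine's structural invariants."""

from itertools import product

import numpy as np
import pytest

from gpes.gp import (
    GPConfig,
    GPIndividual,
    GPNode,
    crossover,
    evaluate_matrix,
    evaluate_node,
    evolve,
    mutate,
    predict_individual,
    ramped_half_and_half_init,
)


def term(i):
    return GPNode(terminal=i)


def op(name, *children):
    return GPNode(operator=name, children=list(children))


ALL_PATTERNS = list(product([-1, 1], repeat=3))


class TestOperatorSemantics:
    @pytest.mark.parametrize("pattern", ALL_PATTERNS)
    def test_min_max_average_match_exhaustive_oracles(self, pattern):
        votes = np.array(pattern)
        tree = {name: op(name, term(0), term(1), term(2)) for name in ("Min", "Max", "Average")}
        assert evaluate_node(tree["Min"], votes) == min(pattern)
        assert evaluate_node(tree["Max"], votes) == max(pattern)
        majority = 1 if sum(pattern) > 0 else -1
        assert evaluate_node(tree["Average"], votes) == majority

    def test_min_vetoes_positive_majority(self):
        assert evaluate_node(op("Min", term(0), term(1), term(2)), [-1, 1, 1]) == -1

    def test_max_rescues_single_positive(self):
        assert evaluate_node(op("Max", term(0), term(1), term(2)), [-1, -1, 1]) == 1

    def test_average_is_majority_of_three(self):
        assert evaluate_node(op("Average", term(0), term(1), term(2)), [1, 1, -1]) == 1

    def test_nested_seven_tree_worked_example(self):
        # Min( Average(T1,T2,T3), T4, Max(T5,T6,T7) ): with T1, T2 and T5
        # negative and the rest positive, the Average child already vetoes
        # through the Min root, so the ensemble answers negative even though
        # five of seven base trees voted positive.
        root = op(
            "Min",
            op("Average", term(0), term(1), term(2)),
            term(3),
            op("Max", term(4), term(5), term(6)),
        )
        votes = np.array([-1, -1, 1, 1, -1, 1, 1])
        assert evaluate_node(root, votes) == -1

    def test_unresolved_reference_raises(self):
        with pytest.raises(IndexError, match="unresolved"):
            evaluate_node(term(5), np.array([1, -1]))


class TestIndividualEvaluation:
    def test_unanimous_terminals_reproduce_the_classifier(self, rng):
        votes = rng.choice([-1, 1], size=(25, 4))
        ind = GPIndividual(root=op("Average", term(2), term(2), term(2)))
        np.testing.assert_array_equal(predict_individual(ind, votes), votes[:, 2])

    def test_min_root_positive_only_on_all_positive(self):
        ind = GPIndividual(root=op("Min", term(0), term(1), term(2)))
        votes = np.array(ALL_PATTERNS)
        pred = predict_individual(ind, votes)
        expected = np.array([1 if all(v == 1 for v in p) else -1 for p in ALL_PATTERNS])
        np.testing.assert_array_equal(pred, expected)

    def test_vectorised_evaluation_equals_per_sample_recursion(self, rng):
        ind = GPIndividual(
            root=op("Average", op("Min", term(0), term(1), term(2)),
                    term(3), op("Max", term(1), term(4), term(0)))
        )
        votes = rng.choice([-1, 1], size=(40, 5))
        fast = evaluate_matrix(ind.root, votes)
        slow = np.array([evaluate_node(ind.root, row) for row in votes])
        np.testing.assert_array_equal(fast, slow)


class TestInitialization:
    def test_full_depth2_tree_has_one_operator_three_terminals(self):
        from gpes.gp import _make_individual

        ind = _make_individual(2, 10, np.random.default_rng(0), full=True)
        assert len(ind.root.operators()) == 1
        assert len(ind.root.terminals()) == 3
        assert ind.root.depth() == 2

    def test_full_depth3_tree_has_four_operators_nine_terminals(self):
        from gpes.gp import _make_individual

        ind = _make_individual(3, 10, np.random.default_rng(0), full=True)
        assert len(ind.root.operators()) == 4
        assert len(ind.root.terminals()) == 9
        assert ind.root.depth() == 3

    def test_population_allocation_and_invariants(self):
        cfg = GPConfig(population_size=80, n_generations=1)
        pop = ramped_half_and_half_init(cfg, pool_size=12, rng=np.random.default_rng(3))
        assert len(pop) == 80
        for ind in pop:
            ind.validate()
            assert 2 <= ind.root.depth() <= 3
        # the two full cells contribute 20 exactly-depth-2 and 20 fully
        # grown depth-3 trees; grow trees can only add to those counts
        assert sum(1 for i in pop if len(i.root.operators()) == 1) >= 20
        assert sum(1 for i in pop if len(i.root.operators()) == 4) >= 20

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ramped_half_and_half_init(GPConfig(), 0, np.random.default_rng(0))


class TestVariation:
    def _random_population(self, rng, n=40, pool=15):
        cfg = GPConfig(population_size=n, n_generations=1)
        return ramped_half_and_half_init(cfg, pool, rng)

    def test_thousand_crossovers_never_violate_invariants(self, rng):
        pop = self._random_population(rng)
        for _ in range(1000):
            a, b = rng.integers(len(pop), size=2)
            ca, cb = crossover(pop[a], pop[b], rng)
            for child in (ca, cb):
                child.validate()
                assert child.root.depth() <= 3
                assert not child.root.is_terminal

    def test_leaf_swap_preserves_terminal_multiset_across_the_pair(self, rng):
        a = GPIndividual(root=op("Min", term(0), term(1), term(2)))
        b = GPIndividual(root=op("Max", term(3), term(4), term(5)))
        ca, cb = crossover(a, b, rng)
        combined = sorted(ca.root.terminals() + cb.root.terminals())
        assert combined == [0, 1, 2, 3, 4, 5]

    def test_thousand_mutations_preserve_structure(self, rng):
        pop = self._random_population(rng)
        for _ in range(1000):
            ind = pop[rng.integers(len(pop))]
            out = mutate(ind, 15, rng)
            out.validate()
            assert out.root.depth() == ind.root.depth()
            assert len(out.root.terminals()) == len(ind.root.terminals())

    def test_root_operator_mutation_changes_tie_sensitive_predictions(self):
        # Average and Min differ exactly on mixed patterns with a positive
        # majority containing at least one negative vote
        avg = GPIndividual(root=op("Average", term(0), term(1), term(2)))
        mn = GPIndividual(root=op("Min", term(0), term(1), term(2)))
        votes = np.array(ALL_PATTERNS)
        differs = predict_individual(avg, votes) != predict_individual(mn, votes)
        expected = [sum(p) == 1 for p in ALL_PATTERNS]  # two +1, one -1
        np.testing.assert_array_equal(differs, expected)

    def test_mutating_terminal_in_singleton_pool_is_behavioural_noop(self, rng):
        ind = GPIndividual(root=op("Average", term(0), term(0), term(0)))
        votes = rng.choice([-1, 1], size=(10, 1))
        out = mutate(ind, 1, rng)
        np.testing.assert_array_equal(
            predict_individual(out, votes), predict_individual(ind, votes)
        )


class TestEvolution:
    def _votes(self, rng, n_samples=30, n_pool=8, perfect=None):
        y = rng.choice([-1, 1], size=n_samples)
        votes = rng.choice([-1, 1], size=(n_samples, n_pool))
        if perfect is not None:
            votes[:, perfect] = y
        return votes, y

    def test_perfect_terminal_drives_best_fitness_to_one(self, rng):
        votes, y = self._votes(rng, perfect=3)
        cfg = GPConfig(population_size=20, n_generations=15)
        history = []
        pop = evolve(cfg, 8, votes, y, rng, history=history)
        assert max(ind.fitness for ind in pop) == 1.0
        assert any(h["best"] == 1.0 for h in history[:-1])  # well before the end

    def test_best_fitness_monotone_under_elitism(self, rng):
        votes, y = self._votes(rng)
        history = []
        evolve(GPConfig(population_size=16, n_generations=20), 8, votes, y, rng,
               history=history)
        best = [h["best"] for h in history]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_same_seed_gives_identical_final_population(self):
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        votes, y = self._votes(np.random.default_rng(0))
        cfg = GPConfig(population_size=12, n_generations=10)
        pop1 = evolve(cfg, 8, votes, y, rng1)
        pop2 = evolve(cfg, 8, votes, y, rng2)
        for a, b in zip(pop1, pop2):
            assert a.fitness == b.fitness
            np.testing.assert_array_equal(
                predict_individual(a, votes), predict_individual(b, votes)
            )

    def test_fitness_equals_independent_recomputation(self, rng):
        votes, y = self._votes(rng)
        pop = evolve(GPConfig(population_size=10, n_generations=3), 8, votes, y, rng)
        for ind in pop:
            assert 0 <= ind.fitness <= 1
            recomputed = np.mean(predict_individual(ind, votes) == y)
            assert ind.fitness == pytest.approx(recomputed)


def test_config_validation():
    with pytest.raises(ValueError, match="rates"):
        GPConfig(crossover_rate=1.5)
    with pytest.raises(ValueError, match="population"):
        GPConfig(population_size=1)
    with pytest.raises(ValueError, match="depth"):
        GPConfig(min_init_depth=1)


def test_node_invariants_enforced():
    with pytest.raises(ValueError, match="exactly 3"):
        op("Min", term(0), term(1)).validate()
    with pytest.raises(ValueError, match="root"):
        GPIndividual(root=term(0)).validate()
    deep = op("Min", op("Min", op("Min", term(0), term(0), term(0)),
                        term(0), term(0)), term(0), term(0))
    with pytest.raises(ValueError, match="depth"):
        GPIndividual(root=op("Min", deep, term(0), term(0))).validate()
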