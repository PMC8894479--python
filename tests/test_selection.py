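import itertools

import numpy as np
import pytest

from eegsel.dataio import ChannelMontage
from eegsel.selection import (Fitness, ParetoEntry, ParetoFront,
                              brute_force_pareto, coincidence_tally,
                              crowding_distance, dominates,
                              evaluate_chromosome, evolve, non_dominated_sort,
                              per_size_best, repair)


def brute_fronts(points):
    """Oracle: peel non-dominated layers by exhaustive pairwise comparison."""
    remaining = list(range(len(points)))
    fronts = []
    while remaining:
        layer = [i for i in remaining
                 if not any(dominates(points[j], points[i])
                            for j in remaining if j != i)]
        fronts.append(sorted(layer))
        remaining = [i for i in remaining if i not in layer]
    return fronts


class TestDominance:
    def test_better_in_both_dominates(self):
        assert dominates(Fitness(0.90, 4), Fitness(0.80, 6))

    def test_equal_points_do_not_dominate(self):
        assert not dominates(Fitness(0.90, 4), Fitness(0.90, 4))

    def test_trade_off_is_incomparable(self):
        assert not dominates(Fitness(0.95, 8), Fitness(0.90, 4))
        assert not dominates(Fitness(0.90, 4), Fitness(0.95, 8))

    def test_equal_accuracy_fewer_channels_dominates(self):
        assert dominates(Fitness(0.90, 3), Fitness(0.90, 4))


class TestNonDominatedSort:
    def test_three_point_example(self):
        pts = [Fitness(0.9, 4), Fitness(0.8, 6), Fitness(0.7, 2)]
        fronts = non_dominated_sort(pts)
        assert sorted(fronts[0]) == [0, 2]
        assert fronts[1] == [1]

    def test_identical_points_form_single_front(self):
        pts = [Fitness(0.5, 3)] * 4
        assert non_dominated_sort(pts) == [[0, 1, 2, 3]]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_point_sets(self, seed):
        rng = np.random.default_rng(seed)
        pts = [Fitness(float(rng.integers(0, 11)) / 10, int(rng.integers(1, 9)))
               for _ in range(50)]
        fronts = [sorted(f) for f in non_dominated_sort(pts)]
        assert fronts == brute_fronts(pts)

    def test_fronts_partition_the_input(self):
        rng = np.random.default_rng(99)
        pts = [Fitness(float(rng.random()), int(rng.integers(1, 33)))
               for _ in range(40)]
        fronts = non_dominated_sort(pts)
        flat = sorted(itertools.chain.from_iterable(fronts))
        assert flat == list(range(40))


class TestCrowdingDistance:
    def test_two_point_front_both_infinite(self):
        d = crowding_distance([Fitness(0.5, 2), Fitness(0.9, 6)])
        assert np.all(np.isinf(d))

    def test_three_evenly_spaced_middle_distance_is_two(self):
        front = [Fitness(0.2, 2), Fitness(0.5, 4), Fitness(0.8, 6)]
        d = crowding_distance(front)
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_duplicated_interior_point_gets_zero(self):
        front = [Fitness(0.2, 2), Fitness(0.5, 4), Fitness(0.5, 4),
                 Fitness(0.5, 4), Fitness(0.8, 6)]
        d = crowding_distance(front)
        assert min(d[1:4]) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula_on_random_fronts(self, seed):
        rng = np.random.default_rng(seed)
        front = [Fitness(float(rng.random()), int(rng.integers(1, 20)))
                 for _ in range(12)]
        d = crowding_distance(front)
        # direct evaluation of the standard formula
        expected = np.zeros(12)
        for key in (lambda f: f.acc, lambda f: f.n_channels):
            vals = np.array([key(f) for f in front], float)
            order = np.argsort(vals, kind="stable")
            expected[order[0]] = expected[order[-1]] = np.inf
            rng_span = vals[order[-1]] - vals[order[0]]
            if rng_span > 0:
                for r in range(1, 11):
                    if not np.isinf(expected[order[r]]):
                        expected[order[r]] += (vals[order[r + 1]] - vals[order[r - 1]]) / rng_span
        finite = ~np.isinf(expected)
        np.testing.assert_allclose(d[finite], expected[finite])
        assert np.array_equal(np.isinf(d), np.isinf(expected))


class TestChromosomes:
    def test_fitness_counts_selected_channels(self):
        mask = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=np.int8)
        fit = evaluate_chromosome(mask, lambda m: 0.5)
        assert fit.n_channels == 4

    def test_cache_prevents_reevaluation(self):
        calls = []

        def ev(mask):
            calls.append(mask.copy())
            return 0.7

        cache = {}
        mask = np.array([1, 0, 1], dtype=np.int8)
        f1 = evaluate_chromosome(mask, ev, cache)
        f2 = evaluate_chromosome(mask.copy(), ev, cache)
        assert len(calls) == 1
        assert f1 == f2

    def test_all_zero_mask_rejected_without_repair(self):
        with pytest.raises(ValueError):
            evaluate_chromosome(np.zeros(5, dtype=np.int8), lambda m: 0.5)

    def test_repair_flips_exactly_one_gene(self):
        rng = np.random.default_rng(0)
        out = repair(np.zeros(32, dtype=np.int8), rng)
        assert out.sum() == 1

    def test_repair_leaves_valid_masks_alone(self):
        rng = np.random.default_rng(0)
        mask = np.array([0, 1, 0], dtype=np.int8)
        np.testing.assert_array_equal(repair(mask, rng), mask)


def overlap_fitness(planted, n):
    """Deterministic toy fitness: fraction of planted channels covered."""
    planted = set(planted)

    def ev(mask):
        return sum(int(mask[i]) for i in planted) / len(planted)

    return ev


class TestBruteForce:
    def test_single_channel_front(self):
        front = brute_force_pareto(lambda m: 0.5, 1)
        assert len(front) == 1
        assert front.entries[0].n_channels == 1

    def test_monotone_fitness_gives_one_entry_per_size(self):
        n = 5
        front = brute_force_pareto(lambda m: m.sum() / n, n)
        assert [e.n_channels for e in front.entries] == list(range(1, n + 1))
        assert [e.acc for e in front.entries] == pytest.approx(
            [k / n for k in range(1, n + 1)])

    def test_large_n_refused(self):
        with pytest.raises(ValueError):
            brute_force_pareto(lambda m: 0.5, 20)


class TestEvolve:
    @pytest.mark.parametrize("seed", range(20))
    def test_front_matches_exhaustive_enumeration(self, seed):
        # toy problem: 6 channels, 3 planted, deterministic overlap fitness
        ev = overlap_fitness([1, 3, 4], 6)
        expected = brute_force_pareto(ev, 6)
        front, _ = evolve(ev, 6, pop_size=10, max_gen=50, seed=seed)
        got = [(e.n_channels, e.acc) for e in front.entries]
        want = [(e.n_channels, e.acc) for e in expected.entries]
        assert got == want

    def test_same_seed_gives_identical_front(self):
        ev = overlap_fitness([0, 2], 8)
        f1, _ = evolve(ev, 8, pop_size=10, max_gen=30, seed=5)
        f2, _ = evolve(ev, 8, pop_size=10, max_gen=30, seed=5)
        assert [(e.mask, e.acc, e.n_channels) for e in f1.entries] == \
               [(e.mask, e.acc, e.n_channels) for e in f2.entries]

    def test_zero_generations_rejected(self):
        with pytest.raises(ValueError):
            evolve(lambda m: 0.5, 6, max_gen=0)

    def test_tolerance_termination_fires_on_static_problem(self):
        front, hist = evolve(lambda m: 0.5, 6, pop_size=10, max_gen=100, seed=0)
        assert hist.termination == "tolerance"
        assert hist.stopped_at < 100

    def test_archive_front_is_mutually_non_dominated(self):
        ev = overlap_fitness([2, 5], 7)
        front, _ = evolve(ev, 7, pop_size=10, max_gen=20, seed=3)
        for a, b in itertools.permutations(front.entries, 2):
            assert not dominates(a.fitness, b.fitness)

    def test_accuracy_non_decreasing_in_channel_count_within_front(self):
        ev = overlap_fitness([0, 1, 2, 3], 8)
        front, _ = evolve(ev, 8, pop_size=10, max_gen=30, seed=1)
        accs = [e.acc for e in front.entries]  # entries sorted by n_channels
        assert all(a <= b + 1e-12 for a, b in zip(accs, accs[1:]))


class TestReporting:
    def test_per_size_best_picks_max_and_leaves_gaps(self):
        front = ParetoFront([ParetoEntry((1, 1, 0, 0, 0), 0.8, 2),
                             ParetoEntry((1, 1, 1, 1, 1), 0.9, 5)])
        table = per_size_best(front, sizes=range(1, 7))
        assert table[2] == 0.8
        assert table[5] == 0.9
        assert table[1] is None and table[3] is None

    def test_tally_counts_subject_usage(self):
        montage = ChannelMontage(("Fp1", "AF3", "PO3"))
        f1 = ParetoFront([ParetoEntry((1, 0, 0), 0.9, 1)])
        f2 = ParetoFront([ParetoEntry((0, 0, 1), 0.8, 1)])
        tally = coincidence_tally({("s01", "arousal"): f1,
                                   ("s02", "arousal"): f2}, montage)
        assert tally.loc[1, "Fp1"] == 1
        assert tally.loc[1, "PO3"] == 1
        assert tally.loc[1, "AF3"] == 0

    def test_pooling_dimensions_doubles_max_count(self):
        montage = ChannelMontage(("Fp1", "AF3"))
        front = ParetoFront([ParetoEntry((1, 0), 0.9, 1)])
        tally = coincidence_tally({("s01", "arousal"): front,
                                   ("s01", "valence"): front}, montage)
        assert tally.loc[1, "Fp1"] == 2

    def test_absent_channel_counts_zero(self):
        montage = ChannelMontage(("Fp1", "AF3"))
        front = ParetoFront([ParetoEntry((1, 0), 0.9, 1)])
        tally = coincidence_tally({("s01", "arousal"): front}, montage)
        assert tally["AF3"].sum() == 0

    def test_dominated_entry_rejected_at_construction(self):
        with pytest.raises(ValueError):
            ParetoFront([ParetoEntry((1, 0), 0.9, 1),
                         ParetoEntry((1, 1), 0.8, 2)])
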