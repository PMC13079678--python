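"""Wrapper feature selection: RPPUS rule, operators, full runs."""

from itertools import permutations

import numpy as np
import pytest

from interleaf import egpo, simkit


def make_population(fitnesses, F=4, seed=0):
    """Population with prescribed fitness values, n_parties x b_members."""
    rng = np.random.default_rng(seed)
    parties = []
    k = 0
    for p in range(len(fitnesses)):
        party = []
        for m in range(len(fitnesses[p])):
            pos = rng.uniform(size=F)
            party.append(egpo.PolicyVector(
                position=pos, prev_position=pos.copy(),
                mask=egpo.mask_from_position(pos), fitness=fitnesses[p][m],
                party_id=p, member_id=m))
            k += 1
        parties.append(party)
    return egpo.Population(parties=parties)


class TestRPPUS:
    def test_hand_example_case1(self):
        out = egpo.rppus_update(np.r_[0.5], np.r_[0.6], np.r_[0.8], R=0.5)
        assert out[0] == pytest.approx(0.8)

    def test_hand_example_case2(self):
        out = egpo.rppus_update(np.r_[0.5], np.r_[0.6], np.r_[0.55], R=0.5)
        assert out[0] == pytest.approx(0.55)

    def test_all_coincide_returns_attractor(self):
        for R in (0.01, 0.3, 0.97):
            out = egpo.rppus_update(np.r_[0.7], np.r_[0.7], np.r_[0.7], R=R)
            assert out[0] == pytest.approx(0.7)

    def test_case3_hand_example(self):
        # a* outermost below: a*=0.1 <= x(s-1)=0.4 <= x(s)=0.6
        out = egpo.rppus_update(np.r_[0.4], np.r_[0.6], np.r_[0.1], R=0.75)
        assert out[0] == pytest.approx(0.1 + 0.5 * 0.3)

    def test_exactly_one_case_fires_for_every_ordering(self):
        """Exhaustive: all orderings of three distinct values plus every
        tie pattern satisfy exactly one case, with ties resolving to the
        earliest case."""
        values = [0.2, 0.5, 0.8]
        triples = set(permutations(values)) | {
            (a, a, b) for a in values for b in values} | {
            (a, b, a) for a in values for b in values} | {
            (b, a, a) for a in values for b in values}
        for (xp, xc, a) in triples:
            c1 = (xp <= xc <= a) or (xp >= xc >= a)
            c2 = (xp <= a <= xc) or (xp >= a >= xc)
            c3 = (a <= xp <= xc) or (a >= xp >= xc)
            assert c1 or c2 or c3            # totality
            out = egpo.rppus_update(np.r_[xp], np.r_[xc], np.r_[a], R=0.5)
            if c1:
                expected = a                    # (2R-1) = 0 at R = 0.5
            elif c2:
                expected = xp + 0.5 * (xc - xp)
            else:
                expected = a
            assert out[0] == pytest.approx(expected)

    def test_positions_stay_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            xp, xc, a = rng.uniform(size=3)
            out = egpo.rppus_update(np.r_[xp], np.r_[xc], np.r_[a],
                                    R=rng.uniform())
            assert 0.0 <= out[0] <= 1.0


class TestSchedule:
    @pytest.mark.parametrize("s,S,lmax,expected", [
        (0, 100, 0.5, 0.5), (100, 100, 0.5, 0.0), (50, 100, 0.5, 0.25)])
    def test_linear_decay(self, s, S, lmax, expected):
        assert egpo.switching_rate(s, S, lmax) == pytest.approx(expected)


class TestPartySwitch:
    def test_zero_rate_is_identity(self):
        pop = make_population([[0.1, 0.2], [0.3, 0.4]])
        before = [(m.party_id, m.member_id) for m in pop.members()]
        egpo.party_switch(pop, 0.0, np.random.default_rng(0))
        assert [(m.party_id, m.member_id) for m in pop.members()] == before

    def test_switch_count_matches_binomial(self):
        """Mean switches over trials within 3 sd of lambda * n * b."""
        lam, n_members, trials = 0.3, 20, 2000
        rng = np.random.default_rng(2)
        total = 0
        for _ in range(trials):
            pop = make_population([[0.1] * 5, [0.2] * 5, [0.3] * 5, [0.4] * 5])
            total += egpo.party_switch(pop, lam, rng)
        mean = total / trials
        sd = np.sqrt(n_members * lam * (1 - lam) / trials)
        assert abs(mean - lam * n_members) < 3 * sd

    def test_rate_one_touches_every_member_once(self):
        pop = make_population([[0.1, 0.2], [0.3, 0.4]])
        n = egpo.party_switch(pop, 1.0, np.random.default_rng(3))
        assert n == 4


class TestFitness:
    @pytest.fixture(scope="class")
    def bench(self):
        return simkit.simulate_feature_benchmark(300, 4, 4, 0, 16, 5.0, seed=9)

    def test_alpha_one_ignores_size(self, bench):
        cfg = egpo.EGPOConfig(alpha=1.0, seed=9)
        small = np.zeros(20, bool)
        small[bench.informative_idx] = True
        large = np.ones(20, bool)
        f_small = egpo.evaluate_fitness(small, bench.X, bench.y, cfg)
        err_small = 1 - egpo.nearest_centroid_cv(bench.X[:, small], bench.y,
                                                 seed=9)
        assert f_small == pytest.approx(err_small)

    def test_size_penalty_dominates_on_perfect_data(self, bench):
        cfg = egpo.EGPOConfig(alpha=0.9, seed=9)
        mask = np.zeros(20, bool)
        mask[bench.informative_idx] = True
        fit = egpo.evaluate_fitness(mask, bench.X, bench.y, cfg)
        balacc = egpo.nearest_centroid_cv(bench.X[:, mask], bench.y, seed=9)
        assert fit == pytest.approx(0.9 * (1 - balacc) + 0.1 * 4 / 20)

    def test_chance_level_on_shuffled_labels(self, bench):
        rng = np.random.default_rng(4)
        y = rng.permutation(bench.y)
        accs = [egpo.nearest_centroid_cv(bench.X, rng.permutation(y), seed=s)
                for s in range(5)]
        assert abs(np.mean(accs) - 0.25) < 0.1

    def test_empty_mask_rejected(self, bench):
        with pytest.raises(ValueError):
            egpo.evaluate_fitness(np.zeros(20, bool), bench.X, bench.y,
                                  egpo.EGPOConfig())

    def test_single_class_rejected(self, bench):
        with pytest.raises(ValueError):
            egpo.nearest_centroid_cv(bench.X, np.zeros_like(bench.y))


class TestGreedyRefine:
    def test_zero_budget_is_identity(self):
        bench = simkit.simulate_feature_benchmark(120, 3, 3, 0, 7, 4.0, seed=5)
        cfg = egpo.EGPOConfig(seed=5)
        mask = np.ones(10, bool)
        pv = egpo.PolicyVector(position=np.full(10, 0.9),
                               prev_position=np.full(10, 0.9), mask=mask,
                               fitness=egpo.evaluate_fitness(mask, bench.X,
                                                             bench.y, cfg),
                               party_id=0, member_id=0)
        out = egpo.greedy_refine(pv, bench.X, bench.y, cfg, budget=0)
        assert np.array_equal(out.mask, mask)
        assert out.fitness == pv.fitness

    def test_refinement_never_worsens_and_drops_noise(self):
        """Exhaustive flip-scan oracle: when dropping some noise feature
        strictly improves fitness, greedy refinement must improve too."""
        bench = simkit.simulate_feature_benchmark(150, 3, 3, 0, 7, 5.0, seed=6)
        cfg = egpo.EGPOConfig(seed=6)
        mask = np.ones(10, bool)
        base = egpo.evaluate_fitness(mask, bench.X, bench.y, cfg)
        flips = []
        for j in range(10):
            cand = mask.copy()
            cand[j] = False
            flips.append(egpo.evaluate_fitness(cand, bench.X, bench.y, cfg))
        pv = egpo.PolicyVector(position=np.full(10, 0.9),
                               prev_position=np.full(10, 0.9),
                               mask=mask, fitness=base, party_id=0, member_id=0)
        out = egpo.greedy_refine(pv, bench.X, bench.y, cfg)
        assert out.fitness <= base
        if min(flips) < base:       # an improving single flip exists
            assert out.fitness <= min(flips) + 1e-12 or out.fitness < base


class TestCoalitionAndElite:
    def test_no_stagnation_is_identity(self):
        pop = make_population([[0.1, 0.2], [0.3, 0.4]])
        before = [m.position.copy() for m in pop.members()]
        changed = egpo.coalition_restructure(pop, stagnation=3, window=10,
                                             rng=np.random.default_rng(0))
        assert not changed
        for b, m in zip(before, pop.members()):
            assert np.array_equal(b, m.position)

    def test_restructure_clusters_on_best_leader(self):
        pop = make_population([[0.1, 0.1], [0.9, 0.9]], F=50)
        best_leader_pos = pop.leader(0).position.copy()
        changed = egpo.coalition_restructure(pop, stagnation=10, window=10,
                                             rng=np.random.default_rng(1))
        assert changed
        for m in pop.parties[1]:
            # Normal(0, 0.1) displacement: 0.4 is a 4-sigma envelope
            close = np.abs(m.position - best_leader_pos) < 0.4
            assert close.mean() > 0.9

    def test_elite_preserve_inserts_archive(self):
        pop = make_population([[0.5, 0.6], [0.7, 0.8]])
        elite = egpo.PolicyVector(position=np.full(4, 0.9),
                                  prev_position=np.full(4, 0.9),
                                  mask=np.ones(4, bool), fitness=0.05,
                                  party_id=0, member_id=0)
        pop.elite = elite
        egpo.elite_preserve(pop)
        assert min(m.fitness for m in pop.members()) <= elite.fitness


class TestRunEGPO:
    def test_history_is_monotone_and_deterministic(self):
        bench = simkit.simulate_feature_benchmark(200, 4, 3, 0, 12, 4.0, seed=8)
        cfg = egpo.EGPOConfig(seed=8, iterations=15)
        a = egpo.run_egpo(bench.X, bench.y, cfg)
        b = egpo.run_egpo(bench.X, bench.y, cfg)
        assert np.all(np.diff(a.history) <= 1e-12)
        assert a.history == b.history
        assert np.array_equal(a.best_mask, b.best_mask)

    def test_single_iteration_runs(self):
        bench = simkit.simulate_feature_benchmark(100, 2, 2, 0, 6, 4.0, seed=9)
        res = egpo.run_egpo(bench.X, bench.y,
                            egpo.EGPOConfig(seed=9, iterations=1))
        assert len(res.history) == 2          # init + one iteration
        assert res.best_mask.any()

    def test_dimensionality_pressure_on_pure_noise(self):
        """With alpha < 1 and no signal anywhere, selected masks are
        much smaller than the random-mask expectation F/2."""
        rng = np.random.default_rng(10)
        sizes = []
        for seed in range(3):
            X = rng.standard_normal((120, 30))
            y = np.repeat([0, 1, 2], 40)
            res = egpo.run_egpo(X, y, egpo.EGPOConfig(seed=seed, iterations=20))
            sizes.append(res.best_mask.sum())
        assert np.mean(sizes) < 15

    def test_too_few_features_raise(self):
        with pytest.raises(ValueError):
            egpo.run_egpo(np.zeros((20, 1)), np.repeat([0, 1], 10),
                          egpo.EGPOConfig(seed=0))

    def test_selected_groups_reported(self):
        bench = simkit.simulate_feature_benchmark(100, 2, 2, 0, 6, 5.0, seed=11)
        gmap = {"left": (0, 4), "right": (4, 8)}
        res = egpo.run_egpo(bench.X, bench.y,
                            egpo.EGPOConfig(seed=11, iterations=10),
                            group_map=gmap)
        idx = res.selected_indices
        expected = [n for n, (lo, hi) in gmap.items()
                    if np.any((idx >= lo) & (idx < hi))]
        assert res.selected_groups == expected
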