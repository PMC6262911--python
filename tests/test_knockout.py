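import numpy as np
import pytest

from coext.knockout import (
    ExtinctionState,
    ModelConfig,
    effective_threshold,
    node_average_effective_threshold,
    remove_plant,
    robustness,
    run_da,
    run_model,
    run_ordered,
    run_rw,
    run_so,
    shared_pollinator_matrix,
)
from coext.network_io import BipartiteNetwork
from coext.synthetic import GeneratorSpec, generate, perfect_matching, star

import oracles
from conftest import random_network


def net_from(M, weighted=False):
    M = np.asarray(M, dtype=float)
    A, P = M.shape
    return BipartiteNetwork(
        [f"a{i}" for i in range(A)], [f"p{j}" for j in range(P)], M, weighted=weighted
    )


class TestModelConfig:
    def test_threshold_zero_rejected(self):
        with pytest.raises(ValueError, match="0 < T <= 1"):
            ModelConfig(model="SO", T=0.0)

    def test_threshold_above_one_rejected(self):
        with pytest.raises(ValueError, match="0 < T <= 1"):
            ModelConfig(model="SO", T=1.1)

    def test_threshold_one_allowed(self):
        assert ModelConfig(model="SO", T=1.0).T == 1.0

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="model"):
            ModelConfig(model="XX")


class TestRobustness:
    def test_perfect_matching_closed_form(self):
        assert robustness([4, 3, 2, 1, 0], 4, 4) == pytest.approx(10 / 16)

    def test_total_collapse(self):
        assert robustness([5, 0, 0, 0], 5, 3) == pytest.approx(1 / 3)

    def test_maximal_survival_upper_bound(self):
        assert robustness([5, 5, 5, 0], 5, 3) == pytest.approx(1.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="P\\+1"):
            robustness([4, 2, 0], 4, 3)

    def test_increasing_curve_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            robustness([4, 2, 3, 0], 4, 3)

    def test_wrong_endpoints_rejected(self):
        with pytest.raises(ValueError, match="start at A"):
            robustness([3, 2, 1, 1], 4, 3)


class TestEffectiveThreshold:
    def test_worked_example_k5(self):
        # a degree-5 node at T=0.5 dies on its 3rd lost edge: 3/5 = 0.6
        assert effective_threshold(5, 0.5) == 0.6

    def test_degree_one_always_one(self):
        for T in (0.1, 0.5, 1.0):
            assert effective_threshold(1, T) == 1.0

    def test_exactly_realizable(self):
        assert effective_threshold(4, 0.5) == 0.5

    def test_float_representation_of_exact_products(self):
        # 0.3 * 10 is 3.0000000000000004 in floats; must still give 3/10
        assert effective_threshold(10, 0.3) == pytest.approx(0.3)
        assert effective_threshold(3, 0.1) == pytest.approx(1 / 3)

    def test_at_least_T(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = int(rng.integers(1, 60))
            T = float(rng.uniform(0.01, 1.0))
            te = effective_threshold(k, T)
            assert te >= T - 1e-12
            assert te <= 1.0

    def test_zero_degree_rejected(self):
        with pytest.raises(ValueError):
            effective_threshold(0, 0.5)


class TestNodeAverageEffectiveThreshold:
    def test_perfect_matching_all_degree_one(self, perfect_matching4):
        assert node_average_effective_threshold(perfect_matching4, 0.5) == 1.0

    def test_all_degree_four(self):
        net = net_from(np.ones((4, 4)))
        assert node_average_effective_threshold(net, 0.5) == 0.5

    def test_mixed_plant_degrees_one_and_five(self):
        # plants with degree 5 and 1 at T=0.5: (0.6 + 1.0) / 2 = 0.8
        M = np.ones((5, 2))
        M[1:, 1] = 0
        net = net_from(M)
        assert node_average_effective_threshold(net, 0.5, guild="plants") == pytest.approx(0.8)

    def test_guild_restriction(self, star5):
        assert node_average_effective_threshold(star5, 0.5, guild="animals") == 1.0
        assert node_average_effective_threshold(star5, 0.5, guild="plants") == pytest.approx(
            effective_threshold(5, 0.5)
        )


class TestRemovePlant:
    def cfg(self, weighted=False, T=0.5):
        return ModelConfig(model="SO", weighted=weighted, T=T)

    def test_private_pollinator_dies_with_its_plant(self):
        # star plant feeding a degree-1 pollinator: loss fraction 1 >= any T
        net = net_from([[1, 0], [1, 1]])
        state = ExtinctionState(net, weighted=False)
        _, dead = remove_plant(state, 0, self.cfg(T=1.0))
        assert list(dead) == [0]

    def test_degree5_pollinator_survives_two_losses_dies_on_third(self):
        net = net_from(np.ones((2, 5)))  # both pollinators have degree 5
        state = ExtinctionState(net, weighted=False)
        cfg = self.cfg(T=0.5)
        _, d1 = remove_plant(state, 0, cfg)
        _, d2 = remove_plant(state, 1, cfg)
        assert len(d1) == len(d2) == 0  # 2/5 < 0.5
        _, d3 = remove_plant(state, 2, cfg)
        assert set(d3.tolist()) == {0, 1}  # 3/5 >= 0.5

    def test_weighted_loss_uses_total_weight(self):
        # weights (9, 1): losing the weight-1 plant is a 0.1 loss (survives);
        # losing the weight-9 plant is a 0.9 loss (dies)
        net = net_from([[9, 1], [1, 9]], weighted=True)
        state = ExtinctionState(net, weighted=True)
        _, dead = remove_plant(state, 1, self.cfg(weighted=True))
        assert list(dead) == [1]  # animal 1 lost 9/10
        assert state.alive_animals[0]  # animal 0 lost 1/10

    def test_removing_dead_plant_rejected(self, perfect_matching4):
        state = ExtinctionState(perfect_matching4, weighted=False)
        remove_plant(state, 0, self.cfg())
        with pytest.raises(ValueError, match="already extinct"):
            remove_plant(state, 0, self.cfg())

    def test_zero_degree_network_rejected(self):
        net = BipartiteNetwork(
            ["a1", "a2"], ["p1"], np.array([[1.0], [0.0]]), allow_zero_degree=True
        )
        with pytest.raises(ValueError, match="interaction"):
            ExtinctionState(net, weighted=False)


def run_invariants(net, run):
    P, A = net.n_plants, net.n_animals
    assert run.a_curve[0] == A and run.a_curve[-1] == 0
    assert np.all(np.diff(run.a_curve) <= 0)
    assert len(run.a_curve) == P + 1
    assert sorted(run.plant_sequence) == list(range(P))
    assert sorted(run.ranks.tolist()) == list(range(1, P + 1))
    # R = 1 is attainable in degenerate cases (e.g. A=1, P=2, T=1: the single
    # pollinator legally survives until the final plant removal)
    assert 1 / P - 1e-12 <= run.R <= 1


class TestRunSO:
    def test_single_plant_degenerate(self, star5):
        run = run_so(star5, ModelConfig("SO", T=0.5, seed=0))
        assert run.R == 1.0  # forced by the formula: a(0)=A is the only term

    def test_perfect_matching_order_independent(self, perfect_matching4):
        for seed in range(10):
            run = run_so(perfect_matching4, ModelConfig("SO", T=0.5, seed=seed))
            assert run.R == pytest.approx(0.625)

    def test_sequence_is_uniform_permutation(self):
        # each plant's rank uniform over {1..P}: chi-square per plant
        from scipy.stats import chisquare

        net = generate(GeneratorSpec(n_plants=4, n_animals=6, n_edges=12, seed=1))
        n = 4000
        counts = np.zeros((4, 4))
        rng = np.random.default_rng(11)
        for _ in range(n):
            run = run_so(net, ModelConfig("SO", T=0.5), rng)
            for rank0, plant in enumerate(run.plant_sequence):
                counts[plant, rank0] += 1
        for plant in range(4):
            assert chisquare(counts[plant]).pvalue > 0.001

    def test_all_steps_are_triggers(self, small_random):
        run = run_so(small_random, ModelConfig("SO", T=0.5, seed=2))
        assert all(run.trigger_flags)

    def test_matches_independent_oracle_replay(self, small_random):
        cfg = ModelConfig("SO", T=0.5, seed=5)
        run = run_so(small_random, cfg)
        a = oracles.sequence_survivors(
            small_random.M.tolist(), run.plant_sequence, 0.5, weighted=False
        )
        assert list(run.a_curve) == a

    def test_invariants_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            net = random_network(rng, weighted=True)
            for weighted in (False, True):
                cfg = ModelConfig("SO", weighted=weighted, T=0.5)
                run_invariants(net, run_so(net, cfg, np.random.default_rng(1)))


class TestRunDA:
    def test_hand_traced_avalanche(self):
        # a1 visits p1 only; a2 visits both; a3 visits p2 only. T=0.5.
        # Any trigger kills its private pollinator and the shared one, so the
        # other plant has lost 1 of its 2 pollinator-weighted interactions
        # (>= 0.5) and falls in the avalanche: exactly one trigger per run.
        net = net_from([[1, 0], [1, 1], [0, 1]])
        for seed in range(5):
            run = run_da(net, ModelConfig("DA", T=0.5, seed=seed))
            assert run.n_triggers == 1
            assert run.trigger_flags == (True, False)
            assert list(run.a_curve) == [3, 1, 0]

    def test_equals_so_at_T1_run_for_run(self, ac_like):
        for seed in (0, 1, 2):
            so = run_so(ac_like, ModelConfig("SO", T=1.0, seed=seed))
            da = run_da(ac_like, ModelConfig("DA", T=1.0, seed=seed))
            assert so.plant_sequence == da.plant_sequence
            assert np.array_equal(so.a_curve, da.a_curve)
            assert all(da.trigger_flags)

    def test_curve_length_regardless_of_avalanches(self):
        rng = np.random.default_rng(8)
        for _ in range(15):
            net = random_network(rng, weighted=True)
            for weighted in (False, True):
                cfg = ModelConfig("DA", weighted=weighted, T=0.3)
                run_invariants(net, run_da(net, cfg, np.random.default_rng(2)))


class TestRunRW:
    def test_walk_probabilities_match_shared_counts(self):
        # plant 0 shares 2 pollinators with plant 1 and 1 with plant 2:
        # conditional on plant 0 triggering first, the next victim is
        # plant 1 with probability 2/3 and plant 2 with probability 1/3
        net = net_from([[1, 1, 0], [1, 1, 0], [1, 0, 1]])
        cfg = ModelConfig("RW", T=0.5)
        rng = np.random.default_rng(9)
        second = {1: 0, 2: 0}
        total = 0
        for _ in range(12000):
            run = run_rw(net, cfg, rng)
            if run.plant_sequence[0] == 0:
                second[run.plant_sequence[1]] += 1
                total += 1
        assert total > 3000
        assert second[1] / total == pytest.approx(2 / 3, abs=0.03)
        assert second[2] / total == pytest.approx(1 / 3, abs=0.03)

    def test_disconnected_components_never_crossed_by_walk(self, two_component):
        cfg = ModelConfig("RW", T=0.5)
        rng = np.random.default_rng(10)
        comp = {0: 0, 1: 0, 2: 1, 3: 1}
        for _ in range(50):
            run = run_rw(two_component, cfg, rng)
            for step in range(1, 4):
                if not run.trigger_flags[step]:  # walk step stayed in component
                    assert comp[run.plant_sequence[step]] == comp[run.plant_sequence[step - 1]]

    def test_perfect_matching_degenerates_to_all_restarts(self, perfect_matching4):
        run = run_rw(perfect_matching4, ModelConfig("RW", T=0.5, seed=3))
        assert all(run.trigger_flags)
        assert run.R == pytest.approx(0.625)

    def test_plants_never_die_by_threshold(self):
        # stranded plant (all pollinators dead) persists until visited:
        # every plant appears exactly once in the sequence by contract
        rng = np.random.default_rng(11)
        for _ in range(10):
            net = random_network(rng, weighted=True)
            for weighted in (False, True):
                cfg = ModelConfig("RW", weighted=weighted, T=0.2)
                run_invariants(net, run_rw(net, cfg, np.random.default_rng(4)))


class TestRunOrdered:
    def test_increasing_beats_decreasing_on_skewed(self):
        net = generate(
            GeneratorSpec(
                n_plants=8, n_animals=20, n_edges=45, skew="skewed",
                hub_fraction=0.7, seed=12,
            )
        )
        cfg = ModelConfig("SO", T=0.5)
        r_inc = run_ordered(net, "increasing_degree", cfg).R
        r_dec = run_ordered(net, "decreasing_degree", cfg).R
        assert r_inc > r_dec

    def test_ordered_matches_independent_oracle(self, small_random):
        cfg = ModelConfig("SO", T=0.5)
        for order in ("increasing_degree", "decreasing_degree"):
            run = run_ordered(small_random, order, cfg)
            assert run.R == pytest.approx(
                oracles.sequence_robustness(
                    small_random.M.tolist(), run.plant_sequence, 0.5, False
                )
            )

    def test_perfect_matching_both_orders_equal(self, perfect_matching4):
        cfg = ModelConfig("SO", T=0.5)
        assert (
            run_ordered(perfect_matching4, "increasing_degree", cfg).R
            == run_ordered(perfect_matching4, "decreasing_degree", cfg).R
            == pytest.approx(0.625)
        )

    def test_replay_of_recorded_run(self, small_random):
        cfg = ModelConfig("SO", T=0.5, seed=13)
        recorded = run_so(small_random, cfg)
        replay = run_ordered(small_random, list(recorded.plant_sequence), cfg)
        assert replay.R == recorded.R
        assert np.array_equal(replay.a_curve, recorded.a_curve)

    def test_non_permutation_rejected(self, perfect_matching4):
        with pytest.raises(ValueError, match="permutation"):
            run_ordered(perfect_matching4, [0, 0, 1, 2], ModelConfig("SO", T=0.5))


class TestSharedPollinatorMatrix:
    def test_identity_pattern_all_zero(self, perfect_matching4):
        state = ExtinctionState(perfect_matching4, weighted=False)
        assert shared_pollinator_matrix(state).sum() == 0

    def test_single_generalist_pollinator(self):
        net = net_from(np.ones((1, 4)))
        state = ExtinctionState(net, weighted=False)
        F = shared_pollinator_matrix(state)
        assert np.all(F[~np.eye(4, dtype=bool)] == 1)
        assert np.all(np.diag(F) == 0)

    def test_two_component_block_diagonal(self, two_component):
        state = ExtinctionState(two_component, weighted=False)
        F = shared_pollinator_matrix(state)
        assert F[0, 2] == F[0, 3] == F[1, 2] == 0
        assert F[0, 1] == 2 and F[2, 3] == 2

    def test_matches_brute_force(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            net = random_network(rng, weighted=True)
            state = ExtinctionState(net, weighted=True)
            F = shared_pollinator_matrix(state)
            assert np.array_equal(F, oracles.brute_shared_matrix(state.C))
            assert np.array_equal(F, F.T)


class TestEquivalencesAndDeterminism:
    def test_bso_equals_wso_at_T1(self, ac_like):
        for seed in (0, 1, 2):
            b = run_so(ac_like, ModelConfig("SO", weighted=False, T=1.0, seed=seed))
            w = run_so(ac_like, ModelConfig("SO", weighted=True, T=1.0, seed=seed))
            assert b.plant_sequence == w.plant_sequence
            assert np.array_equal(b.a_curve, w.a_curve)
            assert b.R == w.R

    @pytest.mark.parametrize("model", ["SO", "DA", "RW"])
    def test_seed_determinism(self, ac_like, model):
        cfg = ModelConfig(model, weighted=True, T=0.5, seed=99)
        r1 = run_model(ac_like, cfg)
        r2 = run_model(ac_like, cfg)
        assert r1.plant_sequence == r2.plant_sequence
        assert np.array_equal(r1.a_curve, r2.a_curve)
        assert r1.trigger_flags == r2.trigger_flags
        assert r1.R == r2.R
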