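"""Lattice agent-based model: growth rules, mutation dynamics, invariants."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from gradres.abm import (
    LatticeBoundaryError,
    LatticeState,
    SimulationParams,
    run_colony_cohort,
    simulate_colony,
    simulate_preincubation,
    step_lattice,
)
from gradres.reference import reference_cohort


class TestDivisionProbability:
    def test_endpoints_exact(self):
        p = SimulationParams(p_init=0.12, p_max=0.87, n_steps=7)
        assert p.division_prob(0) == 0.12
        assert p.division_prob(7) == 0.87

    def test_strictly_increasing_when_p_max_above_p_init(self):
        p = SimulationParams(p_init=0.1, p_max=0.9, n_steps=30)
        probs = p.division_prob(np.arange(31))
        assert np.all(np.diff(probs) > 0)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(p_init=0.5, p_max=0.3),
            dict(p_init=-0.1, p_max=0.5),
            dict(p_init=0.1, p_max=0.5, n_steps=0),
            dict(p_init=0.1, p_max=0.5, mu=1.5),
            dict(p_init=0.1, p_max=0.5, death_prob=1.0),
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationParams(**kw)


class TestStepLattice:
    def test_single_cell_certain_division_doubles(self, rng):
        params = SimulationParams(p_init=1.0, p_max=1.0)
        state = LatticeState.single_founder(params, side=9)
        step_lattice(state, params, rng)
        assert state.n_alive == 2

    def test_zero_division_probability_freezes_state(self, rng):
        params = SimulationParams(p_init=0.0, p_max=0.0)
        state = LatticeState.single_founder(params, side=9)
        for _ in range(5):
            step_lattice(state, params, rng)
        assert state.n_alive == 1

    def test_fully_occupied_lattice_cannot_divide(self, rng):
        params = SimulationParams(p_init=1.0, p_max=1.0)
        state = LatticeState.fully_occupied(params, side=6)
        step_lattice(state, params, rng)
        assert state.n_alive == 36

    def test_death_only_dynamics(self, rng):
        params = SimulationParams(p_init=0.0, p_max=0.0, death_prob=0.5)
        state = LatticeState.fully_occupied(params, side=6)
        step_lattice(state, params, rng)
        assert state.n_alive < 36  # P(no deaths) = 0.5^36


class TestSimulateColony:
    def test_no_updates_keeps_single_founder(self):
        params = SimulationParams(p_init=0.7, p_max=0.7)
        res = simulate_colony(params, n_updates=0, seed=0)
        assert res.final_size == 1
        assert list(res.size_trajectory) == [1]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_unconstrained_certain_growth_doubles_each_round(self, seed):
        # at sizes <= 8 the push rule always finds space on a 15x15 lattice
        params = SimulationParams(p_init=1.0, p_max=1.0)
        res = simulate_colony(params, n_updates=3, seed=seed, lattice_size=15)
        assert res.final_size == 8
        assert list(res.size_trajectory) == [1, 2, 4, 8]

    def test_population_and_geometry_bounds(self):
        params = SimulationParams(p_init=1.0, p_max=1.0)
        t = 8
        res = simulate_colony(params, n_updates=t, seed=7)
        assert res.final_size <= 2**t
        assert np.all(np.diff(res.size_trajectory) >= 0)  # no death: monotone
        assert res.bbox_side <= 1 + 4 * t

    def test_boundary_contact_raises(self):
        params = SimulationParams(p_init=1.0, p_max=1.0)
        with pytest.raises(LatticeBoundaryError):
            simulate_colony(params, n_updates=10, seed=0, lattice_size=7)

    def test_step_indices_monotone_without_bidirectionality(self):
        params = SimulationParams(p_init=0.4, p_max=0.9, n_steps=5, mu=0.3)
        res = simulate_colony(params, n_updates=10, founder_step=2, seed=3)
        hist = res.step_index_histogram
        assert hist[:2].sum() == 0  # nobody below the founder's step
        assert hist.sum() == res.final_size

    def test_certain_mutation_advances_every_lineage_tip(self):
        # p = 1 and mu = 1: after r rounds every cell has divided r times,
        # so every lineage tip sits at step min(r, n_steps)
        params = SimulationParams(p_init=1.0, p_max=1.0, n_steps=3, mu=1.0)
        for r, expected in [(1, 1), (2, 2), (4, 3)]:
            res = simulate_colony(params, n_updates=r, seed=11)
            hist = res.step_index_histogram
            assert hist[expected] == res.final_size

    def test_reproducible_given_seed(self):
        params = SimulationParams(p_init=0.5, p_max=0.9, n_steps=10, mu=0.1)
        a = simulate_colony(params, n_updates=10, seed=42)
        b = simulate_colony(params, n_updates=10, seed=42)
        assert a.final_size == b.final_size
        assert np.array_equal(a.size_trajectory, b.size_trajectory)
        assert np.array_equal(a.step_index_histogram, b.step_index_histogram)

    def test_small_colony_mean_matches_branching_process(self, rng):
        # while space never binds, E[size after t rounds] = (1 + p)^t
        p, t, n = 0.5, 3, 3000
        sizes = np.array(
            [simulate_colony(SimulationParams(p_init=p, p_max=p), t, seed=s).final_size
             for s in range(n)]
        )
        expected = (1 + p) ** t
        se = sizes.std(ddof=1) / np.sqrt(n)
        assert abs(sizes.mean() - expected) < 3 * se


class TestOracleEquivalence:
    def test_final_size_distribution_matches_reference(self, rng):
        # light-weight version of the full cross-validation: one p, one depth
        p = 0.6
        params = SimulationParams(p_init=p, p_max=p)
        main = run_colony_cohort(params, 0, 400, clonogenic_days=5, rng=rng)
        ref = reference_cohort(p, 10, 400, rng=rng)
        assert ks_2samp(main, ref).pvalue > 0.005


class TestPreincubation:
    def test_zero_duration_all_cells_at_step_zero(self, rng):
        params = SimulationParams(p_init=0.2, p_max=0.8, n_steps=10, mu=0.1)
        dist = simulate_preincubation(params, 0, rng=rng)
        assert dist[0] == 1.0 and dist[1:].sum() == 0.0

    def test_no_mutation_means_no_steps(self, rng):
        params = SimulationParams(p_init=0.3, p_max=0.8, n_steps=10, mu=0.0)
        dist = simulate_preincubation(params, 14, rng=rng)
        assert dist[0] == 1.0

    def test_certain_mutation_saturates_at_cap(self, rng):
        params = SimulationParams(
            p_init=1.0, p_max=1.0, n_steps=3, mu=1.0, updates_per_day=1
        )
        dist = simulate_preincubation(params, 2, rng=rng)
        assert dist[2] == 1.0  # two divisions -> exactly two steps
        dist = simulate_preincubation(params, 5, rng=rng)
        assert dist[3] == 1.0  # capped at n_steps

    def test_distribution_normalised(self, rng):
        params = SimulationParams(p_init=0.2, p_max=0.9, n_steps=20, mu=0.05)
        dist = simulate_preincubation(params, 21, rng=rng)
        assert abs(dist.sum() - 1.0) < 1e-9


class TestColonyCohort:
    def test_empty_cohort(self, rng):
        params = SimulationParams(p_init=0.5, p_max=0.5)
        assert len(run_colony_cohort(params, 0, 0, rng=rng)) == 0

    def test_no_preincubation_no_mutation_equals_direct_growth(self, rng):
        params = SimulationParams(p_init=0.4, p_max=0.9, n_steps=5, mu=0.0)
        cohort = run_colony_cohort(params, 0, 500, clonogenic_days=7, rng=rng)
        direct = np.array(
            [
                simulate_colony(
                    SimulationParams(p_init=0.4, p_max=0.4), 14, seed=s
                ).final_size
                for s in range(500)
            ]
        )
        assert ks_2samp(cohort, direct).pvalue > 0.01

    def test_longer_preincubation_grows_larger_colonies(self, rng):
        params = SimulationParams(p_init=0.15, p_max=0.8, n_steps=10, mu=0.05)
        w0 = run_colony_cohort(params, 0, 500, rng=rng)
        w3 = run_colony_cohort(params, 3, 500, rng=rng)
        assert np.median(w3) > np.median(w0)

    def test_cohort_reproducible_given_seed(self):
        params = SimulationParams(p_init=0.2, p_max=0.8, n_steps=10, mu=0.05)
        a = run_colony_cohort(params, 1, 50, rng=np.random.default_rng(9))
        b = run_colony_cohort(params, 1, 50, rng=np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_per_colony_p_max_sampler_is_honoured(self, rng):
        # with frequent single-step mutation, colonies approach their own
        # p_max, so a high sampler must yield larger colonies than a low one
        params = SimulationParams(p_init=0.1, p_max=0.9, n_steps=1, mu=0.2)
        high = run_colony_cohort(params, 0, 300, p_max_sampler=0.9, rng=rng)
        low = run_colony_cohort(params, 0, 300, p_max_sampler=0.15, rng=rng)
        assert high.mean() > 2 * low.mean()
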