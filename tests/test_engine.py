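"""Tests for population initialisation and the stochastic event loop."""

import dataclasses
import math

import numpy as np
import pytest

from beliefsim import (
    AgentState,
    EdgeDraws,
    ModelParams,
    NewsLink,
    NoiseSpec,
    Population,
    apply_exposure,
    exposure_step,
    init_population,
    new_belief_substep,
    run_simulation,
    sample_edge_draws,
)
from conftest import make_population


def forced_draws(za1=0.01, za2=0.01, rho=1.0, open_gates=True):
    """EdgeDraws with both gates forced open (u=0) or closed (u=1)."""
    u = 0.0 if open_gates else 1.0
    return EdgeDraws(u_gate_first=u, rho_first=rho, za_first=za1,
                     u_gate_second=u, rho_second=rho, za_second=za2)


class TestInitPopulation:
    def test_moments_of_uniform_initialisation(self, rng):
        params = ModelParams(n_agents=1000, n_steps=1)
        pop = init_population(params, rng)
        # U(-1,1): mean 0, variance 1/3; allow a 3-sigma band
        tol = 3.0 * math.sqrt(1.0 / 3.0 / 1000)
        for arr in (pop.a1, pop.a2, pop.a3):
            assert abs(arr.mean()) < tol
            assert np.all(np.abs(arr) <= 1.0)
        assert not pop.adopted.any()

    def test_single_agent_bounds(self, rng):
        pop = init_population(ModelParams(n_agents=1, n_steps=1), rng)
        assert pop.size == 1
        state = pop.agent(0)
        assert all(abs(v) <= 1 for v in (state.a1, state.a2, state.a3))
        assert not state.adopted


class TestExposureStep:
    def test_stable_point_never_moves(self, rng):
        # (+1, -1) under k0 = -1: both gates have probability 0
        pop = make_population(AgentState(1.0, -1.0))
        params = ModelParams(n_agents=1, n_steps=1, link=NewsLink(k0=-1))
        for _ in range(200):
            exposure_step(pop, params, rng)
        assert pop.a1[0] == 1.0 and pop.a2[0] == -1.0

    def test_neutral_agent_moves_by_noise_only(self, rng):
        # at (0, 0) coherence is 0 and both gates always open: each attitude
        # becomes exactly +/- the noise magnitude
        pop = make_population(AgentState(0.0, 0.0))
        params = ModelParams(n_agents=1, n_steps=1)
        exposure_step(pop, params, rng)
        assert abs(pop.a1[0]) == pytest.approx(0.01)
        assert abs(pop.a2[0]) == pytest.approx(0.01)

    def test_hand_computed_step(self):
        # (0.4, 0.5), k0=+1: C = 0.2 shared by both attitudes, gates open,
        # noise +0.01 on both -> (0.61, 0.71)
        pop = make_population(AgentState(0.4, 0.5))
        params = ModelParams(n_agents=1, n_steps=1, link=NewsLink(k0=1))
        apply_exposure(pop, 0, params, forced_draws())
        assert pop.a1[0] == pytest.approx(0.61)
        assert pop.a2[0] == pytest.approx(0.71)
        assert pop.t == 1

    def test_closed_gates_leave_state_unchanged(self):
        pop = make_population(AgentState(0.4, 0.5))
        params = ModelParams(n_agents=1, n_steps=1)
        apply_exposure(pop, 0, params, forced_draws(open_gates=False))
        assert pop.a1[0] == 0.4 and pop.a2[0] == 0.5

    def test_updates_use_pre_update_coherence(self):
        # the second attitude must see C computed before the first moved
        pop = make_population(AgentState(0.5, 0.5))
        params = ModelParams(n_agents=1, n_steps=1, link=NewsLink(k0=1))
        apply_exposure(pop, 0, params, forced_draws(za1=0.01, za2=0.01))
        # C = 0.25 for both: 0.5+0.25+0.01, not 0.5 + 0.76*0.5
        assert pop.a2[0] == pytest.approx(0.76)

    def test_draw_order_consumes_four_uniforms_in_fixed_mode(self, rng):
        state = rng.bit_generator.state
        sample_edge_draws(rng, NoiseSpec())
        rng2 = np.random.default_rng()
        rng2.bit_generator.state = state
        rng2.random(4)
        assert rng.bit_generator.state == rng2.bit_generator.state


class TestNewBeliefSubstep:
    params = ModelParams(n_agents=1, n_steps=1, new_belief_enabled=True,
                         link=NewsLink(k0=-1, k_nb=-1))

    def test_no_adoption_attempt_under_reassurance(self, rng):
        state = AgentState(0.5, 0.5, a3=0.9)
        out = new_belief_substep(state, 0.5, self.params, rng)
        assert out == state

    def test_pure_dissonance_belief_never_adopted(self, rng):
        # a1=1, a3=1, k_nb=-1: adoption probability is max(0, -1) = 0
        for _ in range(500):
            out = new_belief_substep(AgentState(1.0, 0.0, a3=1.0), -1.0,
                                     self.params, rng)
            assert not out.adopted

    def test_adopter_at_extremes_is_frozen(self, rng):
        state = AgentState(1.0, 0.0, a3=-1.0, adopted=True)
        for _ in range(200):
            state = new_belief_substep(state, -1.0, self.params, rng)
        assert state.a1 == 1.0 and state.a3 == -1.0 and state.adopted

    def test_certain_adoption_then_edge_update(self, rng):
        # a1=1, a3=-1, k_nb=-1: adoption probability 1; both edge gates are
        # then closed at the extremes, so attitudes stay put
        out = new_belief_substep(AgentState(1.0, 0.0, a3=-1.0), -0.5,
                                 self.params, rng)
        assert out.adopted and out.a1 == 1.0 and out.a3 == -1.0

    def test_latent_a3_frozen_without_adoption(self, rng):
        params = ModelParams(n_agents=20, n_steps=500, seed=4,
                             new_belief_enabled=False)
        record = run_simulation(params)
        first, last = record.snapshots[0], record.snapshots[-1]
        assert np.array_equal(first.a3, last.a3)


class TestRunSimulation:
    def test_single_step_bookkeeping(self):
        record = run_simulation(ModelParams(n_agents=10, n_steps=1, seed=1))
        assert record.times == [0, 1]
        assert len(record.snapshots) == 2
        assert record.selection_counts.sum() == 1

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(n_agents=10, n_steps=0)

    def test_determinism_same_seed(self):
        params = ModelParams(n_agents=30, n_steps=2000, seed=9,
                             new_belief_enabled=True)
        r1, r2 = run_simulation(params), run_simulation(params)
        assert r1.times == r2.times
        for p1, p2 in zip(r1.snapshots, r2.snapshots):
            assert np.array_equal(p1.a1, p2.a1)
            assert np.array_equal(p1.a2, p2.a2)
            assert np.array_equal(p1.a3, p2.a3)
            assert np.array_equal(p1.adopted, p2.adopted)
        assert np.array_equal(r1.selection_counts, r2.selection_counts)
        assert r1.max_abs_attitude == r2.max_abs_attitude

    def test_attitudes_bounded_throughout(self):
        record = run_simulation(ModelParams(n_agents=50, n_steps=5000, seed=2))
        assert record.max_abs_attitude <= 1.0
        for pop in record.snapshots:
            assert np.all(np.abs(pop.a1) <= 1.0)
            assert np.all(np.abs(pop.a2) <= 1.0)

    def test_snapshot_cadence(self):
        record = run_simulation(
            ModelParams(n_agents=5, n_steps=100, seed=0, snapshot_every=30))
        assert record.times == [0, 30, 60, 90, 100]


def test_corner_population_is_fixed_point_without_noise(rng):
    """With Z_A = 0, corner states consistent with k0 are invariant."""
    agents = [AgentState(1.0, -1.0), AgentState(-1.0, 1.0),
              AgentState(1.0, -1.0)]
    pop = make_population(*agents)
    params = ModelParams(n_agents=3, n_steps=1, link=NewsLink(k0=-1),
                         noise=NoiseSpec(za_magnitude=0.0))
    before = (pop.a1.copy(), pop.a2.copy())
    for _ in range(500):
        exposure_step(pop, params, rng)
    assert np.array_equal(pop.a1, before[0])
    assert np.array_equal(pop.a2, before[1])


def test_mirror_symmetry_under_k0_flip(rng):
    """Negating a2 and k0 while negating the attitude-2 noise signs gives a
    trajectory exactly mirrored in a2 (a1 untouched)."""
    noise = NoiseSpec()
    params_neg = ModelParams(n_agents=40, n_steps=1, link=NewsLink(k0=-1))
    params_pos = dataclasses.replace(params_neg, link=NewsLink(k0=1))
    pop_neg = init_population(params_neg, rng)
    pop_pos = pop_neg.copy()
    pop_pos.a2 = -pop_pos.a2
    for _ in range(3000):
        idx = int(rng.integers(pop_neg.size))
        draws = sample_edge_draws(rng, noise)
        mirrored = dataclasses.replace(draws, za_second=-draws.za_second)
        apply_exposure(pop_neg, idx, params_neg, draws)
        apply_exposure(pop_pos, idx, params_pos, mirrored)
    assert np.array_equal(pop_pos.a1, pop_neg.a1)
    assert np.array_equal(pop_pos.a2, -pop_neg.a2)
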