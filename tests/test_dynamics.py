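import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdpa import (
    GameParams,
    PayoffLedger,
    SimulationConfig,
    accrue_payoffs_sync,
    async_elementary_move,
    async_step,
    build_lattice,
    fermi_probability,
    imitation_update_sync,
    init_population,
    run_simulation,
    sync_step,
)
from _reference import reference_pd_sync_step, reference_sync_step
from conftest import random_world


class TestInitPopulation:
    def test_pd_mode_puts_all_mass_at_level_zero(self, rng):
        w = init_population(build_lattice(30), "pd", rng)
        assert (w.alpha_idx == 0).all()

    def test_opd_mode_uses_only_the_extreme_levels(self, rng):
        w = init_population(build_lattice(100), "opd", rng)
        assert set(np.unique(w.alpha_idx)) == {0, 8}
        frac_loner = (w.alpha_idx == 8).mean()
        assert abs(frac_loner - 0.5) < 0.015  # binomial 3-sigma at N = 10^4

    def test_pdpa_mode_occupies_all_levels_uniformly(self, rng):
        w = init_population(build_lattice(100), "pdpa", rng)
        counts = np.bincount(w.alpha_idx.ravel(), minlength=9)
        assert (counts > 0).all()
        # each level expects N/9 ~ 1111 agents; 5 sigma ~ 166
        assert np.abs(counts - 10_000 / 9).max() < 170

    def test_strategies_are_balanced_coin_flips(self, rng):
        w = init_population(build_lattice(100), "pdpa", rng)
        assert set(np.unique(w.s)) == {0, 1}
        assert abs(w.s.mean() - 0.5) < 0.015

    def test_unknown_mode_raises(self, rng):
        with pytest.raises(ValueError, match="mode"):
            init_population(build_lattice(4), "voluntary", rng)


class TestAccruePayoffsSync:
    def test_all_abstainers_earn_degree_times_loner(self, all_loners_5x5, params, rng):
        ledger = accrue_payoffs_sync(all_loners_5x5, params, rng)
        np.testing.assert_allclose(ledger.utilities, 4 * params.L)

    def test_all_cooperators_earn_degree_times_reward(self, params, rng):
        w = build_lattice(5)  # all C, alpha = 0
        ledger = accrue_payoffs_sync(w, params, rng)
        np.testing.assert_allclose(ledger.utilities, 4 * params.R)

    def test_single_cooperator_utilities_enumerated_by_hand(
        self, single_c_3x3, params, rng
    ):
        # 18 edges on the 3x3 torus: the lone C meets 4 defectors (S = 0 each),
        # its 4 neighbours each exploit it once (T) and meet defectors
        # otherwise (P = 0); the 4 corner defectors only meet defectors.
        util = accrue_payoffs_sync(single_c_3x3, params, rng).utilities.reshape(3, 3)
        expected = np.array([[0, 1.4, 0], [1.4, 0, 1.4], [0, 1.4, 0]])
        np.testing.assert_allclose(util, expected)

    def test_utilities_are_sums_of_four_edge_payoffs(self, params):
        rng = np.random.default_rng(3)
        w = random_world(8, rng)
        util = accrue_payoffs_sync(w, params, rng).utilities
        lo = 4 * min(params.P, params.S)
        hi = 4 * max(params.T, params.R, params.L)
        assert util.min() >= lo and util.max() <= hi

    def test_consumes_exactly_four_draws_per_agent(self, params):
        w = random_world(6, np.random.default_rng(0))
        rng = np.random.default_rng(42)
        accrue_payoffs_sync(w, params, rng)
        expected = np.random.default_rng(42)
        expected.random(4 * w.n_agents)
        assert rng.random() == expected.random()


class TestImitationUpdateSync:
    def test_homogeneous_population_is_fixed(self, params, rng):
        w = build_lattice(4)
        w.s[...] = 1
        new = sync_step(w, params, rng)
        assert new.state_equal(w)

    def test_unique_strictly_best_neighbour_is_copied(self, single_c_3x3):
        # give the North neighbour of every site the only high utility
        util = np.zeros(9)
        util[0 * 3 + 1] = 2.0  # site (0,1), the North neighbour of the centre C
        new = imitation_update_sync(single_c_3x3, PayoffLedger(util))
        # centre (1,1) copies (0,1): a defector at level 0
        assert new.s[1, 1] == 1
        # (0,1) itself is weakly best in its own neighbourhood: unchanged
        assert new.s[0, 1] == single_c_3x3.s[0, 1]

    def test_two_way_tie_at_maximum_freezes_agent(self, single_c_3x3):
        util = np.zeros(9)
        util[0 * 3 + 1] = 1.4  # North neighbour of the centre
        util[2 * 3 + 1] = 1.4  # South neighbour: tie at the maximum
        new = imitation_update_sync(single_c_3x3, PayoffLedger(util))
        assert new.s[1, 1] == 0  # the centre cooperator keeps its state

    def test_tie_between_best_neighbour_and_self_freezes_agent(self, single_c_3x3):
        util = np.zeros(9)
        util[0 * 3 + 1] = 1.4
        util[1 * 3 + 1] = 1.4  # the centre matches its best neighbour
        new = imitation_update_sync(single_c_3x3, PayoffLedger(util))
        assert new.s[1, 1] == 0

    def test_lone_cooperator_world_is_frozen_by_the_tie_rule(
        self, single_c_3x3, params, rng
    ):
        # All four maximal neighbours of the centre tie at u = T, so the
        # centre keeps cooperating; every other agent is weakly best or tied.
        new = sync_step(single_c_3x3, params, rng)
        assert new.state_equal(single_c_3x3)

    def test_does_not_mutate_input_world(self, params, rng):
        w = random_world(5, rng)
        s0, a0 = w.s.copy(), w.alpha_idx.copy()
        ledger = accrue_payoffs_sync(w, params, rng)
        imitation_update_sync(w, ledger)
        assert np.array_equal(w.s, s0) and np.array_equal(w.alpha_idx, a0)


class TestSyncStep:
    def test_all_defectors_is_closed(self, params, rng):
        w = build_lattice(6)
        w.s[...] = 1
        w.alpha_idx[...] = rng.integers(0, 9, size=(6, 6))
        for _ in range(5):
            w = sync_step(w, params, rng)
        assert (w.s == 1).all()

    def test_fixed_seed_reproduces_bitwise(self, params):
        w = random_world(10, np.random.default_rng(1))
        a = sync_step(w, params, np.random.default_rng(9))
        b = sync_step(w, params, np.random.default_rng(9))
        assert a.state_equal(b)

    @pytest.mark.parametrize("side,seed", [(3, 0), (4, 1), (5, 2), (8, 3)])
    def test_matches_naive_reference(self, params, side, seed):
        w = random_world(side, np.random.default_rng(seed))
        got = sync_step(w, params, np.random.default_rng(seed + 100))
        ref_s, ref_ai = reference_sync_step(w, params, np.random.default_rng(seed + 100))
        assert np.array_equal(got.s, ref_s)
        assert np.array_equal(got.alpha_idx, ref_ai)

    def test_pd_mode_trajectory_matches_abstention_free_engine(self, params):
        w = random_world(8, np.random.default_rng(4), mode="pd")
        engine_rng = np.random.default_rng(5)
        ref_rng = np.random.default_rng(5)
        cur = w
        for _ in range(10):
            cur = sync_step(cur, params, engine_rng)
            ref_s, ref_ai = reference_pd_sync_step(w, params, ref_rng)
            w.s[...] = ref_s
            w.alpha_idx[...] = ref_ai
            assert np.array_equal(cur.s, ref_s)
            assert np.array_equal(cur.alpha_idx, ref_ai)


class TestFermiProbability:
    def test_equal_utilities_give_half(self):
        assert fermi_probability(2.2, 2.2) == 0.5

    def test_closed_form_value(self):
        # (u_x - u_y)/(kappa K) = ln 3 at the standard kappa=4, K=0.1
        w = fermi_probability(0.4 * np.log(3.0), 0.0)
        assert w == pytest.approx(0.25, abs=1e-12)

    def test_large_gap_is_stable(self):
        assert fermi_probability(-100.0, 0.0) == pytest.approx(1.0, abs=1e-15)
        assert fermi_probability(100.0, 0.0) == pytest.approx(0.0, abs=1e-15)

    @given(
        ux=st.floats(-6, 6),
        uy=st.floats(-6, 6),
    )
    @settings(deadline=None)
    def test_complement_identity_and_range(self, ux, uy):
        w = fermi_probability(ux, uy)
        assert 0.0 < w < 1.0
        assert w + fermi_probability(uy, ux) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_decreasing_in_utility_gap(self):
        gaps = np.linspace(-3, 3, 25)
        vals = [fermi_probability(g, 0.0) for g in gaps]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_noise_or_degree_raises(self):
        with pytest.raises(ValueError):
            fermi_probability(0, 0, K=0.0)
        with pytest.raises(ValueError):
            fermi_probability(0, 0, kappa=0)


class TestAsyncDynamics:
    def test_identical_population_never_changes_observably(self, params):
        w = build_lattice(5)  # all C, alpha = 0
        rng = np.random.default_rng(2)
        for _ in range(20):
            w = async_step(w, params, rng)
        assert (w.s == 0).all() and (w.alpha_idx == 0).all()

    def test_all_loners_are_frozen(self, all_loners_5x5, params):
        # u_x = u_y = 4L always, so u_y > u_x never holds and no copy occurs
        rng = np.random.default_rng(3)
        w = all_loners_5x5.copy()
        for _ in range(20):
            w = async_step(w, params, rng)
        assert w.state_equal(all_loners_5x5)

    def test_all_defectors_strategy_composition_invariant(self, params):
        rng = np.random.default_rng(4)
        w = build_lattice(6)
        w.s[...] = 1
        w.alpha_idx[...] = rng.integers(0, 9, size=(6, 6))
        for _ in range(10):
            w = async_step(w, params, rng)
        assert (w.s == 1).all()

    def test_elementary_move_touches_at_most_one_site(self, params):
        rng = np.random.default_rng(5)
        w = random_world(6, rng)
        before_s, before_ai = w.s.copy(), w.alpha_idx.copy()
        async_elementary_move(w, params, rng)
        changed = (w.s != before_s) | (w.alpha_idx != before_ai)
        assert changed.sum() <= 1

    def test_step_performs_exactly_n_moves_worth_of_draws(self, params):
        w = random_world(4, np.random.default_rng(6))
        rng = np.random.default_rng(77)
        async_step(w, params, rng)
        expected = np.random.default_rng(77)
        expected.random(19 * w.n_agents)  # 19 uniforms per elementary move
        assert rng.random() == expected.random()

    def test_fixed_seed_reproduces_bitwise(self, params):
        w = random_world(8, np.random.default_rng(7))
        a = async_step(w, params, np.random.default_rng(11))
        b = async_step(w, params, np.random.default_rng(11))
        assert a.state_equal(b)
        # the input world is untouched: rebuilding it reproduces its state
        assert np.array_equal(w.s, random_world(8, np.random.default_rng(7)).s)


class TestRunSimulation:
    def make_config(self, **kw):
        base = dict(
            params=GameParams(T=1.4, L=0.4),
            side=12,
            update_scheme="synchronous",
            init_mode="pdpa",
            mc_steps=50,
            seed=0,
            record_every=10,
        )
        base.update(kw)
        return SimulationConfig(**base)

    def test_zero_steps_disallowed(self):
        with pytest.raises(ValueError, match="mc_steps"):
            run_simulation(self.make_config(mc_steps=0))

    def test_single_step_records_initial_and_final(self):
        r = run_simulation(self.make_config(mc_steps=1))
        assert [m.step for m in r.metrics] == [0, 1]

    def test_record_grid_includes_final_step(self):
        r = run_simulation(self.make_config(mc_steps=25, record_every=10))
        assert [m.step for m in r.metrics] == [0, 10, 20, 25]

    def test_pd_mode_mean_alpha_is_identically_zero(self):
        r = run_simulation(self.make_config(init_mode="pd", mc_steps=40))
        assert all(m.mean_alpha == 0.0 for m in r.metrics)

    @pytest.mark.parametrize("scheme", ["synchronous", "asynchronous"])
    def test_same_config_same_seed_identical_result(self, scheme):
        cfg = self.make_config(update_scheme=scheme, seed=123)
        a, b = run_simulation(cfg), run_simulation(cfg)
        assert a.final_world.state_equal(b.final_world)
        for ma, mb in zip(a.metrics, b.metrics):
            assert ma.step == mb.step
            assert ma.mean_eps == mb.mean_eps
            assert ma.mean_alpha == mb.mean_alpha
            assert np.array_equal(ma.alpha_histogram, mb.alpha_histogram)

    @pytest.mark.parametrize("scheme", ["synchronous", "asynchronous"])
    def test_alpha_support_never_grows(self, scheme):
        cfg = self.make_config(update_scheme=scheme, mc_steps=120, seed=5)
        r = run_simulation(cfg)
        support = [set(np.flatnonzero(m.alpha_histogram)) for m in r.metrics]
        for earlier, later in zip(support, support[1:]):
            assert later <= earlier

    def test_population_size_and_state_validity_preserved(self):
        r = run_simulation(self.make_config(mc_steps=80, seed=9))
        w = r.final_world
        assert w.n_agents == 144
        assert np.isin(w.s, (0, 1)).all()
        assert w.alpha_idx.min() >= 0 and w.alpha_idx.max() < 9

    def test_early_stop_halts_in_absorbing_state(self):
        cfg = self.make_config(init_mode="pd", side=6, mc_steps=500, seed=2, early_stop=True)
        r = run_simulation(cfg)
        w = r.final_world
        absorbed = (w.s == w.s.flat[0]).all() and (w.alpha_idx == w.alpha_idx.flat[0]).all()
        if r.steps_run < 500:
            assert absorbed
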