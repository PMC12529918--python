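"""Sampler mechanics: Metropolis rules, inner sequences, outer acceptance,
adaptation, determinism and state restoration."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from framonc.mbe import CompositeEnergyModel
from framonc.mc import (
    AdaptationController,
    LowLevelSampler,
    MoveSet,
    NestedSpec,
    _metropolis_probability,
    load_checkpoint,
    metropolis_move,
    outer_accept,
    outer_acceptance_probability,
    run_framonc,
    run_inner_sequence,
    save_checkpoint,
)
from framonc.potentials import FFParameters, ForceFieldBackend, ff_configuration_energy
from framonc.system import Box, Configuration, MoleculeInstance
from framonc.toys import ToySystemSpec, generate_toy_system
from framonc.units import R_GAS


def make_sampler(config, templates, seed=0, ensemble="NVT", moveset=None):
    ss = np.random.SeedSequence(seed)
    r1, r2 = [np.random.default_rng(s) for s in ss.spawn(2)]
    return LowLevelSampler(
        config, templates, FFParameters(r_cut=4.5),
        moveset or MoveSet(), ensemble, r1, r2,
    )


class TestInnerMetropolis:
    def test_downhill_and_flat_moves_always_accepted(self):
        assert _metropolis_probability(0.0, 0, 0, 5, 300, 1, "NVT") == 1.0
        assert _metropolis_probability(-3.0, 0, 0, 5, 300, 1, "NVT") == 1.0

    def test_rt_ln2_uphill_move_accepted_half_the_time(self):
        T = 300.0
        dU = R_GAS * T * np.log(2)
        p = _metropolis_probability(dU, 0, 0, 5, T, 1, "NVT")
        assert p == pytest.approx(0.5, rel=1e-12)
        rng = np.random.default_rng(123)
        frac = np.mean(rng.random(100000) < p)
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_infinite_energy_rejected(self):
        assert _metropolis_probability(np.inf, 0, 0, 5, 300, 1, "NVT") == 0.0

    def test_single_move_mutates_at_most_one_molecule(self, water_box_30):
        config, templates = water_box_30
        work = config.copy()
        before = [m.com_position.copy() for m in work.molecules]
        rng = np.random.default_rng(4)
        metropolis_move(
            work, templates, MoveSet(), FFParameters(r_cut=4.5),
            300.0, 1.0, "NVT", rng,
        )
        moved = sum(
            not np.array_equal(b, m.com_position)
            for b, m in zip(before, work.molecules)
        )
        assert moved <= 1


class TestInnerSequence:
    def test_period_one_equals_single_move(self, water_box_30):
        config, templates = water_box_30
        s1 = make_sampler(config.copy(), templates, seed=3)
        s2 = make_sampler(config.copy(), templates, seed=3)
        spec = NestedSpec(period_P=1, T_target=300.0)
        run_inner_sequence(s1, spec)
        s2.attempt(300.0, 1.0)
        for a, b in zip(s1.config.molecules, s2.config.molecules):
            assert np.array_equal(a.com_position, b.com_position)
            assert np.array_equal(a.orientation, b.orientation)

    def test_period_zero_disallowed(self):
        with pytest.raises(ValueError):
            NestedSpec(period_P=0)

    def test_frozen_moveset_returns_start_with_zero_energy_change(
        self, water_box_30
    ):
        config, templates = water_box_30
        frozen = MoveSet(max_translation=0.0, max_rotation=0.0,
                         max_ln_volume_step=0.0)
        sampler = make_sampler(config.copy(), templates, seed=1, moveset=frozen)
        before = [m.com_position.copy() for m in sampler.config.molecules]
        _, dU = run_inner_sequence(sampler, NestedSpec(period_P=25))
        assert dU == 0.0
        for b, m in zip(before, sampler.config.molecules):
            assert np.array_equal(b, m.com_position)

    def test_outer_spacing_decorrelates_with_larger_period(self, water_box_30):
        """Integrated autocorrelation of the generator energy at outer-loop
        spacing shrinks as the inner period grows."""
        config, templates = water_box_30

        def lag1_autocorr(P, seed=9, n_outer=300):
            sampler = make_sampler(config.copy(), templates, seed=seed)
            spec = NestedSpec(period_P=P, T_target=300.0)
            xs = []
            for _ in range(n_outer):
                run_inner_sequence(sampler, spec)
                xs.append(sampler.e_total)
            x = np.asarray(xs[50:])
            x = x - x.mean()
            denom = (x ** 2).sum()
            return float((x[:-1] * x[1:]).sum() / denom) if denom > 0 else 0.0

        r1 = lag1_autocorr(1)
        r100 = lag1_autocorr(40)
        assert r100 < r1


class TestIdealGasEOS:
    def test_npt_mean_volume_matches_closed_form(self, ideal_templates):
        """Zero potential, ln-V proposals: <V> = (N+1)RT/p."""
        N, T, p = 5, 300.0, 1.0
        from framonc.units import BAR_A3_TO_KJ_PER_MOL

        v_expect = (N + 1) * R_GAS * T / (p * BAR_A3_TO_KJ_PER_MOL)
        edge = v_expect ** (1 / 3)
        rng = np.random.default_rng(10)
        config = Configuration(
            Box(np.full(3, edge)),
            [
                MoleculeInstance(
                    "ideal", rng.random(3) * edge, np.array([1.0, 0, 0, 0])
                )
                for _ in range(N)
            ],
        )
        moveset = MoveSet(volume_weight=1.0, translation_weight=0.0,
                          rotation_weight=0.0, max_ln_volume_step=0.8)
        sampler = make_sampler(config, ideal_templates, seed=21,
                               ensemble="NpT", moveset=moveset)
        vols = []
        for _ in range(30000):
            sampler.attempt(T, p)
            vols.append(sampler.config.box.volume)
        from framonc.estimators import ScalarSeries

        series = ScalarSeries(np.array(vols), "A^3", burn_in=2000)
        assert abs(series.mean - v_expect) < 3 * series.sem


class TestOuterAcceptance:
    def test_telescoping_cancellation_gives_unit_probability(self):
        spec = NestedSpec(T_target=300.0, T_gen=300.0)
        for du in (-5.0, 0.0, 17.3):
            assert outer_acceptance_probability(du, du, 0.0, spec) == 1.0

    def test_rt_ln2_energy_mismatch_gives_half(self):
        spec = NestedSpec(T_target=300.0, T_gen=300.0)
        dU_low = 2.0
        dU_high = dU_low + R_GAS * 300.0 * np.log(2)
        assert outer_acceptance_probability(dU_high, dU_low, 0.0, spec) == (
            pytest.approx(0.5, rel=1e-12)
        )

    def test_depends_only_on_energy_differences_at_matched_conditions(self):
        # adding one constant to both tiers shifts both deltas equally
        spec = NestedSpec(T_target=300.0, T_gen=300.0)
        p0 = outer_acceptance_probability(3.7, 1.2, 0.0, spec)
        p1 = outer_acceptance_probability(3.7 + 50.0, 1.2 + 50.0, 0.0, spec)
        assert p0 == pytest.approx(p1, rel=1e-12)

    @given(
        st.floats(-50, 50), st.floats(-50, 50), st.floats(-100, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_probability_always_in_unit_interval(self, du_h, du_l, dv):
        spec = NestedSpec(T_target=290.0, T_gen=350.0, p_target=1.0,
                          p_gen=2.0, ensemble="NpT")
        prob = outer_acceptance_probability(du_h, du_l, dv, spec)
        assert 0.0 <= prob <= 1.0

    def test_decision_reproducible_per_rng(self):
        spec = NestedSpec(T_target=300.0)
        p1, d1 = outer_accept(1.0, 0.5, 0.0, spec, np.random.default_rng(5))
        p2, d2 = outer_accept(1.0, 0.5, 0.0, spec, np.random.default_rng(5))
        assert (p1, d1) == (p2, d2)


class TestAdaptationController:
    def _run_window(self, controller, accepted_fraction, start=0):
        n = controller.spec.adapt_window
        k = int(round(accepted_fraction * n))
        for i in range(n):
            controller.record(i < k, start + i)

    def test_in_window_observation_changes_nothing(self):
        spec = NestedSpec(adapt=True, T_target=300.0)
        c = AdaptationController(spec)
        self._run_window(c, 0.80)
        assert spec.T_gen == 300.0

    def test_low_acceptance_lowers_generating_temperature(self):
        spec = NestedSpec(adapt=True, T_target=300.0)
        c = AdaptationController(spec)
        self._run_window(c, 0.40)
        assert spec.T_gen < 300.0

    def test_high_acceptance_raises_generating_temperature(self):
        spec = NestedSpec(adapt=True, T_target=300.0)
        c = AdaptationController(spec)
        self._run_window(c, 0.98)
        assert spec.T_gen > 300.0

    def test_two_consecutive_in_window_observations_freeze(self):
        spec = NestedSpec(adapt=True, T_target=300.0)
        c = AdaptationController(spec)
        self._run_window(c, 0.80)
        assert not c.frozen
        self._run_window(c, 0.85, start=spec.adapt_window)
        assert c.frozen
        t_frozen = spec.T_gen
        self._run_window(c, 0.10, start=2 * spec.adapt_window)
        assert spec.T_gen == t_frozen  # frozen controller never updates

    def test_updates_clipped_to_safe_band(self):
        spec = NestedSpec(adapt=True, T_target=300.0, adapt_kappa=50.0)
        c = AdaptationController(spec)
        self._run_window(c, 0.0)
        assert spec.T_gen >= 0.5 * 300.0


def small_nested_run(config, templates, seed, n_outer=25, epsilon_scale=1.1,
                     **spec_kwargs):
    params = FFParameters(r_cut=4.5)
    model = CompositeEnergyModel(
        ForceFieldBackend(params),
        ForceFieldBackend(params, epsilon_scale=epsilon_scale),
        3.5,
    )
    spec = NestedSpec(period_P=10, T_target=300.0, seed=seed, **spec_kwargs)
    return run_framonc(
        config.copy(), templates, params, model, spec, MoveSet(), n_outer
    )


class TestNestedRun:
    def test_fixed_seed_reproduces_observables_bitwise(self, water_box_30):
        config, templates = water_box_30
        r1 = small_nested_run(config, templates, seed=42)
        r2 = small_nested_run(config, templates, seed=42)
        assert r1.series["u_high"] == r2.series["u_high"]
        assert r1.series["density"] == r2.series["density"]
        assert r1.outer_accepted == r2.outer_accepted

    def test_rejected_outer_proposal_restores_prior_state(self, water_box_30):
        """A rejection must leave the retained series entry identical to the
        previous one, and the final cached energies must replay exactly."""
        config, templates = water_box_30
        res = small_nested_run(
            config, templates, seed=8, n_outer=40,
            epsilon_scale=2.5, T_gen=600.0,
        )
        assert not all(res.outer_accepted), "expected some rejections"
        u = res.series["u_high"]
        for k, acc in enumerate(res.outer_accepted):
            if k > 0 and not acc:
                assert u[k] == u[k - 1]
        final = res.final_state.config
        e_replay = ff_configuration_energy(
            final, templates, FFParameters(r_cut=4.5)
        )
        assert e_replay == pytest.approx(
            final.cached_energy_low, rel=1e-8, abs=1e-9
        )

    def test_checkpoint_round_trip_preserves_chain_state(
        self, water_box_30, tmp_path
    ):
        config, templates = water_box_30
        res = small_nested_run(config, templates, seed=3, n_outer=10)
        path = tmp_path / "chk.json"
        save_checkpoint(path, res.final_state, templates)
        state = load_checkpoint(path)
        assert state.outer_step == 10
        for a, b in zip(state.config.molecules, res.final_state.config.molecules):
            assert np.allclose(a.com_position, b.com_position)
        assert state.config.cached_energy_high == pytest.approx(
            res.final_state.config.cached_energy_high
        )
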