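"""Kinetic model: integration, limit cycle, decay mode, comparisons."""

import math

import numpy as np
import pytest

from rbdyn.config import reference_model_params
from rbdyn.halflife import fit_exponential
from rbdyn.model import (
    SG2M,
    ModelParams,
    _State,
    _step,
    amount_dynamics_report,
    burn_in_to_limit_cycle,
    compare_model_to_data,
    concentration_amplitude,
    simulate,
    simulate_decay_mode,
)

LN2 = math.log(2.0)


class TestDivision:
    def test_division_halves_mass_and_amount_preserving_concentration(self):
        """With all rates zero, a division step maps (M, Rb) = (2, 1) to
        (1, 0.5); the concentration is 0.5 before and after."""
        params = ModelParams(
            gamma=0.0, delta=1.0, alpha=0.0, beta0=0.0, epsilon=1.0,
            conc_threshold=0.0, t_sg2m=0.01, dt=0.01,
        )
        s = _State(2.0, 1.0)
        s.phase = SG2M
        assert s.conc == pytest.approx(0.5)
        event = _step(params, s)
        assert event[0] == "division"
        assert (s.m, s.rb) == (1.0, 0.5)
        assert s.conc == pytest.approx(0.5)

    def test_recorded_trajectory_continuous_at_division(self, reference_limit_cycle):
        traj = reference_limit_cycle
        i = int(np.argmin(np.abs(traj.times - traj.division_times[0])))
        c = traj.concentration
        assert abs(c[i] - c[i - 1]) < 0.01  # no concentration jump
        assert traj.mass[i] / traj.mass[i - 1] == pytest.approx(0.5, abs=0.01)


class TestAnalyticLimit:
    def test_concentration_converges_to_fixed_point(self):
        """epsilon = delta = 1: dc/dt = alpha - (beta0 + gamma) c, so the
        concentration relaxes to alpha/(beta0+gamma); with the threshold
        below that value the run arrests without a transition."""
        params = reference_model_params(
            epsilon=1.0, delta=1.0, conc_threshold=1e-9, max_g1_hours=200.0
        )
        fixed_point = params.alpha / (params.beta0 + params.gamma)
        traj = simulate(params, (1.0, 1.0), n_cycles=1)
        assert traj.arrested
        assert not traj.gs_times
        assert traj.concentration[-1] == pytest.approx(fixed_point, rel=1e-3)

    def test_monotone_decay_toward_fixed_point_from_above(self):
        params = reference_model_params(
            epsilon=1.0, delta=1.0, conc_threshold=1e-9, max_g1_hours=50.0
        )
        traj = simulate(params, (1.0, 1.0), n_cycles=1)
        assert np.all(np.diff(traj.concentration) < 0)


class TestLimitCycle:
    def test_reference_cycle_converges_with_expected_shape(self, reference_limit_cycle):
        traj = reference_limit_cycle
        assert traj.converged
        c, t = traj.concentration, traj.times
        gs = traj.gs_times[0]
        assert np.all(np.diff(c[t < gs]) < 0)  # dilution through G1
        assert np.all(np.diff(c[t >= gs]) > 0)  # recovery through S-G2-M
        assert gs - t[0] == pytest.approx(10.0, abs=0.1)

    def test_limit_cycle_independent_of_initial_conditions(self, reference_params):
        a = burn_in_to_limit_cycle(reference_params, initial=(1.0, 1.2))
        b = burn_in_to_limit_cycle(reference_params, initial=(5.0, 4.0))
        assert a.converged and b.converged
        assert a.concentration[0] == pytest.approx(b.concentration[0], rel=1e-4)
        assert a.division_times[0] - a.times[0] == pytest.approx(
            b.division_times[0] - b.times[0], rel=1e-4
        )

    def test_halving_dt_changes_birth_concentration_below_tenth_percent(
        self, reference_params, reference_limit_cycle
    ):
        fine = burn_in_to_limit_cycle(reference_model_params(dt=reference_params.dt / 2))
        rel = abs(
            fine.concentration[0] - reference_limit_cycle.concentration[0]
        ) / reference_limit_cycle.concentration[0]
        assert rel < 1e-3

    def test_synthesis_step_variant_has_much_smaller_amplitude(self, reference_limit_cycle):
        synth = burn_in_to_limit_cycle(reference_model_params("synthesis_step"))
        assert synth.converged
        assert concentration_amplitude(synth) < 0.5 * concentration_amplitude(
            reference_limit_cycle
        )

    def test_g1_length_weakly_decreases_with_epsilon(self):
        """Less S-G2-M stabilisation (higher epsilon) lowers the birth
        concentration, shortening the dilution path to the fixed threshold."""
        lengths = []
        for eps in (0.1, 0.2, 0.35, 0.5):
            traj = burn_in_to_limit_cycle(reference_model_params(epsilon=eps))
            assert traj.converged
            lengths.append(traj.gs_times[0] - traj.times[0])
        assert all(a >= b for a, b in zip(lengths, lengths[1:]))

    def test_threshold_above_reachable_band_arrests(self):
        traj = burn_in_to_limit_cycle(
            reference_model_params(conc_threshold=0.05, max_g1_hours=60.0)
        )
        assert traj.arrested and not traj.converged


class TestDecayMode:
    def test_g1_round_trip_recovers_configured_rate(self, reference_params):
        traj = simulate_decay_mode(reference_params, "G1", duration=10.0)
        est = fit_exponential(traj.times, traj.rb_amount, fit_start_delay=0.0)
        assert est.k == pytest.approx(reference_params.beta0, abs=1e-6)
        assert est.t_half == pytest.approx(6.4, abs=1e-4)

    def test_sg2m_rate_is_eighty_percent_lower(self, reference_params):
        g1 = simulate_decay_mode(reference_params, "G1", duration=10.0)
        sg2 = simulate_decay_mode(reference_params, "SG2M", duration=10.0)
        k_g1 = fit_exponential(g1.times, g1.rb_amount, fit_start_delay=0.0).k
        k_sg2 = fit_exponential(sg2.times, sg2.rb_amount, fit_start_delay=0.0).k
        assert 100.0 * (1.0 - k_sg2 / k_g1) == pytest.approx(80.0, abs=1e-6)

    def test_epsilon_one_makes_phases_identical(self):
        params = reference_model_params(epsilon=1.0)
        g1 = simulate_decay_mode(params, "G1", duration=10.0)
        sg2 = simulate_decay_mode(params, "SG2M", duration=10.0)
        np.testing.assert_allclose(g1.rb_amount, sg2.rb_amount, rtol=1e-12)

    def test_unknown_phase_rejected(self, reference_params):
        with pytest.raises(ValueError):
            simulate_decay_mode(reference_params, "M", duration=5.0)


class TestAmountDynamics:
    def test_reference_cycle_amount_nearly_constant_in_early_g1(self, reference_limit_cycle):
        report = amount_dynamics_report(reference_limit_cycle)
        assert report["early_g1_rel_change"] < 0.15
        assert report["sg2m_fold_accumulation"] > 1.5

    def test_no_synthesis_amount_strictly_decreasing(self):
        params = reference_model_params(alpha=0.0, conc_threshold=1e-9, max_g1_hours=20.0)
        traj = simulate(params, (1.0, 1.0), n_cycles=1)
        assert np.all(np.diff(traj.rb_amount) < 0)

    def test_no_degradation_amount_strictly_increasing(self):
        params = reference_model_params(beta0=0.0, conc_threshold=1e-9, max_g1_hours=20.0)
        traj = simulate(params, (1.0, 1.0), n_cycles=1)
        assert np.all(np.diff(traj.rb_amount) > 0)


class TestModelDataComparison:
    def test_model_vs_itself_is_zero(self, reference_limit_cycle):
        traj = reference_limit_cycle
        rmse = compare_model_to_data(
            traj, traj.times - traj.gs_times[0], traj.concentration
        )
        assert rmse == pytest.approx(0.0, abs=1e-12)

    def test_model_vs_flat_trace_equals_normalized_rms_deviation(self, reference_limit_cycle):
        traj = reference_limit_cycle
        times = traj.times - traj.gs_times[0]
        rmse = compare_model_to_data(traj, times, np.ones_like(times))
        c = traj.concentration / traj.concentration.mean()
        assert rmse == pytest.approx(float(np.sqrt(np.mean((c - 1.0) ** 2))), rel=1e-6)

    def test_no_overlap_rejected(self, reference_limit_cycle):
        with pytest.raises(ValueError, match="overlap"):
            compare_model_to_data(
                reference_limit_cycle, np.array([1000.0, 1001.0]), np.array([1.0, 1.0])
            )

    def test_degradation_variant_fits_dilution_cohort_better(self, cycling_cohort):
        """On an aligned synthetic dilution cohort, the degradation-step
        limit cycle overlays better than the synthesis-step variant."""
        from rbdyn.traces import (
            align_and_normalize,
            annotate_phases,
            cohort_geminin_threshold,
            concentration_trace,
        )

        thr = cohort_geminin_threshold(cycling_cohort)
        conc_traces, anchors = [], {}
        for trace in cycling_cohort:
            ann = annotate_phases(trace, thr)
            sg2 = ann.interval("SG2")
            if sg2 is None or (ann.interval("earlyG1") or ann.interval("G1")) is None:
                continue
            conc_traces.append(concentration_trace(trace, "rb"))
            anchors[trace.cell_id] = sg2[0]
        _, summary, _ = align_and_normalize(conc_traces, anchors)
        dense = summary[summary["n"] >= 20]
        rmses = {}
        for variant in ("degradation_step", "synthesis_step"):
            traj = burn_in_to_limit_cycle(reference_model_params(variant))
            rmses[variant] = compare_model_to_data(
                traj, dense.index.to_numpy(), dense["mean"].to_numpy()
            )
        assert rmses["degradation_step"] < rmses["synthesis_step"]


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        reference_model_params(epsilon=0.0)
    with pytest.raises(ValueError):
        reference_model_params(dt=-0.1)
    with pytest.raises(ValueError):
        reference_model_params(variant="nope")
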