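"""Trace analysis: baseline subtraction, amplitudes, exponential fits, QC."""

import numpy as np
import pytest

from conftest import pure_exponential_trace
from girkfit.params import CascadeParams, LigandKinetics
from girkfit.protocol import make_protocol
from girkfit.simulate import SimulatedTrace, evoked_ss, simulate_trace
from girkfit.traces import (QCResult, fit_activation, fit_deactivation,
                            peak_normalize_and_average, qc_trace,
                            response_amplitude, subtract_basal)


def trace_from_values(t, values, protocol, params=None):
    """Wrap raw evoked-magnitude samples as an inward-negative trace."""
    params = params or CascadeParams()
    return SimulatedTrace(time=t, current=-np.asarray(values), seed=None,
                          protocol=protocol, params=params)


@pytest.fixture(scope="module")
def washout_protocol():
    return make_protocol("washout", "L", [1e-8], pre_s=10.0, tail_s=120.0)


class TestSubtractBasal:
    def test_constant_trace_becomes_zero(self, washout_protocol):
        t = np.linspace(0, 140, 500)
        tr = trace_from_values(t, np.full_like(t, 1.0), washout_protocol)
        out = subtract_basal(tr, (0.0, 9.0))
        np.testing.assert_allclose(out.current, 0.0, atol=1e-12)

    def test_idempotent_up_to_noise_mean_error(self, washout_protocol):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 140, 4000)
        tr = trace_from_values(t, 0.5 + rng.normal(0, 0.005, len(t)),
                               washout_protocol)
        once = subtract_basal(tr, (0.0, 9.0))
        twice = subtract_basal(once, (0.0, 9.0))
        n_window = np.sum((t >= 0) & (t <= 9))
        assert np.max(np.abs(twice.current - once.current)) < \
            5 * 0.005 / np.sqrt(n_window)

    def test_window_overlapping_application_rejected(self, washout_protocol):
        t = np.linspace(0, 140, 500)
        tr = trace_from_values(t, np.zeros_like(t), washout_protocol)
        with pytest.raises(ValueError, match="overlaps"):
            subtract_basal(tr, (5.0, 15.0))

    def test_window_outside_trace_rejected(self, washout_protocol):
        t = np.linspace(0, 140, 500)
        tr = trace_from_values(t, np.zeros_like(t), washout_protocol)
        with pytest.raises(ValueError, match="outside"):
            subtract_basal(tr, (130.0, 150.0))


class TestResponseAmplitude:
    def test_staircase_levels_match_closed_form(self, fast_noise_free):
        lig = LigandKinetics("L", k_on=1e7, k_off=0.1)
        concs = [lig.true_kd / 3, lig.true_kd, 3 * lig.true_kd]
        proto = make_protocol("staircase", "L", concs, pre_s=60.0)
        trace = simulate_trace(lig, fast_noise_free, proto, seed=None)
        trace = subtract_basal(trace, (10.0, 50.0))
        for conc, step in zip(concs, proto.steps):
            amp = response_amplitude(trace, step)
            assert amp == pytest.approx(
                evoked_ss(conc, lig, fast_noise_free), rel=0.02)

    def test_zero_concentration_step_has_zero_amplitude(self, fast_params,
                                                        da_wt):
        proto = make_protocol("activation", "DA", [0.0], app_s=30.0)
        trace = simulate_trace(da_wt, fast_params, proto, seed=5)
        trace = subtract_basal(trace, (1.0, 9.0))
        amp = response_amplitude(trace, proto.steps[0])
        assert abs(amp) < 4 * fast_params.noise_sd

    def test_step_shorter_than_evaluation_window_rejected(self, fast_params,
                                                          da_wt):
        proto = make_protocol("activation", "DA", [1e-8], app_s=0.5)
        trace = simulate_trace(da_wt, fast_params, proto, seed=0)
        with pytest.raises(ValueError, match="shorter"):
            response_amplitude(trace, proto.steps[0])


class TestFitDeactivation:
    @pytest.mark.parametrize("tau", [1.0, 10.0, 100.0])
    def test_noise_free_exponential_recovered_exactly(self, tau,
                                                      washout_protocol):
        t, y = pure_exponential_trace(tau, 0.4, 0.02, t_end=23.0 + 6 * tau,
                                      t_start=23.0)
        proto = make_protocol("washout", "L", [1e-8], pre_s=10.0,
                              tail_s=6 * tau)
        tr = trace_from_values(t, y, proto)
        fit = fit_deactivation(tr, washout_start=23.0, window_s=5 * tau)
        assert fit.tau == pytest.approx(tau, rel=1e-3)
        assert fit.converged

    def test_noisy_decay_at_reference_dissociation_rate(self, washout_protocol):
        # tau = 1/0.197 s with realistic recording noise
        t, y = pure_exponential_trace(5.076, 0.3, 0.0, t_end=65.0,
                                      noise_sd=0.005, seed=11, t_start=23.0)
        tr = trace_from_values(t, y, washout_protocol)
        fit = fit_deactivation(tr, washout_start=23.0, window_s=42.0)
        assert fit.rate == pytest.approx(0.197, rel=0.03)

    def test_slow_ligand_full_simulation_recovery(self, fast_noise_free):
        """Simulated washout at k_off = 0.030/s, 104-s window: 1/tau within
        10% of the generating rate."""
        lig = LigandKinetics("(R)", k_on=8.65e5, k_off=0.030, efficacy=0.11)
        proto = make_protocol("washout", "(R)", [300e-9], tail_s=120.0)
        trace = simulate_trace(lig, fast_noise_free, proto, seed=None)
        trace = subtract_basal(trace, (1.0, 9.0))
        fit = fit_deactivation(trace, washout_start=23.0, window_s=104.0)
        assert fit.rate == pytest.approx(0.030, rel=0.10)

    def test_window_choice_insensitive_for_fast_decays(self, fast_params,
                                                       da_wt):
        """Fitted tau moves by < 5% between the 42-s and 104-s windows when
        the true time constant is ~5 s."""
        proto = make_protocol("washout", "DA", [10e-9], tail_s=120.0)
        trace = simulate_trace(da_wt, fast_params, proto, seed=3)
        trace = subtract_basal(trace, (1.0, 9.0))
        short = fit_deactivation(trace, 23.0, 42.0)
        long = fit_deactivation(trace, 23.0, 104.0)
        assert abs(short.tau / long.tau - 1) < 0.05

    def test_estimator_unbiased_across_seeds(self, washout_protocol):
        """Mean fitted rate over 50 noisy synthetic decays lies within one
        standard error of the generating rate."""
        rates = []
        for seed in range(50):
            t, y = pure_exponential_trace(8.0, 0.08, 0.0, t_end=65.0,
                                          noise_sd=0.005, seed=seed,
                                          t_start=23.0)
            tr = trace_from_values(t, y, washout_protocol)
            rates.append(fit_deactivation(tr, 23.0, 42.0).rate)
        rates = np.array(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - 1 / 8.0) <= se

    def test_fit_window_must_lie_inside_trace(self, washout_protocol):
        t = np.linspace(0, 140, 500)
        tr = trace_from_values(t, np.exp(-t / 5), washout_protocol)
        with pytest.raises(ValueError, match="outside trace"):
            fit_deactivation(tr, washout_start=100.0, window_s=104.0)


class TestFitActivation:
    def make_rise(self, tau, noise_sd=0.0, seed=None, app_s=30.0):
        proto = make_protocol("activation", "L", [1e-8], pre_s=10.0,
                              app_s=app_s, tail_s=1.0)
        t = np.arange(int(proto.total_duration * 156)) / 156.0
        y = np.where(t < 10.0, 0.0, 0.5 * (1 - np.exp(-(t - 10.0) / tau)))
        if noise_sd:
            y = y + np.random.default_rng(seed).normal(0, noise_sd, len(t))
        return trace_from_values(t, y, proto)

    @pytest.mark.parametrize("rise_fraction", [0.5, 0.8, 0.95])
    def test_noise_free_rise_tau_independent_of_window(self, rise_fraction):
        tr = self.make_rise(tau=2.0)
        fit = fit_activation(tr, app_start=10.0, rise_fraction=rise_fraction)
        assert fit.tau == pytest.approx(2.0, rel=5e-3)

    def test_kobs_matches_kon_c_plus_koff(self, fast_noise_free, da_wt):
        """k_obs from a simulated 10 nM application is within 10% of
        k_on*c + k_off = 1.167/s for the reference dopamine kinetics."""
        proto = make_protocol("activation", "DA", [10e-9], pre_s=10.0,
                              app_s=60.0, tail_s=5.0)
        trace = simulate_trace(da_wt, fast_noise_free, proto, seed=None)
        trace = subtract_basal(trace, (1.0, 9.0))
        fit = fit_activation(trace, app_start=10.0)
        expected = da_wt.k_on * 10e-9 + da_wt.k_off
        assert fit.rate == pytest.approx(expected, rel=0.10)

    def test_rise_fraction_controls_window_end(self):
        """The fit window stops once the requested fraction of the rise is
        covered: 80% excludes the plateau, 99.9% runs almost to the end of
        the application, and both windows agree on tau within noise."""
        tr = self.make_rise(tau=2.0, noise_sd=0.02, seed=1, app_s=60.0)
        fit_80 = fit_activation(tr, 10.0, rise_fraction=0.8)
        fit_999 = fit_activation(tr, 10.0, rise_fraction=0.999)
        assert fit_80.window[1] < fit_999.window[1]
        assert fit_80.window[1] - 10.0 < 6.0      # ~1.6 tau, plateau excluded
        assert fit_80.tau == pytest.approx(fit_999.tau, rel=0.15)

    def test_plateau_not_reached_is_an_error(self, fast_noise_free):
        slow = LigandKinetics("slow", k_on=1e5, k_off=0.01)
        proto = make_protocol("activation", "slow", [slow.true_kd / 10],
                              app_s=20.0)
        trace = simulate_trace(slow, fast_noise_free, proto, seed=None)
        trace = subtract_basal(trace, (1.0, 9.0))
        with pytest.raises(ValueError, match="longer"):
            fit_activation(trace, app_start=10.0)


class TestPeakNormalizeAndAverage:
    def make_noisy(self, seed, washout_protocol):
        t = np.arange(int(140 * 156)) / 156.0
        y = np.where(t < 10, 0.0, 0.4 * np.exp(-np.maximum(t - 23, 0) / 20.0))
        y[(t >= 10) & (t < 23)] = 0.4
        y = y + np.random.default_rng(seed).normal(0, 0.01, len(t))
        return trace_from_values(t, y, washout_protocol)

    def test_single_trace_is_scaled_to_unit_peak(self, washout_protocol):
        tr = self.make_noisy(0, washout_protocol)
        avg = peak_normalize_and_average([tr], align_time=23.0)
        assert np.max(avg.evoked) == pytest.approx(1.0)
        assert avg.time[0] == pytest.approx(-23.0)

    def test_identical_traces_average_to_one_of_them(self, washout_protocol):
        tr = self.make_noisy(1, washout_protocol)
        avg = peak_normalize_and_average([tr, tr, tr])
        np.testing.assert_allclose(avg.evoked,
                                   tr.evoked / np.max(tr.evoked), rtol=1e-12)

    def test_averaging_reduces_noise_by_sqrt_n(self, washout_protocol):
        traces = [self.make_noisy(s, washout_protocol) for s in range(10)]
        avg = peak_normalize_and_average(traces, align_time=23.0)
        single = traces[0]
        # compare residual SD around the common decay in the washout tail
        sel = (single.time >= 40) & (single.time <= 100)
        sel_avg = (avg.time >= 40 - 23) & (avg.time <= 100 - 23)
        ref = 0.4 * np.exp(-(single.time[sel] - 23) / 20.0) / 0.4
        sd_single = np.std(single.evoked[sel] / 0.4 - ref)
        sd_avg = np.std(avg.evoked[sel_avg] - ref)
        assert 2.2 < sd_single / sd_avg < 4.5

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            peak_normalize_and_average([])


class TestQC:
    def test_low_basal_passes(self, fast_params, da_wt):
        proto = make_protocol("washout", "DA", [10e-9], tail_s=20.0)
        trace = simulate_trace(da_wt, fast_params, proto, seed=0)
        assert qc_trace(trace).passed

    def test_high_basal_fails_with_reason(self, fast_params, da_wt):
        proto = make_protocol("washout", "DA", [10e-9], tail_s=20.0)
        params = fast_params.replace(i_basal=0.6)
        trace = simulate_trace(da_wt, params, proto, seed=0)
        result = qc_trace(trace)
        assert not result.passed
        assert any("basal current exceeds limit" in r for r in result.reasons)

    def test_nan_sample_fails(self, fast_params, da_wt):
        proto = make_protocol("washout", "DA", [10e-9], tail_s=20.0)
        trace = simulate_trace(da_wt, fast_params, proto, seed=0)
        bad = trace.current.copy()
        bad[100] = np.nan
        result = qc_trace(trace.with_current(bad))
        assert not result.passed

    def test_qc_result_invariant(self):
        with pytest.raises(ValueError):
            QCResult(passed=True, reasons=("something",))
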