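"""Tests of evoked field-potential component analysis and I-O metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hiquant.ephys import (
    ComponentWindows,
    FieldTrace,
    IOCurve,
    build_io_curve,
    hltp_contrast,
    io_auc,
    measure_components,
    paired_pulse_facilitation,
)
from hiquant.synthetic import EphysSpec, make_fepsp_sweep, make_io_series, make_paired_pulse


def flat_trace(value=0.0, length_ms=60.0, fs=25.0, stims=(10.0,), current=100.0):
    n = int(length_ms * fs)
    t = np.arange(n) / fs
    return FieldTrace(
        time_ms=t,
        voltage_mv=np.full(n, value),
        sampling_rate=fs,
        stim_times_ms=stims,
        stim_current_ua=current,
    )


def trace_with_trough(trough_mv=-0.8, latency_ms=5.0, stim=10.0, width=0.4):
    base = flat_trace(stims=(stim,))
    v = base.voltage_mv + trough_mv * np.exp(
        -0.5 * ((base.time_ms - (stim + latency_ms)) / width) ** 2
    )
    return FieldTrace(base.time_ms, v, base.sampling_rate, (stim,), 100.0)


class TestMeasureComponents:
    def test_flat_trace_has_zero_amplitudes(self):
        m = measure_components(flat_trace())
        assert m.vb_amp_mv == m.fp1_amp_mv == m.fp2_amp_mv == 0.0
        assert np.isnan(m.fp1_latency_ms)

    def test_constructed_trough_amplitude_and_latency(self):
        m = measure_components(trace_with_trough(-0.8, 5.0))
        assert m.fp1_amp_mv == pytest.approx(0.8, abs=1e-6)
        assert m.fp1_latency_ms == pytest.approx(5.0, abs=1.0 / 25.0)

    def test_window_beyond_trace_rejected(self):
        short = flat_trace(length_ms=18.0)
        with pytest.raises(ValueError, match="beyond"):
            measure_components(short, windows=ComponentWindows(fp2=(6.0, 12.0)))

    def test_noiseless_latencies_recovered_within_one_sample(self):
        spec = EphysSpec(noise_sd_mv=0.0)
        m = measure_components(make_fepsp_sweep(spec, 650.0))
        one_sample = 1.0 / spec.sampling_rate
        assert m.fp1_latency_ms == pytest.approx(spec.fp1_latency_ms, abs=one_sample)
        assert m.fp2_latency_ms == pytest.approx(spec.fp2_latency_ms, abs=one_sample)

    def test_noisy_batch_mean_amplitude_matches_generator(self):
        spec = EphysSpec(noise_sd_mv=0.05)
        amps = []
        for seed in range(100):
            s = EphysSpec(noise_sd_mv=0.05, seed=seed)
            amps.append(measure_components(make_fepsp_sweep(s, 650.0)).fp1_amp_mv)
        noiseless = measure_components(
            make_fepsp_sweep(EphysSpec(noise_sd_mv=0.0), 650.0)
        ).fp1_amp_mv
        sem = np.std(amps, ddof=1) / np.sqrt(len(amps))
        # the trough of max(noise) biases upward by ~noise_sd; allow 3 SEM + that
        assert abs(np.mean(amps) - noiseless) <= 3 * sem + 0.05

    @settings(derandomize=True, max_examples=20)
    @given(offset=st.floats(min_value=-5.0, max_value=5.0))
    def test_baseline_invariance(self, offset):
        spec = EphysSpec(noise_sd_mv=0.0)
        trace = make_fepsp_sweep(spec, 300.0)
        shifted = FieldTrace(
            trace.time_ms,
            trace.voltage_mv + offset,
            trace.sampling_rate,
            trace.stim_times_ms,
            trace.stim_current_ua,
        )
        a = measure_components(trace)
        b = measure_components(shifted)
        assert b.fp1_amp_mv == pytest.approx(a.fp1_amp_mv, abs=1e-9)
        assert b.fp1_latency_ms == pytest.approx(a.fp1_latency_ms, abs=1e-9)

    @settings(derandomize=True, max_examples=20)
    @given(c=st.floats(min_value=0.1, max_value=10.0))
    def test_amplitude_scaling_leaves_ppf_unchanged(self, c):
        spec = EphysSpec(noise_sd_mv=0.0, facilitation_factor=1.4)
        trace = make_paired_pulse(spec)
        scaled = FieldTrace(
            trace.time_ms,
            trace.voltage_mv * c,
            trace.sampling_rate,
            trace.stim_times_ms,
            trace.stim_current_ua,
        )
        a = paired_pulse_facilitation(trace)
        b = paired_pulse_facilitation(scaled)
        assert b.first_amp_mv == pytest.approx(c * a.first_amp_mv, rel=1e-9)
        assert b.ppf_percent == pytest.approx(a.ppf_percent, abs=1e-6)


class TestIOCurve:
    def test_14_point_series_yields_14_curve_points(self, quiet_ephys_spec):
        curve = build_io_curve(make_io_series(quiet_ephys_spec))
        assert curve.currents_ua.size == 14

    def test_constant_one_mv_curve_auc_is_650(self):
        currents = np.arange(0.0, 651.0, 50.0)
        curve = IOCurve(currents, np.ones(14), np.ones(14))
        assert io_auc(curve, "fp1") == pytest.approx(650.0)

    def test_linear_curve_auc_is_325(self):
        currents = np.arange(0.0, 651.0, 50.0)
        curve = IOCurve(currents, currents / 650.0, currents / 650.0)
        assert io_auc(curve, "fp1") == pytest.approx(325.0)

    def test_sigmoid_auc_matches_closed_form_trapezoid(self, quiet_ephys_spec):
        spec = quiet_ephys_spec
        curve = build_io_curve(make_io_series(spec))
        currents = curve.currents_ua
        amps = spec.fp1_amp_mv / (
            1.0 + np.exp(-spec.io_slope * (currents - spec.io_half_current_ua))
        )
        expected = float(
            np.sum((amps[1:] + amps[:-1]) / 2.0 * np.diff(currents))
        )
        assert curve.auc_fp1 == pytest.approx(expected, rel=1e-9)

    def test_auc_linearity(self):
        currents = np.arange(0.0, 651.0, 50.0)
        a = IOCurve(currents, np.linspace(0, 1, 14), np.zeros(14))
        b = IOCurve(currents, np.linspace(1, 0, 14), np.zeros(14))
        summed = IOCurve(currents, a.fp1_amps_mv + b.fp1_amps_mv, np.zeros(14))
        assert io_auc(summed, "fp1") == pytest.approx(io_auc(a, "fp1") + io_auc(b, "fp1"))

    def test_duplicate_currents_rejected(self, quiet_ephys_spec):
        traces = make_io_series(quiet_ephys_spec, (0.0, 100.0, 200.0))
        traces.append(traces[-1])
        with pytest.raises(ValueError, match="duplicate"):
            build_io_curve(traces)


class TestPPF:
    def test_fifty_percent_facilitation(self):
        spec = EphysSpec(noise_sd_mv=0.0, facilitation_factor=1.5)
        r = paired_pulse_facilitation(make_paired_pulse(spec))
        assert r.ppf_percent == pytest.approx(50.0, abs=1e-6)

    def test_identical_responses_give_zero_percent(self):
        spec = EphysSpec(noise_sd_mv=0.0, facilitation_factor=1.0)
        r = paired_pulse_facilitation(make_paired_pulse(spec))
        assert r.ppf_percent == pytest.approx(0.0, abs=1e-6)

    def test_thirty_percent_facilitation_exact(self):
        spec = EphysSpec(noise_sd_mv=0.0, facilitation_factor=1.3)
        r = paired_pulse_facilitation(make_paired_pulse(spec))
        assert r.ppf_percent == pytest.approx(30.0, abs=1e-6)

    def test_absent_first_response_reports_missing_not_error(self):
        trace = flat_trace(length_ms=100.0, stims=(10.0, 85.0))
        r = paired_pulse_facilitation(trace)
        assert np.isnan(r.ppf_percent)
        assert "undefined" in r.note

    def test_single_stimulus_sweep_rejected(self):
        with pytest.raises(ValueError, match="2 stimulus"):
            paired_pulse_facilitation(flat_trace())


class TestBlockadeConsistency:
    def test_cnqx_and_ttx_flags_propagate_to_measurements(self):
        cnqx = measure_components(make_fepsp_sweep(EphysSpec(cnqx=True, noise_sd_mv=0.0), 650.0))
        assert cnqx.fp1_amp_mv == 0.0 and cnqx.fp2_amp_mv == 0.0 and cnqx.vb_amp_mv > 0
        ttx = measure_components(make_fepsp_sweep(EphysSpec(ttx=True, noise_sd_mv=0.0), 650.0))
        assert ttx.vb_amp_mv == ttx.fp1_amp_mv == ttx.fp2_amp_mv == 0.0


class TestHLTPContrast:
    def test_identical_sides_give_unit_ratio(self, quiet_ephys_spec):
        curve = build_io_curve(make_io_series(quiet_ephys_spec))
        r = hltp_contrast([curve], [curve])
        assert r.auc_ratio == pytest.approx(1.0)

    def test_noiseless_potentiation_ratio_is_exact(self):
        base = build_io_curve(make_io_series(EphysSpec(noise_sd_mv=0.0)))
        pot = build_io_curve(
            make_io_series(EphysSpec(noise_sd_mv=0.0, potentiation_factor=1.5))
        )
        r = hltp_contrast([pot], [base])
        assert r.auc_ratio == pytest.approx(1.5, rel=1e-3)

    def test_noisy_cohort_ratio_within_monte_carlo_ci(self):
        border, contra = [], []
        for k in range(8):
            border.append(
                build_io_curve(make_io_series(EphysSpec(potentiation_factor=1.5, seed=500 + k)))
            )
            contra.append(
                build_io_curve(make_io_series(EphysSpec(potentiation_factor=1.0, seed=600 + k)))
            )
        r = hltp_contrast(border, contra)
        se = np.sqrt(
            (r.sd_border_auc / np.sqrt(8)) ** 2 + (1.5 * r.sd_contralateral_auc / np.sqrt(8)) ** 2
        ) / r.mean_contralateral_auc
        assert abs(r.auc_ratio - 1.5) <= max(3 * se, 0.02)

    def test_empty_side_rejected(self, quiet_ephys_spec):
        curve = build_io_curve(make_io_series(quiet_ephys_spec))
        with pytest.raises(ValueError, match="per side"):
            hltp_contrast([], [curve])
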