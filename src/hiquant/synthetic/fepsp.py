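"""Synthetic evoked field-potential sweeps.

Each sweep holds a truncated biphasic stimulus artifact at the stimulus
time, then three negative Gaussian deflections: the presynaptic volley
burst (VB), the monosynaptic fEPSP (FP1, trough at 4–6 ms latency) and
the polysynaptic fEPSP (FP2, over 6–10 ms).  Component amplitudes follow
a saturating (logistic) function of stimulus current,

    amp(I) = amp_max / (1 + exp(-io_slope * (I - io_half_current))),

with the FP1/FP2 saturation amplitude additionally scaled by
``potentiation_factor`` (>1 emulates post-hypoxic LTP).  Pharmacological
flags mirror the blockade dissection: ``cnqx`` (AMPA-receptor block)
zeroes FP1 and FP2 only, ``ttx`` (axonal conduction block) zeroes VB,
FP1 and FP2.  Gaussian recording noise is added last.

Exact pulse shapes are a free modelling choice — downstream analysis
measures only amplitudes and trough latencies — so smooth unimodal
negative Gaussians keep the generator analytically invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..ephys import FieldTrace

__all__ = ["EphysSpec", "sigmoid_amplitude", "make_fepsp_sweep", "make_io_series", "make_paired_pulse"]

#: the published stimulus grid: 0 to 650 µA in 50 µA increments (14 levels)
DEFAULT_CURRENTS_UA = tuple(float(c) for c in range(0, 651, 50))


@dataclass
class EphysSpec:
    """Parameters of the synthetic sweep generator.

    Latencies are ms from the stimulus to the component trough and must
    respect the component windows (FP1 in [4, 6], FP2 in (6, 10]);
    amplitudes are saturation values in mV of the negative deflections.
    The I-O sigmoid parameters and absolute amplitudes are free
    parameters of the simulator (no published values exist for them).
    """

    sampling_rate: float = 25.0        # samples per ms (25 kHz)
    sweep_length_ms: float = 120.0
    stim_time_ms: float = 10.0
    vb_latency_ms: float = 2.5
    fp1_latency_ms: float = 5.0
    fp2_latency_ms: float = 8.0
    vb_amp_mv: float = 0.3
    fp1_amp_mv: float = 1.0
    fp2_amp_mv: float = 0.6
    vb_width_ms: float = 0.3
    fp1_width_ms: float = 0.5
    fp2_width_ms: float = 0.8
    artifact_amp_mv: float = 4.0
    io_half_current_ua: float = 200.0
    io_slope: float = 0.015            # per µA
    potentiation_factor: float = 1.0
    facilitation_factor: float = 1.3
    amplitude_cv: float = 0.12         # slice-to-slice responsiveness spread
    cnqx: bool = False
    ttx: bool = False
    noise_sd_mv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 4.0 <= self.fp1_latency_ms <= 6.0:
            raise ValueError("fp1_latency_ms must lie in [4, 6] ms")
        if not 6.0 < self.fp2_latency_ms <= 10.0:
            raise ValueError("fp2_latency_ms must lie in (6, 10] ms")
        if not 1.0 <= self.vb_latency_ms <= 4.0:
            raise ValueError("vb_latency_ms must lie in [1, 4] ms")
        if self.facilitation_factor <= 0:
            raise ValueError("facilitation_factor must be positive")
        if self.potentiation_factor <= 0:
            raise ValueError("potentiation_factor must be positive")
        min_width = min(self.vb_width_ms, self.fp1_width_ms, self.fp2_width_ms)
        if self.sampling_rate * min_width < 5:
            raise ValueError("sampling_rate too low: each component must span >= 5 samples")
        if self.noise_sd_mv < 0 or self.sweep_length_ms <= 0 or self.stim_time_ms < 5.0:
            raise ValueError("need noise_sd_mv >= 0, positive sweep, stim_time >= 5 ms baseline")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.sweep_length_ms * self.sampling_rate))


def sigmoid_amplitude(amp_max: float, current_ua: float, half_ua: float, slope: float) -> float:
    """Saturating input-output amplitude: amp_max / (1 + exp(-slope*(I-half)))."""
    return amp_max / (1.0 + np.exp(-slope * (current_ua - half_ua)))


def _slice_scale(spec: EphysSpec, rng: np.random.Generator) -> float:
    """One multiplicative responsiveness factor per slice preparation.

    Lognormal with unit mean and coefficient of variation
    ``amplitude_cv``; applied jointly to VB/FP1/FP2 so a strong slice is
    strong across components.
    """
    if spec.amplitude_cv <= 0:
        return 1.0
    s = np.sqrt(np.log1p(spec.amplitude_cv**2))
    return float(np.exp(rng.normal(-0.5 * s * s, s)))


def _gaussian(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian pulse with compact support (zero beyond 3 widths).

    Truncation keeps every component strictly inside its own latency
    window — tails cannot contaminate the pre-stimulus baseline or a
    neighbouring component's window, so noiseless measurements are exact.
    """
    g = np.exp(-0.5 * ((t - center) / width) ** 2)
    g[np.abs(t - center) > 3.0 * width] = 0.0
    return g


def _response(
    spec: EphysSpec,
    t: np.ndarray,
    stim: float,
    current: float,
    facilitation: float,
    slice_scale: float,
) -> np.ndarray:
    """Noiseless response to one stimulus (artifact + components)."""
    v = np.zeros_like(t)
    # truncated biphasic artifact confined inside the 0.5 ms blanking span
    v += spec.artifact_amp_mv * _gaussian(t, stim + 0.12, 0.04)
    v -= spec.artifact_amp_mv * _gaussian(t, stim + 0.26, 0.04)
    sig = slice_scale * sigmoid_amplitude(1.0, current, spec.io_half_current_ua, spec.io_slope)
    if not spec.ttx:
        v -= spec.vb_amp_mv * sig * _gaussian(t, stim + spec.vb_latency_ms, spec.vb_width_ms)
        if not spec.cnqx:
            pot = spec.potentiation_factor * facilitation
            v -= spec.fp1_amp_mv * pot * sig * _gaussian(t, stim + spec.fp1_latency_ms, spec.fp1_width_ms)
            v -= spec.fp2_amp_mv * pot * sig * _gaussian(t, stim + spec.fp2_latency_ms, spec.fp2_width_ms)
    return v


def _finalize(spec: EphysSpec, t: np.ndarray, v: np.ndarray, stims: tuple[float, ...],
              current: float, rng: np.random.Generator) -> FieldTrace:
    if spec.noise_sd_mv > 0:
        v = v + rng.normal(0.0, spec.noise_sd_mv, v.shape)
    return FieldTrace(
        time_ms=t,
        voltage_mv=v,
        sampling_rate=spec.sampling_rate,
        stim_times_ms=stims,
        stim_current_ua=current,
    )


def make_fepsp_sweep(
    spec: EphysSpec,
    stim_current_ua: float,
    rng: np.random.Generator | None = None,
    response_scale: float | None = None,
) -> FieldTrace:
    """One single-stimulus sweep at the given current.

    ``rng`` lets a series of sweeps share one seeded stream; when omitted,
    a fresh generator is seeded from ``spec.seed``.  ``response_scale``
    fixes the slice responsiveness factor (a series shares one draw);
    when omitted it is drawn here.
    """
    if stim_current_ua < 0:
        raise ValueError("stimulus current must be non-negative")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if response_scale is None:
        response_scale = _slice_scale(spec, rng)
    t = np.arange(spec.n_samples) / spec.sampling_rate
    v = _response(spec, t, spec.stim_time_ms, stim_current_ua,
                  facilitation=1.0, slice_scale=response_scale)
    return _finalize(spec, t, v, (spec.stim_time_ms,), stim_current_ua, rng)


def make_io_series(
    spec: EphysSpec, currents_ua: tuple[float, ...] | None = None
) -> list[FieldTrace]:
    """One sweep per stimulus current, sharing a single seeded noise stream.

    Defaults to the published grid 0, 50, ..., 650 µA; duplicate or
    negative currents are rejected.
    """
    currents = DEFAULT_CURRENTS_UA if currents_ua is None else tuple(float(c) for c in currents_ua)
    if len(currents) == 0:
        raise ValueError("currents must be non-empty")
    if any(c < 0 for c in currents):
        raise ValueError("currents must be non-negative")
    if len(set(currents)) != len(currents):
        raise ValueError("duplicate stimulus currents")
    rng = np.random.default_rng(spec.seed)
    scale = _slice_scale(spec, rng)  # one slice preparation per series
    return [make_fepsp_sweep(spec, c, rng=rng, response_scale=scale) for c in currents]


def make_paired_pulse(
    spec: EphysSpec, stim_current_ua: float = 50.0, interval_ms: float = 75.0
) -> FieldTrace:
    """A two-stimulus sweep for paired-pulse facilitation.

    The second response's FP1/FP2 amplitudes are the first's times
    ``facilitation_factor`` (the presynaptic facilitation the metric
    recovers exactly in the noiseless case).  The inter-stimulus interval
    must leave the two responses non-overlapping, and the second
    response's measurement window must fit inside the sweep.
    """
    if stim_current_ua < 0:
        raise ValueError("stimulus current must be non-negative")
    response_span = spec.fp2_latency_ms + 4.0 * spec.fp2_width_ms
    if interval_ms <= response_span:
        raise ValueError(
            f"interval {interval_ms} ms overlaps the first response (span {response_span:.1f} ms)"
        )
    second = spec.stim_time_ms + interval_ms
    if second + 10.0 > spec.sweep_length_ms:
        raise ValueError("sweep too short for the second response window")
    rng = np.random.default_rng(spec.seed)
    scale = _slice_scale(spec, rng)
    t = np.arange(spec.n_samples) / spec.sampling_rate
    v = _response(spec, t, spec.stim_time_ms, stim_current_ua,
                  facilitation=1.0, slice_scale=scale)
    v += _response(spec, t, second, stim_current_ua,
                   facilitation=spec.facilitation_factor, slice_scale=scale)
    return _finalize(spec, t, v, (spec.stim_time_ms, second), stim_current_ua, rng)
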