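"""Evoked field-potential metrics.

Quantifies extracellular field responses evoked by cortical stimulation:
the presynaptic volley burst (VB, TTX-sensitive), the monosynaptic fEPSP
(FP1, 4–6 ms latency) and the polysynaptic fEPSP (FP2, over 6–10 ms),
all negative deflections measured baseline-to-trough within fixed
post-stimulus latency windows.  On top of per-sweep component measures it
builds input-output (I-O) curves over a stimulus-current series, summarises
them by trapezoidal area under the curve (a scalar index of synaptic
strength and excitability), and computes paired-pulse facilitation (PPF),
the percentage increase of the second response over the first for a
closely spaced stimulus pair.

Conventions: samples within 0.5 ms after each stimulus are blanked to the
baseline value before any measurement (the stimulus artifact is truncated),
the baseline is the mean over the 5 ms preceding the stimulus, and window
bounds are closed except FP2's lower edge, which is open (latency strictly
over 6 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FieldTrace",
    "ComponentWindows",
    "ComponentMeasure",
    "IOCurve",
    "PPFResult",
    "HLTPContrast",
    "measure_components",
    "build_io_curve",
    "io_auc",
    "paired_pulse_facilitation",
    "hltp_contrast",
]

BLANK_MS = 0.5          # artifact blanking span after each stimulus
BASELINE_MS = 5.0       # pre-stimulus baseline span


@dataclass
class FieldTrace:
    """One evoked sweep: voltage vs time with stimulus metadata."""

    time_ms: np.ndarray
    voltage_mv: np.ndarray
    sampling_rate: float            # samples per ms
    stim_times_ms: tuple[float, ...]
    stim_current_ua: float

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        if self.time_ms.shape != self.voltage_mv.shape or self.time_ms.ndim != 1:
            raise ValueError("time and voltage must be matching 1-D arrays")
        if self.time_ms.size < 2:
            raise ValueError("trace too short")
        dt = np.diff(self.time_ms)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace must be uniformly sampled")
        if not np.all(np.isfinite(self.voltage_mv)):
            raise ValueError("voltage contains non-finite samples")
        self.stim_times_ms = tuple(float(t) for t in self.stim_times_ms)
        if not self.stim_times_ms:
            raise ValueError("at least one stimulus time required")
        t0, t1 = self.time_ms[0], self.time_ms[-1]
        if not all(t0 <= s <= t1 for s in self.stim_times_ms):
            raise ValueError("stimulus times must lie within the trace")
        self.stim_current_ua = float(self.stim_current_ua)


@dataclass(frozen=True)
class ComponentWindows:
    """Post-stimulus latency windows in ms: VB [1,4], FP1 [4,6], FP2 (6,10]."""

    vb: tuple[float, float] = (1.0, 4.0)
    fp1: tuple[float, float] = (4.0, 6.0)
    fp2: tuple[float, float] = (6.0, 10.0)


@dataclass
class ComponentMeasure:
    """Amplitudes (mV, >=0; 0 = absent) and trough latencies of one response."""

    vb_amp_mv: float
    fp1_amp_mv: float
    fp2_amp_mv: float
    fp1_latency_ms: float
    fp2_latency_ms: float
    baseline_mv: float


@dataclass
class IOCurve:
    """Input-output curve: component amplitude vs stimulus current."""

    currents_ua: np.ndarray
    fp1_amps_mv: np.ndarray
    fp2_amps_mv: np.ndarray
    auc_fp1: float = 0.0
    auc_fp2: float = 0.0

    def __post_init__(self) -> None:
        self.currents_ua = np.asarray(self.currents_ua, dtype=float)
        self.fp1_amps_mv = np.asarray(self.fp1_amps_mv, dtype=float)
        self.fp2_amps_mv = np.asarray(self.fp2_amps_mv, dtype=float)
        if not (self.currents_ua.size == self.fp1_amps_mv.size == self.fp2_amps_mv.size):
            raise ValueError("currents and amplitudes must align")
        if np.any(np.diff(self.currents_ua) <= 0):
            raise ValueError("currents must be strictly increasing")


@dataclass
class PPFResult:
    """Paired-pulse facilitation: 100*(A2-A1)/A1 on the FP1 amplitudes."""

    first_amp_mv: float
    second_amp_mv: float
    ppf_percent: float      # NaN when the first response is absent
    note: str = ""


@dataclass
class HLTPContrast:
    """Descriptive border-vs-contralateral AUC contrast (potentiation index)."""

    mean_border_auc: float
    mean_contralateral_auc: float
    auc_ratio: float
    sd_border_auc: float
    sd_contralateral_auc: float
    n_border: int
    n_contralateral: int


def _window_slice(
    trace: FieldTrace, stim: float, window: tuple[float, float], open_left: bool
) -> np.ndarray:
    lo, hi = stim + window[0], stim + window[1]
    if hi > trace.time_ms[-1] + 1e-9:
        raise ValueError(f"window {window} extends beyond the trace for stimulus at {stim} ms")
    if open_left:
        sel = (trace.time_ms > lo) & (trace.time_ms <= hi)
    else:
        sel = (trace.time_ms >= lo) & (trace.time_ms <= hi)
    return np.flatnonzero(sel)


def measure_components(
    trace: FieldTrace,
    stim_index: int = 1,
    windows: ComponentWindows | None = None,
    amplitude_mode: str = "baseline_trough",
    blank_ms: float = BLANK_MS,
) -> ComponentMeasure:
    """Measure VB/FP1/FP2 of the response to one stimulus of a sweep.

    Parameters
    ----------
    trace : FieldTrace
    stim_index : {1, 2}
        Which stimulus of the sweep to analyse (paired-pulse sweeps carry
        two).
    windows : ComponentWindows, optional
        Post-stimulus latency windows; the defaults put VB at 1–4 ms,
        FP1 at 4–6 ms and FP2 at (6, 10] ms.
    amplitude_mode : {'baseline_trough', 'peak_to_peak'}
        'baseline_trough' (default) takes baseline minus window minimum,
        clamped at 0; 'peak_to_peak' takes window maximum minus minimum.
    blank_ms : float
        Artifact span after every stimulus replaced by the baseline value
        before measuring.

    Returns
    -------
    ComponentMeasure
        Latencies are NaN for components whose amplitude clamps to 0.
    """
    windows = windows or ComponentWindows()
    if stim_index not in (1, 2):
        raise ValueError("stim_index must be 1 or 2")
    if stim_index > len(trace.stim_times_ms):
        raise ValueError(f"trace has no stimulus #{stim_index}")
    if windows.vb[0] < blank_ms:
        raise ValueError("component windows must start after the artifact blanking span")
    stim = trace.stim_times_ms[stim_index - 1]

    pre = (trace.time_ms >= stim - BASELINE_MS) & (trace.time_ms < stim)
    if not np.any(pre):
        raise ValueError("no pre-stimulus samples available for the baseline")
    baseline = float(trace.voltage_mv[pre].mean())

    v = trace.voltage_mv.copy()
    for s in trace.stim_times_ms:
        blank = (trace.time_ms >= s) & (trace.time_ms <= s + blank_ms)
        v[blank] = baseline

    def amp_latency(window: tuple[float, float], open_left: bool) -> tuple[float, float]:
        idx = _window_slice(trace, stim, window, open_left)
        seg = v[idx]
        if amplitude_mode == "peak_to_peak":
            amp = float(seg.max() - seg.min())
        elif amplitude_mode == "baseline_trough":
            amp = max(0.0, baseline - float(seg.min()))
        else:
            raise ValueError(f"unknown amplitude_mode {amplitude_mode!r}")
        if amp == 0.0:
            return 0.0, float("nan")
        latency = float(trace.time_ms[idx[np.argmin(seg)]] - stim)
        return amp, latency

    vb_amp, _ = amp_latency(windows.vb, open_left=False)
    fp1_amp, fp1_lat = amp_latency(windows.fp1, open_left=False)
    fp2_amp, fp2_lat = amp_latency(windows.fp2, open_left=True)
    return ComponentMeasure(
        vb_amp_mv=vb_amp,
        fp1_amp_mv=fp1_amp,
        fp2_amp_mv=fp2_amp,
        fp1_latency_ms=fp1_lat,
        fp2_latency_ms=fp2_lat,
        baseline_mv=baseline,
    )


def build_io_curve(
    traces: list[FieldTrace], windows: ComponentWindows | None = None
) -> IOCurve:
    """Assemble an I-O curve from single-stimulus sweeps at distinct currents.

    Sweeps are sorted by stimulus current; FP1/FP2 amplitudes come from
    :func:`measure_components` and both AUCs are attached via
    :func:`io_auc`.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 sweeps at distinct currents")
    currents = np.array([t.stim_current_ua for t in traces], dtype=float)
    if np.unique(currents).size != currents.size:
        raise ValueError("duplicate stimulus currents in the series")
    order = np.argsort(currents)
    fp1 = np.empty(currents.size)
    fp2 = np.empty(currents.size)
    for k, i in enumerate(order):
        m = measure_components(traces[i], windows=windows)
        fp1[k] = m.fp1_amp_mv
        fp2[k] = m.fp2_amp_mv
    curve = IOCurve(currents_ua=currents[order], fp1_amps_mv=fp1, fp2_amps_mv=fp2)
    curve.auc_fp1 = io_auc(curve, "fp1")
    curve.auc_fp2 = io_auc(curve, "fp2")
    return curve


def io_auc(curve: IOCurve, component: str = "fp1") -> float:
    """Trapezoidal area under an I-O curve, in mV·µA, over the recorded range."""
    if curve.currents_ua.size < 2:
        raise ValueError("AUC needs at least 2 curve points")
    if component == "fp1":
        amps = curve.fp1_amps_mv
    elif component == "fp2":
        amps = curve.fp2_amps_mv
    else:
        raise ValueError("component must be 'fp1' or 'fp2'")
    return float(np.trapezoid(amps, curve.currents_ua))


def paired_pulse_facilitation(
    trace: FieldTrace, windows: ComponentWindows | None = None
) -> PPFResult:
    """PPF of a two-stimulus sweep: 100*(A2-A1)/A1 on FP1 amplitudes.

    An absent first response (A1 = 0) makes the ratio undefined; the
    result then carries ``ppf_percent = NaN`` and a diagnostic note
    instead of raising.
    """
    if len(trace.stim_times_ms) != 2:
        raise ValueError("paired-pulse analysis needs exactly 2 stimulus times")
    first = measure_components(trace, stim_index=1, windows=windows)
    second = measure_components(trace, stim_index=2, windows=windows)
    a1, a2 = first.fp1_amp_mv, second.fp1_amp_mv
    if a1 == 0.0:
        return PPFResult(a1, a2, float("nan"), note="first response absent; PPF undefined")
    return PPFResult(a1, a2, 100.0 * (a2 - a1) / a1)


def hltp_contrast(
    border_curves: list[IOCurve],
    contralateral_curves: list[IOCurve],
    component: str = "fp1",
) -> HLTPContrast:
    """Border-site vs contralateral-site mean AUC and their ratio.

    The descriptive statistic behind the post-hypoxic potentiation
    readout: a ratio above 1 means stronger evoked responses at the
    lesion border than at the mirror-image contralateral site.
    """
    if not border_curves or not contralateral_curves:
        raise ValueError("need at least one I-O curve per side")
    b = np.array([io_auc(c, component) for c in border_curves])
    c = np.array([io_auc(c, component) for c in contralateral_curves])
    mean_b, mean_c = float(b.mean()), float(c.mean())
    if mean_c == 0.0:
        raise ValueError("contralateral mean AUC is zero; ratio undefined")
    return HLTPContrast(
        mean_border_auc=mean_b,
        mean_contralateral_auc=mean_c,
        auc_ratio=mean_b / mean_c,
        sd_border_auc=float(b.std(ddof=1)) if b.size > 1 else 0.0,
        sd_contralateral_auc=float(c.std(ddof=1)) if c.size > 1 else 0.0,
        n_border=int(b.size),
        n_contralateral=int(c.size),
    )
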