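"""Voxelwise T2 relaxometry from multi-echo spin-echo MRI.

Each voxel of a multi-echo acquisition (an MSME sequence yields one image
per echo time) is modelled as a mono-exponential transverse decay

    S(TE) = S0 * exp(-TE / T2)

with proton-density amplitude ``S0`` (signal units) and relaxation time
``T2`` (ms).  Two estimators are provided:

``loglinear``
    Ordinary least squares of ``ln S`` against ``TE``.  Exact on noiseless
    data, but biased when the magnitude (Rician) noise floor matters.
``nonlinear``
    Least squares on the exponential itself, initialized from the
    log-linear solution.  For a fixed decay rate ``r = 1/T2`` the optimal
    amplitude has the closed form ``S0 = (S.e)/(e.e)`` with
    ``e = exp(-r*TE)`` (variable projection), so the fit reduces to a 1-D
    minimization over the rate, solved by a bracketed golden-section
    search vectorized across voxels.

Fit failures (non-positive decay-rate estimate, non-positive intensities
under the log-linear model) are recorded in the ``valid`` mask rather than
raised, so a single degenerate voxel cannot abort a whole map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "MultiEchoVolume",
    "T2Map",
    "VoxelFit",
    "fit_t2_voxel",
    "fit_t2_map",
]

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class MultiEchoVolume:
    """A 4-D multi-echo signal grid with its echo times.

    Parameters
    ----------
    signal : ndarray, shape (rows, cols, slices, echoes)
        Non-negative magnitude intensities, arbitrary units.
    echo_times : ndarray, shape (echoes,)
        Echo times in ms, strictly increasing and positive; at least 3.
    voxel_size : tuple of float
        Voxel edge lengths in mm per axis.
    """

    signal: np.ndarray
    echo_times: np.ndarray
    voxel_size: tuple[float, float, float] = (0.12, 0.12, 0.5)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (rows, cols, slices, echoes)")
        if self.echo_times.ndim != 1 or self.echo_times.size != self.signal.shape[3]:
            raise ValueError("echo_times length must match the 4th signal axis")
        if self.echo_times.size < 3:
            raise ValueError("at least 3 echoes are required")
        if not (np.all(np.diff(self.echo_times) > 0) and self.echo_times[0] > 0):
            raise ValueError("echo_times must be strictly increasing and positive")
        if np.any(self.signal < 0):
            raise ValueError("magnitude signal must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class T2Map:
    """Voxelwise T2 (ms), amplitude, and fit-quality maps.

    ``r2`` is the coefficient of determination of the fit on the signal
    scale (1 for a perfect fit; can be negative for a fit worse than the
    mean).  ``valid`` marks voxels with a usable fit; all other maps are
    NaN where ``valid`` is false.
    """

    t2: np.ndarray
    s0: np.ndarray
    r2: np.ndarray
    valid: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.t2.shape == self.s0.shape == self.r2.shape == self.valid.shape):
            raise ValueError("map fields must share one 3-D grid")
        if self.t2.ndim != 3:
            raise ValueError("maps must be 3-D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


class VoxelFit(NamedTuple):
    s0: float
    t2_ms: float
    r2: float
    valid: bool


def _loglinear_fit(signals: np.ndarray, te: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of ln(signal) on TE for a (n_voxels, n_echoes) stack.

    Returns (s0, rate, valid); rate = 1/T2 in 1/ms.  Voxels with any
    non-positive intensity, or a non-positive rate estimate, are invalid.
    """
    positive = np.all(signals > 0, axis=1)
    safe = np.where(signals > 0, signals, 1.0)
    y = np.log(safe)
    x = te - te.mean()
    denom = float(np.sum(x * x))
    slope = (y * x).sum(axis=1) / denom
    intercept = y.mean(axis=1) - slope * np.mean(te)
    rate = -slope
    s0 = np.exp(intercept)
    valid = positive & (rate > 0) & np.isfinite(rate)
    return s0, rate, valid


def _projected_sse(signals: np.ndarray, te: np.ndarray, rate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SSE of the exponential model at given rates, S0 profiled out."""
    decay = np.exp(-rate[:, None] * te[None, :])
    denom = np.sum(decay * decay, axis=1)
    s0 = np.sum(signals * decay, axis=1) / denom
    resid = signals - s0[:, None] * decay
    return np.sum(resid * resid, axis=1), s0


def _golden_refine(
    signals: np.ndarray, te: np.ndarray, rate0: np.ndarray, n_iter: int = 90
) -> tuple[np.ndarray, np.ndarray]:
    """Golden-section minimization of the projected SSE over the decay rate.

    Brackets each voxel's rate in [rate0/3, 3*rate0]; 90 contractions shrink
    the bracket by ~1e-19 relative, i.e. to machine precision.
    """
    a = rate0 / 3.0
    b = rate0 * 3.0
    for _ in range(n_iter):
        span = b - a
        c = b - _INVPHI * span
        d = a + _INVPHI * span
        fc, _ = _projected_sse(signals, te, c)
        fd, _ = _projected_sse(signals, te, d)
        take_left = fc < fd
        b = np.where(take_left, d, b)
        a = np.where(take_left, a, c)
    rate = (a + b) / 2.0
    _, s0 = _projected_sse(signals, te, rate)
    return rate, s0


def _fit_stack(
    signals: np.ndarray, te: np.ndarray, method: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit a (n_voxels, n_echoes) stack; returns (s0, t2, r2, valid)."""
    if method not in ("loglinear", "nonlinear"):
        raise ValueError(f"unknown method {method!r}")
    s0, rate, valid = _loglinear_fit(signals, te)
    if method == "nonlinear" and np.any(valid):
        idx = np.flatnonzero(valid)
        rate_nl, s0_nl = _golden_refine(signals[idx], te, rate[idx])
        rate = rate.copy()
        s0 = s0.copy()
        rate[idx] = rate_nl
        s0[idx] = s0_nl
    t2 = np.full(rate.shape, np.nan)
    r2 = np.full(rate.shape, np.nan)
    if np.any(valid):
        idx = np.flatnonzero(valid)
        t2[idx] = 1.0 / rate[idx]
        pred = s0[idx, None] * np.exp(-rate[idx, None] * te[None, :])
        sse = np.sum((signals[idx] - pred) ** 2, axis=1)
        sst = np.sum((signals[idx] - signals[idx].mean(axis=1, keepdims=True)) ** 2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2[idx] = 1.0 - sse / sst
    s0 = np.where(valid, s0, np.nan)
    return s0, t2, r2, valid


def fit_t2_voxel(
    signal: np.ndarray, echo_times: np.ndarray, method: str = "nonlinear"
) -> VoxelFit:
    """Fit ``S(TE) = S0*exp(-TE/T2)`` to one voxel's echo train.

    Parameters
    ----------
    signal : array-like, shape (echoes,)
        Per-echo intensities.
    echo_times : array-like, shape (echoes,)
        Echo times, ms, strictly increasing.
    method : {'nonlinear', 'loglinear'}
        'nonlinear' refines the log-linear solution by least squares on
        the exponential; both agree exactly on noiseless data.

    Returns
    -------
    VoxelFit
        ``(s0, t2_ms, r2, valid)``.  ``valid`` is False (not an error)
        when the decay-rate estimate is non-positive or the intensities
        prevent a log-linear start.
    """
    signal = np.asarray(signal, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if signal.ndim != 1 or te.shape != signal.shape:
        raise ValueError("signal and echo_times must be 1-D and equally long")
    if signal.size < 3:
        raise ValueError("at least 3 echoes are required")
    if not (np.all(np.diff(te) > 0) and te[0] > 0):
        raise ValueError("echo_times must be strictly increasing and positive")
    s0, t2, r2, valid = _fit_stack(signal[None, :], te, method)
    return VoxelFit(float(s0[0]), float(t2[0]), float(r2[0]), bool(valid[0]))


def fit_t2_map(
    vol: MultiEchoVolume,
    brain_mask: np.ndarray | None = None,
    method: str = "nonlinear",
    omit_first_echo: bool = False,
) -> T2Map:
    """Voxelwise T2 fit over a multi-echo volume.

    Parameters
    ----------
    vol : MultiEchoVolume
    brain_mask : ndarray of bool, optional
        Voxels to fit; everything outside is marked invalid without a fit
        attempt.  Must match the spatial grid.
    method : {'nonlinear', 'loglinear'}
    omit_first_echo : bool
        Drop the first echo before fitting (a common multi-echo
        convention when the first echo is contaminated by stimulated
        echoes); off by default.

    Returns
    -------
    T2Map
    """
    shape = vol.grid_shape
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    else:
        brain_mask = np.asarray(brain_mask, dtype=bool)
        if brain_mask.shape != shape:
            raise ValueError("brain_mask grid does not match the volume")
    signal = vol.signal
    te = vol.echo_times
    if omit_first_echo:
        if te.size - 1 < 3:
            raise ValueError("omitting the first echo leaves fewer than 3 echoes")
        signal = signal[..., 1:]
        te = te[1:]

    t2 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    r2 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    idx = np.flatnonzero(brain_mask.ravel())
    if idx.size:
        stack = signal.reshape(-1, te.size)[idx]
        s0_v, t2_v, r2_v, valid_v = _fit_stack(stack, te, method)
        t2.ravel()[idx] = t2_v
        s0.ravel()[idx] = s0_v
        r2.ravel()[idx] = r2_v
        valid.ravel()[idx] = valid_v
    return T2Map(t2=t2, s0=s0, r2=r2, valid=valid, voxel_size=vol.voxel_size)
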