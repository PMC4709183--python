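"""Classical single-channel ERP features: averaging, peak picking, area,
and complex-Morlet time-frequency maps.

Peak picking and area operate on trial-averaged waveforms inside the P300
window (220-500 ms post-stimulus by default). The time-frequency map is
descriptive output: it is computed per trial with a complex Morlet wavelet
and averaged, but it is not part of the classification feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .containers import EpochSet
from .errors import DomainError

__all__ = [
    "P300Window",
    "ERPWaveform",
    "TimeFrequencyMap",
    "average_erp",
    "peak_picking",
    "area_feature",
    "cwt_morlet",
]


@dataclass(frozen=True)
class P300Window:
    """Post-stimulus window (ms) in which the P300 deflection is scored."""

    start_ms: float = 220.0
    end_ms: float = 500.0

    def __post_init__(self):
        if not 0 <= self.start_ms < self.end_ms:
            raise DomainError(
                f"invalid P300 window [{self.start_ms}, {self.end_ms}] ms"
            )


@dataclass
class ERPWaveform:
    """Trial- (and optionally channel-) averaged evoked waveform."""

    values: np.ndarray
    time_ms: np.ndarray
    n_trials_averaged: int
    condition: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != np.asarray(self.time_ms).shape:
            raise DomainError("waveform and time axis lengths differ")
        if self.n_trials_averaged < 1:
            raise DomainError("n_trials_averaged must be >= 1")


@dataclass
class TimeFrequencyMap:
    """Wavelet power (|coefficient|^2), frequencies x time."""

    power: np.ndarray
    freqs: np.ndarray
    time_ms: np.ndarray
    wavelet_params: tuple[float, float]  # (bandwidth fb, center frequency fc)


def average_erp(epochs: EpochSet, condition: str = "target",
                channels=None) -> ERPWaveform:
    """Mean waveform over trials of one condition, then over channels.

    ``condition`` is ``"target"`` or ``"nontarget"``; ``channels`` selects a
    subset by index (default: all).
    """
    if condition not in ("target", "nontarget"):
        raise DomainError(f"unknown condition {condition!r}")
    mask = epochs.is_target if condition == "target" else ~epochs.is_target
    n = int(mask.sum())
    if n == 0:
        raise DomainError(f"no trials with condition {condition!r}")
    sel = epochs.data[mask]
    if channels is not None:
        channels = list(channels)
        if not channels:
            raise DomainError("empty channel selection")
        sel = sel[:, channels, :]
    values = sel.mean(axis=0).mean(axis=0)
    return ERPWaveform(values, epochs.time_ms, n, condition)


def peak_picking(erp: ERPWaveform, window: P300Window = P300Window()) -> float:
    """Peak-to-peak P300 score.

    The highest point inside the P300 window minus the lowest point in the
    post-stimulus interval *before* the window, ``[0, start_ms)``. The
    pre-window minimum is nominally the preceding negativity; when it comes
    out positive a warning is emitted and the unconstrained minimum is used.
    """
    in_win = (erp.time_ms >= window.start_ms) & (erp.time_ms <= window.end_ms)
    pre = (erp.time_ms >= 0) & (erp.time_ms < window.start_ms)
    if not pre.any():
        raise DomainError("no samples between stimulus onset and the P300 window")
    if not in_win.any():
        raise DomainError("P300 window contains no samples")
    lowest = float(erp.values[pre].min())
    if lowest > 0:
        warnings.warn(
            "pre-window minimum is positive; no negative deflection found",
            stacklevel=2,
        )
    return float(erp.values[in_win].max()) - lowest


def area_feature(erp: ERPWaveform, window: P300Window = P300Window()) -> float:
    """Sum of the waveform samples inside the P300 window (inclusive ends)."""
    in_win = (erp.time_ms >= window.start_ms) & (erp.time_ms <= window.end_ms)
    if not in_win.any():
        raise DomainError("P300 window contains no samples")
    return float(erp.values[in_win].sum())


def cwt_morlet(values: np.ndarray, fs: float, freqs: np.ndarray,
               fb: float = 2.0, fc: float = 1.0,
               time_ms: np.ndarray | None = None) -> TimeFrequencyMap:
    """Complex-Morlet continuous wavelet transform of one waveform.

    The mother wavelet is the standard two-parameter complex Morlet
    ``psi(t) = (pi*fb)^(-1/2) * exp(2i*pi*fc*t) * exp(-t^2/fb)`` with
    bandwidth ``fb`` and center frequency ``fc``; scale ``a`` maps to
    frequency ``f = fc / (a * dt)``. Coefficients follow the ``(1/a) *
    integral x(t) psi((t-b)/a) dt`` convention (amplitude-flat: unit
    sinusoids give equal response at every scale), obtained from the
    library's L2-normalized transform by dividing by ``sqrt(a)``. Power is
    the squared coefficient magnitude. Trial-averaged maps are obtained by
    calling this per trial and averaging the power.
    """
    values = np.asarray(values, float)
    freqs = np.asarray(freqs, float)
    if fb <= 0 or fc <= 0:
        raise DomainError("fb and fc must be positive")
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise DomainError("requested frequencies must lie in (0, fs/2)")
    dt = 1.0 / fs
    scales = fc / (freqs * dt)
    coeffs, _ = pywt.cwt(values, scales, f"cmor{fb}-{fc}", sampling_period=dt)
    coeffs = coeffs / np.sqrt(scales)[:, None]
    if time_ms is None:
        time_ms = np.arange(values.size) * dt * 1000.0
    return TimeFrequencyMap(
        power=np.abs(coeffs) ** 2,
        freqs=freqs,
        time_ms=np.asarray(time_ms, float),
        wavelet_params=(fb, fc),
    )


def average_tf_map(epochs: EpochSet, channel: int, freqs: np.ndarray,
                   fb: float = 2.0, fc: float = 1.0,
                   condition: str | None = None) -> TimeFrequencyMap:
    """Per-trial wavelet power on one channel, averaged across trials."""
    data = epochs.data
    if condition is not None:
        mask = epochs.is_target if condition == "target" else ~epochs.is_target
        data = data[mask]
    if data.shape[0] == 0:
        raise DomainError("no trials to average")
    acc = None
    for trial in data[:, channel, :]:
        tf = cwt_morlet(trial, epochs.fs, freqs, fb, fc, epochs.time_ms)
        acc = tf.power if acc is None else acc + tf.power
    return TimeFrequencyMap(acc / data.shape[0], np.asarray(freqs, float),
                            epochs.time_ms, (fb, fc))
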