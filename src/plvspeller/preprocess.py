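"""Continuous recording -> clean, baseline-normalized epochs.

Order of operations matters: the band-pass runs on the continuous signal
(so filter edge transients fall between, not inside, epochs), blink
components are removed on the continuous signal, and only then are
stimulus-locked windows cut and z-scored against their pre-stimulus
baseline.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .containers import EEGRecording, EpochSet
from .errors import DegenerateInputError, DomainError, EstimationError

__all__ = [
    "bandpass_filter",
    "remove_blink_components",
    "extract_epochs",
    "zscore_baseline",
    "preprocess_recording",
]

#: Standard epoch window in seconds relative to flash onset, half-open.
DEFAULT_EPOCH_WINDOW = (-0.2, 0.8)
#: Frontal electrodes used to flag ocular components.
DEFAULT_FRONTAL_LABELS = frozenset({"Fp1", "Fp2"})


def design_bandpass(low: float, high: float, fs: float,
                    transition: float = 1.0) -> np.ndarray:
    """Linear-phase windowed-sinc band-pass taps (Hamming window).

    The tap count is chosen for a transition band of ``transition`` Hz
    (Hamming main-lobe rule of thumb: width ~ 3.3 / N normalized), forced odd
    so the filter is exactly symmetric (type I) and zero-phase after delay
    compensation.
    """
    if not (0 < low < high < fs / 2):
        raise DomainError(f"invalid band [{low}, {high}] Hz at fs={fs}")
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2
    return signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs, window="hamming")


def bandpass_filter(rec: EEGRecording, low: float = 1.0, high: float = 12.0,
                    transition: float = 1.0) -> EEGRecording:
    """Zero-phase FIR band-pass, applied per channel.

    The symmetric FIR kernel is applied in a single pass with its group
    delay compensated (``mode="same"`` convolution), which is exactly
    zero-phase for a linear-phase filter and keeps passband gain ~ 1.
    """
    taps = design_bandpass(low, high, rec.fs, transition)
    filtered = signal.fftconvolve(rec.data, taps[None, :], mode="same", axes=-1)
    return rec.copy_with(filtered)


def remove_blink_components(
    rec: EEGRecording,
    frontal_labels=DEFAULT_FRONTAL_LABELS,
    ratio_threshold: float = 3.0,
    random_state: int = 0,
    max_iter: int = 1000,
) -> tuple[EEGRecording, int]:
    """Reject ocular ICA components by their frontal mixing-weight ratio.

    The recording is decomposed into ``n_channels`` independent components.
    A component is called ocular when the mean absolute mixing weight over
    the frontal electrodes exceeds ``ratio_threshold`` times the mean
    absolute weight over all remaining electrodes — eye blinks project far
    more strongly to Fp1/Fp2 than to the rest of the scalp. Flagged
    components are zeroed before back-projection.

    Returns the cleaned recording and the number of rejected components.
    The decomposition backend is pluggable in spirit: any unmixing that
    yields a mixing matrix would do; FastICA is the default.
    """
    from sklearn.decomposition import FastICA

    frontal_idx = [i for i, lab in enumerate(rec.channel_labels) if lab in frontal_labels]
    other_idx = [i for i in range(rec.n_channels) if i not in frontal_idx]
    if not frontal_idx:
        raise DomainError(f"no frontal channels {set(frontal_labels)} in recording")
    if len(other_idx) < 2:
        raise DomainError("need at least 2 non-frontal channels")

    cond = np.linalg.cond(np.cov(rec.data))
    if not np.isfinite(cond) or cond > 1e12:
        raise EstimationError(
            f"channel covariance is rank deficient (condition number {cond:.3g})"
        )

    if np.isinf(ratio_threshold):
        return rec.copy_with(rec.data.copy()), 0

    ica = FastICA(
        n_components=rec.n_channels,
        whiten="unit-variance",
        random_state=random_state,
        max_iter=max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter is handled by cond check
        sources = ica.fit_transform(rec.data.T)  # (samples, components)
    mixing = ica.mixing_  # (channels, components)

    frontal_w = np.abs(mixing[frontal_idx]).mean(axis=0)
    other_w = np.abs(mixing[other_idx]).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(other_w > 0, frontal_w / other_w, np.inf)
    reject = ratio > ratio_threshold
    n_rejected = int(reject.sum())

    if n_rejected == 0:
        return rec.copy_with(rec.data.copy()), 0
    kept = sources.copy()
    kept[:, reject] = 0.0
    cleaned = (mixing @ kept.T) + ica.mean_[:, None]
    return rec.copy_with(cleaned), n_rejected


def extract_epochs(rec: EEGRecording,
                   window: tuple[float, float] = DEFAULT_EPOCH_WINDOW) -> EpochSet:
    """Cut one stimulus-locked epoch per flash event.

    The sample window is half-open, ``[onset + window[0], onset + window[1])``,
    so at 500 Hz the standard [-200, 800) ms window yields exactly 500
    samples. Events whose window would run past either end of the recording
    are dropped with a warning and counted in ``EpochSet.n_dropped``.
    """
    if rec.events is None or len(rec.events) == 0:
        raise DomainError("recording carries no events to epoch")
    pre_s, post_s = window
    if not pre_s < post_s:
        raise DomainError("epoch window must be increasing")
    n_epoch = int(round((post_s - pre_s) * rec.fs))
    offset = int(round(pre_s * rec.fs))

    trials, keep = [], []
    n_dropped = 0
    for k, onset in enumerate(rec.events.onsets):
        start = int(round(onset * rec.fs)) + offset
        stop = start + n_epoch
        if start < 0 or stop > rec.n_samples:
            n_dropped += 1
            continue
        trials.append(rec.data[:, start:stop])
        keep.append(k)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} event(s) with truncated epoch windows",
            stacklevel=2,
        )
    if not trials:
        raise DomainError("no event leaves room for a full epoch window")

    keep = np.asarray(keep, int)
    time_ms = (np.arange(n_epoch) + offset) / rec.fs * 1000.0
    return EpochSet(
        data=np.stack(trials),
        time_ms=time_ms,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        is_target=np.asarray(rec.events.is_target, bool)[keep],
        stimulus_ids=np.asarray(rec.events.stimulus_ids, int)[keep],
        character_indices=np.asarray(rec.events.character_indices, int)[keep],
        n_dropped=n_dropped,
    )


def preprocess_recording(rec: EEGRecording, low: float = 1.0,
                         high: float = 12.0,
                         window: tuple[float, float] = DEFAULT_EPOCH_WINDOW,
                         zscore: bool = True) -> EpochSet:
    """Standard chain: band-pass the continuous signal, epoch, z-score.

    Blink-component removal is deliberately not part of this helper — run
    :func:`remove_blink_components` first when the recording has ocular
    artifacts (synthetic sessions do not).
    """
    epochs = extract_epochs(bandpass_filter(rec, low, high), window)
    return zscore_baseline(epochs) if zscore else epochs


def zscore_baseline(epochs: EpochSet,
                    baseline_ms: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Z-score every epoch against its own pre-stimulus baseline.

    Per trial and channel, all samples are transformed as
    ``(x - mean_baseline) / sd_baseline`` where the statistics come from the
    half-open baseline window (default [-200, 0) ms), so the whole epoch —
    baseline and response — ends up on one scale and the baseline itself has
    mean 0 and standard deviation 1 by construction.
    """
    lo, hi = baseline_ms
    mask = (epochs.time_ms >= lo) & (epochs.time_ms < hi)
    if mask.sum() < 2:
        raise DomainError(f"baseline window [{lo}, {hi}) ms has fewer than 2 samples")
    base = epochs.data[:, :, mask]
    mu = base.mean(axis=-1, keepdims=True)
    sd = base.std(axis=-1, keepdims=True)
    bad = np.nonzero(sd[..., 0] == 0)
    if bad[0].size:
        t, c = bad[0][0], bad[1][0]
        raise DegenerateInputError(
            f"zero baseline variance in trial {t}, channel "
            f"{epochs.channel_labels[c]!r}"
        )
    out = epochs.select(np.arange(epochs.n_trials))
    out.data = (epochs.data - mu) / sd
    out.n_dropped = epochs.n_dropped
    return out
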