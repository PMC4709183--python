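"""Across-trial phase-locking value (PLV), surrogate significance, edge counts.

The PLV between channels x and y at epoch time t, over Tr trials, is the
mean resultant length of the per-trial instantaneous phase differences:

    PLV_xy(t) = (1/Tr) | sum_n exp(i * (phi_x,n(t) - phi_y,n(t))) |

with phases extracted from the analytic (Hilbert) signal of each
band-limited epoch. PLV is 1 when the phase relation between the two
channels is identical in every trial and tends to ~ 1/sqrt(Tr) for
independent phases (the Rayleigh resultant), so it is a *trial-consistency*
measure, undefined on a single trial.

Significance of an observed window-averaged PLV is assessed against
surrogate data: each trial/channel signal is phase-randomized in the
frequency domain (amplitude spectrum preserved exactly), the full
phase -> PLV -> window-average pipeline is re-run per surrogate set, and an
edge is retained when the observed value exceeds the surrogate distribution
at the add-one empirical rank level ``p = (1 + #{surr >= obs}) / (1 + n_surr)``.
The count of significant edges is the decoding feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats

from .containers import EpochSet
from .errors import DegenerateInputError, DomainError

__all__ = [
    "PhaseTensor",
    "PLVTimeCourse",
    "SurrogateDistribution",
    "ConnectivityGraph",
    "instantaneous_phase",
    "plv_timecourse",
    "window_average",
    "make_surrogates",
    "significant_edges",
    "mean_plv_feature",
    "condition_contrast",
    "normalize_plv_baseline",
    "pair_index",
    "surrogate_epochs",
]

DEFAULT_WINDOW_MS = (200.0, 500.0)
DEFAULT_N_SURROGATES = 200
DEFAULT_ALPHA = 0.01


def pair_index(n_channels: int) -> list[tuple[int, int]]:
    """Channel pairs (i < j) in upper-triangle order; C(n, 2) of them."""
    ii, jj = np.triu_indices(n_channels, k=1)
    return list(zip(ii.tolist(), jj.tolist()))


@dataclass
class PhaseTensor:
    """Instantaneous phases, trials x channels x samples, in (-pi, pi]."""

    phases: np.ndarray
    time_ms: np.ndarray
    fs: float
    is_target: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.phases.shape[0]

    @property
    def n_channels(self) -> int:
        return self.phases.shape[1]


@dataclass
class PLVTimeCourse:
    """PLV per channel pair and time sample, with the trial count used."""

    plv: np.ndarray  # (n_pairs, n_samples) in [0, 1]
    pairs: list[tuple[int, int]]
    n_trials: int
    time_ms: np.ndarray
    fs: float


@dataclass
class SurrogateDistribution:
    """Window-averaged PLV of each pair under the phase-randomized null."""

    plv_surr: np.ndarray  # (n_surrogates, n_pairs)
    pairs: list[tuple[int, int]]
    window_ms: tuple[float, float]
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self):
        n_surr = self.plv_surr.shape[0]
        if n_surr < 1.0 / self.alpha - 1:
            raise DomainError(
                f"{n_surr} surrogates cannot resolve alpha={self.alpha}; "
                f"need at least {int(np.ceil(1 / self.alpha)) - 1}"
            )

    @property
    def n_surrogates(self) -> int:
        return self.plv_surr.shape[0]


@dataclass
class ConnectivityGraph:
    """Window-averaged PLV as a symmetric weight matrix, plus significance."""

    weights: np.ndarray  # (n_channels, n_channels), symmetric, zero diagonal
    window_ms: tuple[float, float]
    n_trials: int
    adjacency: np.ndarray | None = None  # boolean, after the surrogate test
    p_values: np.ndarray | None = None  # per pair, upper-triangle order
    channel_labels: tuple[str, ...] | None = None

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return pair_index(self.n_channels)

    @property
    def edge_count(self) -> int:
        """Number of significant edges (half the sum of the adjacency)."""
        if self.adjacency is None:
            raise DomainError("no adjacency yet: run significant_edges first")
        return int(self.adjacency.sum()) // 2

    def edge_set(self) -> frozenset[tuple[int, int]]:
        if self.adjacency is None:
            raise DomainError("no adjacency yet: run significant_edges first")
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return frozenset(zip(ii.tolist(), jj.tolist()))

    def to_edge_frame(self):
        """Edge-list table (ch_i, ch_j, weight, significant) for export."""
        import pandas as pd

        labels = self.channel_labels or tuple(
            f"CH{i}" for i in range(self.n_channels)
        )
        rows = []
        for i, j in self.pairs:
            rows.append(
                {
                    "ch_i": labels[i],
                    "ch_j": labels[j],
                    "weight": self.weights[i, j],
                    "significant": bool(self.adjacency[i, j])
                    if self.adjacency is not None
                    else None,
                }
            )
        return pd.DataFrame(rows)


def instantaneous_phase(epochs: EpochSet) -> PhaseTensor:
    """Hilbert-transform phase of every trial/channel epoch.

    Expects band-limited input (run the 1-12 Hz band-pass first); raises on
    all-zero signals, whose phase is undefined.
    """
    flat_energy = np.abs(epochs.data).max(axis=-1)
    bad = np.nonzero(flat_energy == 0)
    if bad[0].size:
        raise DegenerateInputError(
            f"all-zero signal in trial {bad[0][0]}, channel {bad[1][0]}: "
            "phase undefined"
        )
    analytic = sp_signal.hilbert(epochs.data, axis=-1)
    return PhaseTensor(
        phases=np.angle(analytic),
        time_ms=epochs.time_ms,
        fs=epochs.fs,
        is_target=np.asarray(epochs.is_target, bool),
    )


def plv_timecourse(phases: PhaseTensor,
                   condition_mask: np.ndarray | None = None) -> PLVTimeCourse:
    """Across-trial PLV time course for every channel pair (i < j).

    ``condition_mask`` selects the trials entering the resultant (boolean
    mask or indices); at least 2 are required.
    """
    phi = phases.phases
    if condition_mask is not None:
        phi = phi[np.asarray(condition_mask)]
    n_trials = phi.shape[0]
    if n_trials < 2:
        raise DomainError("PLV needs at least 2 trials (undefined on a single trial)")
    z = np.exp(1j * phi)  # (Tr, C, S)
    zt = np.ascontiguousarray(z.transpose(2, 1, 0))  # (S, C, Tr)
    resultant = np.matmul(zt, np.conj(zt.transpose(0, 2, 1))) / n_trials  # (S, C, C)
    ii, jj = np.triu_indices(phases.n_channels, k=1)
    plv = np.abs(resultant[:, ii, jj]).T  # (pairs, S)
    return PLVTimeCourse(
        plv=plv,
        pairs=list(zip(ii.tolist(), jj.tolist())),
        n_trials=n_trials,
        time_ms=phases.time_ms,
        fs=phases.fs,
    )


def window_average(plv: PLVTimeCourse,
                   window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
                   channel_labels: tuple[str, ...] | None = None) -> ConnectivityGraph:
    """Mean PLV over the analysis window, as a symmetric weight matrix.

    The window is inclusive at both ends (``start <= t <= end``); the
    default 200-500 ms bracket of the P300 stays clear of Hilbert edge
    effects at the epoch borders.
    """
    lo, hi = window_ms
    mask = (plv.time_ms >= lo) & (plv.time_ms <= hi)
    if not mask.any():
        raise DomainError(f"window [{lo}, {hi}] ms contains no samples")
    means = plv.plv[:, mask].mean(axis=1)
    n = int(round((1 + np.sqrt(1 + 8 * len(plv.pairs))) / 2))
    weights = np.zeros((n, n))
    for (i, j), w in zip(plv.pairs, means):
        weights[i, j] = weights[j, i] = w
    return ConnectivityGraph(
        weights=weights,
        window_ms=(lo, hi),
        n_trials=plv.n_trials,
        channel_labels=channel_labels,
    )


def normalize_plv_baseline(plv: PLVTimeCourse,
                           baseline_ms: tuple[float, float] = (-200.0, 0.0)
                           ) -> PLVTimeCourse:
    """Z-score each pair's PLV time course against its pre-stimulus baseline.

    Optional descriptive normalization (off the default edge-decision path).
    """
    lo, hi = baseline_ms
    mask = (plv.time_ms >= lo) & (plv.time_ms < hi)
    if mask.sum() < 2:
        raise DomainError("baseline window too short for PLV normalization")
    base = plv.plv[:, mask]
    sd = base.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateInputError("constant baseline PLV; cannot z-score")
    return PLVTimeCourse(
        plv=(plv.plv - base.mean(axis=1, keepdims=True)) / sd,
        pairs=plv.pairs,
        n_trials=plv.n_trials,
        time_ms=plv.time_ms,
        fs=plv.fs,
    )


def _random_phase_factors(rng, shape, n_freq):
    """Unit-modulus spectral rotation factors, identity at DC and Nyquist."""
    theta = rng.uniform(0.0, 2.0 * np.pi, size=shape + (n_freq,)).astype(np.float32)
    theta[..., 0] = 0.0
    theta[..., -1] = 0.0
    return np.exp(1j * theta).astype(np.complex64)


def surrogate_epochs(epochs: EpochSet, rng_seed: int = 0) -> EpochSet:
    """One time-domain phase-randomized surrogate copy of every trial/channel.

    Each signal's spectral phases (excluding DC and Nyquist) are rotated by
    independent uniform angles, preserving the amplitude spectrum exactly.
    """
    rng = np.random.default_rng(rng_seed)
    x = epochs.data
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    factors = _random_phase_factors(rng, x.shape[:-1], spec.shape[-1])
    out = np.fft.irfft(spec * factors, n=n, axis=-1)
    surr = epochs.select(np.arange(epochs.n_trials))
    surr.data = out
    return surr


def _analytic_from_spectrum(rspec: np.ndarray, n: int) -> np.ndarray:
    """Analytic signal via the one-sided spectrum (equals scipy's hilbert)."""
    shape = rspec.shape[:-1] + (n,)
    full = np.zeros(shape, dtype=np.complex64 if rspec.dtype == np.complex64
                    else complex)
    nf = rspec.shape[-1]
    full[..., 0] = rspec[..., 0]
    if n % 2 == 0:
        full[..., 1 : nf - 1] = 2.0 * rspec[..., 1 : nf - 1]
        full[..., nf - 1] = rspec[..., -1]
    else:
        full[..., 1:nf] = 2.0 * rspec[..., 1:]
    return np.fft.ifft(full, axis=-1)


def make_surrogates(
    epochs: EpochSet,
    condition_mask: np.ndarray | None = None,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    rng_seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    randomize: str = "all_channels",
    _block: int = 32,
) -> SurrogateDistribution:
    """Window-averaged PLV distribution under the phase-randomized null.

    Every trial/channel signal is independently phase-randomized
    (Hermitian-symmetric spectral rotation, amplitude spectrum untouched),
    then phases are re-extracted and the across-trial window-averaged PLV is
    recomputed — once per surrogate. ``randomize="one_of_pair"`` leaves the
    lower-indexed channel of each pair at its original phases instead.

    Deterministic for a fixed ``rng_seed``. Surrogates are processed in
    blocks and in single precision: the null distribution is an empirical
    rank reference, where float32 resolution (~1e-7) is far below the
    ~1/sqrt(Tr) spread of the null itself.
    """
    if randomize not in ("all_channels", "one_of_pair"):
        raise DomainError(f"unknown randomize mode {randomize!r}")
    x = epochs.data
    if condition_mask is not None:
        x = x[np.asarray(condition_mask)]
    n_trials, n_ch, n_samp = x.shape
    if n_trials < 2:
        raise DomainError("surrogate PLV needs at least 2 trials")
    lo, hi = window_ms
    wmask = (epochs.time_ms >= lo) & (epochs.time_ms <= hi)
    if not wmask.any():
        raise DomainError(f"window [{lo}, {hi}] ms outside the epoch")

    rng = np.random.default_rng(rng_seed)
    spec = np.fft.rfft(x, axis=-1).astype(np.complex64)
    nf = spec.shape[-1]
    ii, jj = np.triu_indices(n_ch, k=1)

    if randomize == "one_of_pair":
        a0 = _analytic_from_spectrum(spec, n_samp)[..., wmask]
        z0 = (a0 / np.abs(a0)).astype(np.complex64)

    out = np.empty((n_surrogates, len(ii)), dtype=float)
    done = 0
    while done < n_surrogates:
        k = min(_block, n_surrogates - done)
        factors = _random_phase_factors(rng, (k, n_trials, n_ch), nf)
        a = _analytic_from_spectrum(spec[None] * factors, n_samp)[..., wmask]
        z = (a / np.abs(a)).astype(np.complex64)  # (k, Tr, C, W)
        if randomize == "one_of_pair":
            # original phases on channel i, surrogate phases on channel j
            prod = z0[None, :, ii, :] * np.conj(z[:, :, jj, :])
            plv_w = np.abs(prod.mean(axis=1)).mean(axis=-1)
        else:
            zt = np.ascontiguousarray(z.transpose(0, 3, 1, 2))  # (k, W, Tr, C)
            res = (
                np.matmul(zt.transpose(0, 1, 3, 2).conj(), zt) / n_trials
            )  # (k, W, C, C)
            plv_w = np.abs(res[:, :, ii, jj]).mean(axis=1)
        out[done : done + k] = plv_w
        done += k

    return SurrogateDistribution(
        plv_surr=out,
        pairs=list(zip(ii.tolist(), jj.tolist())),
        window_ms=(lo, hi),
        alpha=alpha,
    )


def significant_edges(graph: ConnectivityGraph,
                      surr: SurrogateDistribution) -> ConnectivityGraph:
    """Threshold the observed window-averaged PLV against the surrogate null.

    Per pair, the one-sided add-one empirical p-value is
    ``(1 + #{surrogate >= observed}) / (1 + n_surrogates)``; the edge is
    retained when ``p < alpha``.
    """
    pairs = graph.pairs
    if pairs != surr.pairs:
        raise DomainError("graph and surrogate distribution index different pairs")
    ii, jj = np.triu_indices(graph.n_channels, k=1)
    observed = graph.weights[ii, jj]
    exceed = (surr.plv_surr >= observed[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + surr.n_surrogates)
    keep = p < surr.alpha
    adjacency = np.zeros_like(graph.weights, dtype=bool)
    adjacency[ii[keep], jj[keep]] = True
    adjacency |= adjacency.T
    return ConnectivityGraph(
        weights=graph.weights,
        window_ms=graph.window_ms,
        n_trials=graph.n_trials,
        adjacency=adjacency,
        p_values=p,
        channel_labels=graph.channel_labels,
    )


def mean_plv_feature(graph: ConnectivityGraph) -> float:
    """Mean of the off-diagonal upper-triangle weights."""
    ii, jj = np.triu_indices(graph.n_channels, k=1)
    return float(graph.weights[ii, jj].mean())


def condition_contrast(target_values, nontarget_values) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum contrast of a per-observation statistic
    (edge count or mean PLV) between target and non-target conditions."""
    x = np.asarray(target_values, float)
    y = np.asarray(nontarget_values, float)
    if len(x) < 5 or len(y) < 5:
        raise DomainError("need at least 5 observations per condition")
    res = stats.ranksums(x, y)
    return float(res.statistic), float(res.pvalue)
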