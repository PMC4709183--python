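"""Synthetic multichannel EEG sessions with known ground truth.

Real speller recordings are rarely shareable, so every downstream stage is
validated against simulated sessions whose structure is known exactly:

* background noise per channel, white or 1/f ("pink", the canonical EEG
  spectral shape);
* on *target* flashes, a P300-like evoked deflection added to a configurable
  subset of channels, time-locked to stimulus onset;
* on *target* flashes, a band-limited oscillation whose phase is shared
  (up to per-channel jitter) within designated channel pairs — elevated
  inter-channel phase coupling;
* on *non-target* flashes, the same channels carry oscillations of the same
  amplitude and band but with fully independent phases, so the two
  conditions differ in phase consistency rather than in spectral content.

The coupling model gives each connected component of the coupling graph one
hidden phase process (a linear phase at a carrier frequency drawn from
``carrier_band`` plus a slow random walk); each member channel observes that
phase plus an independent Gaussian offset of standard deviation
``phase_jitter_sd``. For a coupled pair the across-trial phase-difference
concentration then has the tractable expectation ``exp(-phase_jitter_sd**2)``,
which the validation suite exploits. Ground truth is exact when the
configured pairs form disjoint edges or cliques (the presets do).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CHANNELS_1020_19, EEGRecording
from .errors import DomainError
from .paradigm import SessionPlan, SpellerMatrix, build_schedule, default_matrix

__all__ = ["SimulationConfig", "GroundTruth", "simulate_session", "make_fixture"]

#: Length of the post-stimulus interval that carries evoked structure (s).
RESPONSE_WINDOW_S = 0.8


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic session.

    Amplitudes are in microvolts, times in milliseconds unless noted.
    """

    plan: SessionPlan
    n_channels: int = 19
    fs: float = 500.0
    erp_amplitude: float = 8.0
    erp_latency_ms: float = 350.0
    erp_width_ms: float = 55.0
    erp_channels: tuple[int, ...] = ()
    coupling_pairs: tuple[tuple[int, int], ...] = ()
    coupling_amplitude: float = 6.0
    phase_jitter_sd: float = 0.3
    carrier_band: tuple[float, float] = (4.0, 8.0)
    phase_walk_sd: float = 0.05  # radians per sample of slow carrier drift
    noise_sd: float = 8.0
    noise_model: str = "one_over_f"  # or "white"
    #: Post-stimulus interval (s) carrying the evoked oscillation. Kept a
    #: transient around the P300 so that, at the 250 ms ISI, one flash's
    #: oscillation barely overlaps the analysis window of its neighbors.
    coupling_window_s: tuple[float, float] = (0.15, 0.55)
    rng_seed: int = 0

    def __post_init__(self):
        if self.phase_jitter_sd < 0:
            raise DomainError("phase_jitter_sd must be non-negative")
        if self.noise_model not in ("white", "one_over_f"):
            raise DomainError(f"unknown noise model {self.noise_model!r}")
        lo, hi = self.carrier_band
        if not (0 < lo < hi < self.fs / 2):
            raise DomainError("carrier band must lie within (0, fs/2)")
        wlo, whi = self.coupling_window_s
        if not (0 <= wlo < whi <= RESPONSE_WINDOW_S):
            raise DomainError("coupling window must lie within the post-stimulus window")
        if not (0 < self.erp_latency_ms < RESPONSE_WINDOW_S * 1000):
            raise DomainError("erp_latency_ms must fall inside the post-stimulus window")
        for i, j in self.coupling_pairs:
            if not (0 <= i < self.n_channels and 0 <= j < self.n_channels and i != j):
                raise DomainError(f"invalid coupling pair ({i}, {j})")


@dataclass
class GroundTruth:
    """What the generator actually injected, for validation."""

    true_edges: frozenset[tuple[int, int]]
    is_target: np.ndarray  # per flash
    erp_template: np.ndarray  # (n_channels, epoch_samples) on epoch_time_ms
    epoch_time_ms: np.ndarray
    config: SimulationConfig


def _erp_template(cfg: SimulationConfig, t_ms: np.ndarray) -> np.ndarray:
    """P300-like waveform: a positive Gaussian deflection at ``erp_latency_ms``
    preceded by a smaller negativity near 150 ms, zero before onset."""
    pos = np.exp(-0.5 * ((t_ms - cfg.erp_latency_ms) / cfg.erp_width_ms) ** 2)
    neg = -0.35 * np.exp(-0.5 * ((t_ms - 150.0) / (0.55 * cfg.erp_width_ms)) ** 2)
    wave = cfg.erp_amplitude * (pos + neg)
    wave[t_ms < 0] = 0.0
    template = np.zeros((cfg.n_channels, t_ms.size))
    template[list(cfg.erp_channels)] = wave
    return template


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, sd: float) -> np.ndarray:
    """1/f-amplitude Gaussian noise, scaled to per-channel standard deviation ``sd``."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    shaped *= sd / shaped.std(axis=-1, keepdims=True)
    return shaped


def _ramped_envelope(n: int, fs: float, ramp_s: float = 0.05) -> np.ndarray:
    """Unit envelope with raised-cosine on/off ramps to avoid hard edges."""
    env = np.ones(n)
    k = min(int(round(ramp_s * fs)), n // 2)
    if k > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
        env[:k] = ramp
        env[-k:] = ramp[::-1]
    return env


def _coupling_components(pairs) -> list[set[int]]:
    """Connected components of the coupling graph (union-find over pairs)."""
    parent: dict[int, int] = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in pairs:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    comps: dict[int, set[int]] = {}
    for node in parent:
        comps.setdefault(find(node), set()).add(node)
    return list(comps.values())


def simulate_session(config: SimulationConfig) -> tuple[EEGRecording, GroundTruth]:
    """Generate one continuous recording for the configured session plan.

    Deterministic under a fixed ``config.rng_seed``. Raises
    :class:`~plvspeller.errors.DomainError` when the schedule is empty or the
    implied duration is not representable.
    """
    cfg = config
    sched = cfg.plan.schedule
    if len(sched) == 0:
        raise DomainError("session plan has no flash events")
    duration = sched.onsets[-1] + RESPONSE_WINDOW_S + 0.5
    n_samples = int(round(duration * cfg.fs))
    if n_samples <= 0 or n_samples > 5e8:
        raise DomainError(f"implied recording length {n_samples} samples not representable")

    rng = np.random.default_rng(cfg.rng_seed)
    if cfg.noise_model == "white":
        data = rng.standard_normal((cfg.n_channels, n_samples)) * cfg.noise_sd
    else:
        data = _pink_noise(rng, cfg.n_channels, n_samples, cfg.fs, cfg.noise_sd)
    if cfg.noise_sd == 0:
        data = np.zeros((cfg.n_channels, n_samples))

    resp_n = int(round(RESPONSE_WINDOW_S * cfg.fs))
    t_rel = np.arange(resp_n) / cfg.fs
    osc_start = int(round(cfg.coupling_window_s[0] * cfg.fs))
    osc_stop = int(round(cfg.coupling_window_s[1] * cfg.fs))
    osc_n = osc_stop - osc_start
    osc_t = np.arange(osc_n) / cfg.fs
    osc_env = _ramped_envelope(osc_n, cfg.fs)

    # evoked template, sampled on the standard [-200, 800) ms epoch axis
    epoch_n = int(round(1.0 * cfg.fs))
    epoch_time_ms = (np.arange(epoch_n) - int(round(0.2 * cfg.fs))) / cfg.fs * 1000.0
    template = _erp_template(cfg, epoch_time_ms)
    resp_template = cfg.erp_amplitude * (
        np.exp(-0.5 * ((t_rel * 1000 - cfg.erp_latency_ms) / cfg.erp_width_ms) ** 2)
        - 0.35 * np.exp(-0.5 * ((t_rel * 1000 - 150.0) / (0.55 * cfg.erp_width_ms)) ** 2)
    )

    components = _coupling_components(cfg.coupling_pairs)
    coupled_channels = sorted(set().union(*components)) if components else []
    lo, hi = cfg.carrier_band

    def hidden_phase() -> np.ndarray:
        f0 = rng.uniform(lo, hi)
        walk = np.cumsum(rng.standard_normal(osc_n)) * cfg.phase_walk_sd
        return 2 * np.pi * f0 * osc_t + rng.uniform(0, 2 * np.pi) + walk

    for onset, is_target in zip(sched.onsets, sched.is_target):
        start = int(round(onset * cfg.fs))
        stop = start + resp_n
        if stop > n_samples:
            continue
        osc_sl = slice(start + osc_start, start + osc_stop)
        if is_target:
            # the Gaussian template is already ~0 at the window edges
            data[list(cfg.erp_channels), start:stop] += resp_template
            for comp in components:
                phi = hidden_phase()
                for ch in comp:
                    jitter = rng.normal(0.0, cfg.phase_jitter_sd)
                    data[ch, osc_sl] += (
                        cfg.coupling_amplitude * osc_env * np.cos(phi + jitter)
                    )
        else:
            for ch in coupled_channels:
                data[ch, osc_sl] += (
                    cfg.coupling_amplitude * osc_env * np.cos(hidden_phase())
                )

    labels = tuple(CHANNELS_1020_19[: cfg.n_channels]) if cfg.n_channels <= 19 else tuple(
        f"CH{i}" for i in range(cfg.n_channels)
    )
    rec = EEGRecording(data=data, fs=cfg.fs, channel_labels=labels, events=sched)
    truth = GroundTruth(
        true_edges=frozenset(tuple(sorted(p)) for p in cfg.coupling_pairs),
        is_target=np.asarray(sched.is_target, bool),
        erp_template=template,
        epoch_time_ms=epoch_time_ms,
        config=cfg,
    )
    return rec, truth


def _reference_config(rng_seed: int = 0) -> SimulationConfig:
    """19 channels at 500 Hz, 14 characters x 15 repetitions on a 5x6 grid,
    strong parieto-occipital phase coupling plus a central-parietal P300."""
    matrix = default_matrix()
    plan = build_schedule(matrix, list(range(14)), n_repetitions=15, rng_seed=rng_seed)
    labels = CHANNELS_1020_19
    idx = {name: i for i, name in enumerate(labels)}
    erp_channels = tuple(idx[c] for c in ("C3", "C4", "P3", "P4", "Pz", "Cz"))
    coupling_pairs = (
        (idx["P3"], idx["P4"]),
        (idx["P3"], idx["Pz"]),
        (idx["P4"], idx["Pz"]),
        (idx["O1"], idx["O2"]),
        (idx["Cz"], idx["Pz"]),
        (idx["Cz"], idx["P3"]),
        (idx["Cz"], idx["P4"]),
    )
    return SimulationConfig(
        plan=plan,
        n_channels=19,
        fs=500.0,
        erp_channels=erp_channels,
        coupling_pairs=coupling_pairs,
        phase_jitter_sd=0.25,
        rng_seed=rng_seed,
    )


def _tiny_config(rng_seed: int = 0) -> SimulationConfig:
    matrix = SpellerMatrix(2, 2)
    plan = build_schedule(matrix, [0, 3], n_repetitions=2,
                          inter_character_gap=1.0, rng_seed=rng_seed)
    return SimulationConfig(
        plan=plan,
        n_channels=4,
        fs=250.0,
        erp_channels=(2, 3),
        coupling_pairs=((0, 1),),
        phase_jitter_sd=0.2,
        rng_seed=rng_seed,
    )


_PRESETS = {"reference": _reference_config, "tiny": _tiny_config}


def make_fixture(name: str, rng_seed: int = 0) -> tuple[EEGRecording, GroundTruth]:
    """Deterministic canned dataset for tests and examples.

    ``"reference"`` mirrors the reference acquisition scale (19 channels,
    500 Hz, 14 characters x 15 repetitions -> 420 target / 1890 non-target
    flashes); ``"tiny"`` is a 4-channel session small enough for smoke tests.
    """
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise DomainError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return simulate_session(factory(rng_seed))


def preset_config(name: str, rng_seed: int = 0) -> SimulationConfig:
    """The :class:`SimulationConfig` behind a named preset (for variation)."""
    try:
        return _PRESETS[name](rng_seed)
    except KeyError:
        raise DomainError(f"unknown preset {name!r}") from None
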