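"""Pipeline configuration: every tunable default in one serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Defaults for the full simulate -> preprocess -> features -> decode run.

    Units: frequencies in Hz, windows in ms, amplitudes in microvolts.
    """

    band_low_hz: float = 1.0
    band_high_hz: float = 12.0
    ica_ratio_threshold: float = 3.0
    epoch_window_s: tuple[float, float] = (-0.2, 0.8)
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    p300_window_ms: tuple[float, float] = (220.0, 500.0)
    plv_window_ms: tuple[float, float] = (200.0, 500.0)
    n_surrogates: int = 200
    alpha: float = 0.01
    wavelet_fb: float = 2.0
    wavelet_fc: float = 1.0
    train_fraction: float = 0.8
    n_repeats: int = 10
    rng_seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("epoch_window_s", "baseline_ms", "p300_window_ms", "plv_window_ms"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
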