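"""Minimal EDF (European Data Format) export/import for recordings.

No installed package writes EDF in this stack, so the writer here emits a
plain 16-bit EDF with one-second data records and symmetric per-channel
physical scaling. Round trips are validated in the test suite against MNE's
independent EDF reader, which is also what :func:`read_edf` uses, so the
real-data path and the synthetic path share one reader.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .containers import EEGRecording
from .errors import DomainError
from .paradigm import FlashSchedule

__all__ = ["write_edf", "read_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as 16-bit EDF with 1 s data records.

    Requires an integer sampling rate. The signal is zero-padded to a whole
    number of records; quantization error is bounded by half a digital step
    of the per-channel symmetric physical range.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise DomainError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per signal
    ns = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((ns, n_records * spr))
    padded[:, : rec.n_samples] = rec.data

    amp = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    amp = np.array([float(f"{a * 1.001:.4g}") for a in amp])

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (ns + 1), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii("1", 8),
            _ascii(ns, 4),
            b"".join(_ascii(lab, 16) for lab in rec.channel_labels),
            b"".join(_ascii("", 80) for _ in range(ns)),
            b"".join(_ascii("uV", 8) for _ in range(ns)),
            b"".join(_ascii(f"{-a:g}"[:8], 8) for a in amp),
            b"".join(_ascii(f"{a:g}"[:8], 8) for a in amp),
            b"".join(_ascii(_DIG_MIN, 8) for _ in range(ns)),
            b"".join(_ascii(_DIG_MAX, 8) for _ in range(ns)),
            b"".join(_ascii("", 80) for _ in range(ns)),
            b"".join(_ascii(spr, 8) for _ in range(ns)),
            b"".join(_ascii("", 32) for _ in range(ns)),
        ]
    )

    scale = (_DIG_MAX - _DIG_MIN) / (2 * amp)
    digital = np.round((padded + amp[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path, events: FlashSchedule | None = None,
             events_tsv=None) -> EEGRecording:
    """Load an EDF file into an :class:`EEGRecording` (microvolts).

    Events may be supplied directly or as a sidecar TSV written by
    :meth:`FlashSchedule.to_tsv`.
    """
    import mne

    raw = mne.io.read_raw_edf(Path(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    if events is None and events_tsv is not None:
        events = FlashSchedule.from_tsv(events_tsv)
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        events=events,
    )
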