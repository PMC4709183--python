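"""Row/column speller paradigm: stimulus matrix, flash schedule, trial bookkeeping.

The oddball speller presents a grid of characters. Rows and columns are
intensified ("flashed") in randomized blocks; the row and the column that
contain the attended character are *target* stimuli (expected to evoke a
P300), all others are *non-target*. This module is the single source of
truth for the counting identities used throughout the pipeline:

    flashes per block     = n_rows + n_cols
    targets per block     = 2
    non-targets per block = n_rows + n_cols - 2

Stimulus ids enumerate rows first, then columns: id ``r`` in
``[0, n_rows)`` is row ``r``; id ``n_rows + c`` is column ``c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "SpellerMatrix",
    "FlashSchedule",
    "SessionPlan",
    "build_schedule",
    "expected_counts",
    "default_matrix",
]

#: Flash duration in seconds (stimulus intensification time).
DEFAULT_FLASH_DURATION = 0.150
#: Inter-stimulus interval in seconds (onset-to-onset spacing).
DEFAULT_ISI = 0.250
#: Blank period between characters in seconds; carries no events.
DEFAULT_INTER_CHARACTER_GAP = 3.0


@dataclass(frozen=True)
class SpellerMatrix:
    """Character grid of the speller.

    Parameters
    ----------
    n_rows, n_cols
        Grid geometry; both must be at least 2.
    symbols
        Row-major display labels, one per cell. Arbitrary strings, so any
        alphabet works. Defaults to ``"S0" ... "S{n-1}"``.
    """

    n_rows: int
    n_cols: int
    symbols: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_rows < 2 or self.n_cols < 2:
            raise DomainError("matrix must be at least 2x2")
        if not self.symbols:
            object.__setattr__(
                self,
                "symbols",
                tuple(f"S{i}" for i in range(self.n_rows * self.n_cols)),
            )
        if len(self.symbols) != self.n_rows * self.n_cols:
            raise DomainError(
                f"need {self.n_rows * self.n_cols} symbols, got {len(self.symbols)}"
            )

    @property
    def n_characters(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_stimuli(self) -> int:
        """Distinct stimuli per block: one flash per row and per column."""
        return self.n_rows + self.n_cols

    def character_position(self, character_index: int) -> tuple[int, int]:
        """(row, col) of a 0-based character index (row-major)."""
        if not 0 <= character_index < self.n_characters:
            raise DomainError(
                f"character index {character_index} out of range "
                f"[0, {self.n_characters})"
            )
        return divmod(character_index, self.n_cols)

    def target_stimuli(self, character_index: int) -> tuple[int, int]:
        """Stimulus ids of the row and column containing the character."""
        row, col = self.character_position(character_index)
        return row, self.n_rows + col

    def stimulus_is_row(self, stimulus_id: int) -> bool:
        if not 0 <= stimulus_id < self.n_stimuli:
            raise DomainError(f"stimulus id {stimulus_id} out of range")
        return stimulus_id < self.n_rows

    def character_at(self, row_id: int, col_id: int) -> int:
        """Character index at the intersection of a row id and a column id."""
        if not (0 <= row_id < self.n_rows):
            raise DomainError(f"row id {row_id} out of range")
        col = col_id - self.n_rows
        if not (0 <= col < self.n_cols):
            raise DomainError(f"column id {col_id} out of range")
        return row_id * self.n_cols + col


def default_matrix() -> SpellerMatrix:
    """The 5-row x 6-column grid used as the package default (11 stimuli)."""
    return SpellerMatrix(5, 6)


@dataclass
class FlashSchedule:
    """Ordered stimulus event stream of a session.

    One entry per flash: onset time (s), stimulus id, target flag and the
    0-based index (into the session's character list) of the character the
    subject is attending during that flash.
    """

    onsets: np.ndarray  # float seconds
    stimulus_ids: np.ndarray  # int
    is_target: np.ndarray  # bool
    character_indices: np.ndarray  # int, position in the session character list
    flash_duration: float = DEFAULT_FLASH_DURATION
    isi: float = DEFAULT_ISI

    def __post_init__(self):
        n = len(self.onsets)
        if not (len(self.stimulus_ids) == len(self.is_target) == len(self.character_indices) == n):
            raise DomainError("schedule columns must have equal length")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def duration(self) -> float:
        """Time from start to the end of the last flash window (s)."""
        return float(self.onsets[-1]) + self.isi if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.onsets,
                "stimulus_id": self.stimulus_ids,
                "is_target": self.is_target.astype(int),
                "character_index": self.character_indices,
            }
        )

    def to_tsv(self, path) -> None:
        """Write a BIDS-style events table (tab-separated, one row per flash)."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, flash_duration: float = DEFAULT_FLASH_DURATION,
                 isi: float = DEFAULT_ISI) -> "FlashSchedule":
        df = pd.read_csv(path, sep="\t")
        return cls(
            onsets=df["onset_s"].to_numpy(float),
            stimulus_ids=df["stimulus_id"].to_numpy(int),
            is_target=df["is_target"].to_numpy(int).astype(bool),
            character_indices=df["character_index"].to_numpy(int),
            flash_duration=flash_duration,
            isi=isi,
        )


@dataclass
class SessionPlan:
    """A full spelling session: which characters, how many repetitions, when."""

    characters: list[int]
    matrix: SpellerMatrix
    n_repetitions: int
    schedule: FlashSchedule
    inter_character_gap: float = DEFAULT_INTER_CHARACTER_GAP

    @property
    def n_flashes(self) -> int:
        return len(self.schedule)


def build_schedule(
    matrix: SpellerMatrix,
    characters: list[int],
    n_repetitions: int,
    flash_duration: float = DEFAULT_FLASH_DURATION,
    isi: float = DEFAULT_ISI,
    inter_character_gap: float = DEFAULT_INTER_CHARACTER_GAP,
    start_time: float = 1.0,
    rng_seed: int = 0,
) -> SessionPlan:
    """Build a randomized flash schedule for a list of attended characters.

    For each character, ``n_repetitions`` blocks are scheduled; each block
    flashes every one of the ``n_rows + n_cols`` stimuli exactly once in a
    fresh random order, with onsets spaced exactly ``isi`` seconds apart.
    A blank gap of ``inter_character_gap`` seconds (no events) separates
    consecutive characters, and the first flash is delayed by ``start_time``
    seconds so that pre-stimulus epoch windows fit inside the recording.

    Target flags are set by membership of the attended character in the
    flashed row or column. Reproducible for a fixed ``rng_seed``.
    """
    if n_repetitions < 1:
        raise DomainError("n_repetitions must be >= 1")
    if flash_duration <= 0 or isi <= 0:
        raise DomainError("flash_duration and isi must be positive")
    if flash_duration > isi:
        raise DomainError("flash_duration cannot exceed the inter-stimulus interval")
    for c in characters:
        matrix.character_position(c)  # raises DomainError when invalid

    if start_time < 0:
        raise DomainError("start_time must be non-negative")
    rng = np.random.default_rng(rng_seed)
    n_stim = matrix.n_stimuli
    onsets, stim_ids, targets, char_idx = [], [], [], []
    t = float(start_time)
    for ci, character in enumerate(characters):
        tgt_row, tgt_col = matrix.target_stimuli(character)
        for _ in range(n_repetitions):
            order = rng.permutation(n_stim)
            for s in order:
                onsets.append(t)
                stim_ids.append(int(s))
                targets.append(s == tgt_row or s == tgt_col)
                char_idx.append(ci)
                t += isi
        t += inter_character_gap

    schedule = FlashSchedule(
        onsets=np.asarray(onsets, float),
        stimulus_ids=np.asarray(stim_ids, int),
        is_target=np.asarray(targets, bool),
        character_indices=np.asarray(char_idx, int),
        flash_duration=flash_duration,
        isi=isi,
    )
    return SessionPlan(
        characters=list(characters),
        matrix=matrix,
        n_repetitions=n_repetitions,
        schedule=schedule,
        inter_character_gap=inter_character_gap,
    )


def expected_counts(plan: SessionPlan) -> tuple[int, int]:
    """Closed-form (n_target, n_nontarget) flash counts for a session plan.

    n_target     = n_characters * n_repetitions * 2
    n_nontarget  = n_characters * n_repetitions * (n_rows + n_cols - 2)
    """
    n_chars = len(plan.characters)
    n_target = n_chars * plan.n_repetitions * 2
    n_nontarget = n_chars * plan.n_repetitions * (plan.matrix.n_stimuli - 2)
    return n_target, n_nontarget
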