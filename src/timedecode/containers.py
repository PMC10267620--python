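"""In-memory containers for epoched electrophysiology and gaze data.

The pipeline operates on per-participant epoched data: a dense
``trials x channels x timepoints`` voltage array with a uniform time axis in
milliseconds relative to sample onset, paired with a per-trial metadata
table (a plain :class:`pandas.DataFrame` with a fixed column contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EpochedRecording",
    "GazeRecording",
    "TRIAL_COLUMNS",
    "AVAILABILITY_LEVELS",
    "RELEVANCE_LEVELS",
    "CONDITIONS",
    "condition_key",
    "validate_trial_table",
]

#: Required columns of a trial table.
TRIAL_COLUMNS = (
    "sf_value",
    "sf_class",
    "color_index",
    "availability",
    "relevance",
    "correct",
    "participant_id",
)

AVAILABILITY_LEVELS = ("short", "long")
RELEVANCE_LEVELS = ("sf", "color")

#: The four availability x relevance cells of the design, as "avail-rel" keys.
CONDITIONS = tuple(
    f"{a}-{r}" for a in AVAILABILITY_LEVELS for r in RELEVANCE_LEVELS
)


def condition_key(availability: str, relevance: str) -> str:
    """Canonical string key for one cell of the 2 x 2 design."""
    key = f"{availability}-{relevance}"
    if key not in CONDITIONS:
        raise ValueError(f"unknown condition {key!r}; expected one of {CONDITIONS}")
    return key


class ConsistencyError(ValueError):
    """Array/metadata disagreement (e.g. trial-count mismatch)."""


def _check_times(times: np.ndarray, srate: float) -> None:
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if len(times) > 1:
        steps = np.diff(times)
        expected = 1000.0 / srate
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, expected, rtol=0, atol=1e-6):
            raise ValueError(
                f"time axis step must be uniform at 1000/srate = {expected} ms"
            )


def validate_trial_table(table: pd.DataFrame) -> None:
    """Check the trial-table column contract and value domains.

    Raises ``ValueError`` on a missing column, an out-of-range spatial
    frequency, an unset/invalid class label, or an unknown condition level.
    ``sf_class`` may be 0 (unset) or 1..4.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    if len(table) == 0:
        return
    sf = table["sf_value"].to_numpy(dtype=float)
    if np.any(sf < 1.0 - 1e-9) or np.any(sf > 4.0 + 1e-9):
        raise ValueError("sf_value must lie within [1, 4] cpdva")
    cls = table["sf_class"].to_numpy()
    if not np.all(np.isin(cls, [0, 1, 2, 3, 4])):
        raise ValueError("sf_class must be 0 (unset) or an integer in 1..4")
    bad_avail = set(table["availability"]) - set(AVAILABILITY_LEVELS)
    if bad_avail:
        raise ValueError(f"unknown availability levels: {sorted(bad_avail)}")
    bad_rel = set(table["relevance"]) - set(RELEVANCE_LEVELS)
    if bad_rel:
        raise ValueError(f"unknown relevance levels: {sorted(bad_rel)}")


@dataclass
class EpochedRecording:
    """Epoched multichannel voltage data for one participant.

    Parameters
    ----------
    data
        Array ``[n_trials, n_channels, n_times]`` in microvolts.
    times
        Milliseconds relative to sample onset; uniform step ``1000/srate``.
    srate
        Sampling rate in Hz.
    channel_labels
        Unique channel names, one per data row.
    participant_id
        Identifier carried through to outputs.
    """

    data: np.ndarray
    times: np.ndarray
    srate: float
    channel_labels: list[str] = field(default_factory=list)
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be [n_trials, n_channels, n_times]")
        if self.data.shape[2] != len(self.times):
            raise ConsistencyError(
                f"data has {self.data.shape[2]} timepoints but times has "
                f"{len(self.times)}"
            )
        if self.data.shape[1] != len(self.channel_labels):
            raise ConsistencyError(
                f"data has {self.data.shape[1]} channels but "
                f"{len(self.channel_labels)} labels were given"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        _check_times(self.times, self.srate)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **kwargs) -> "EpochedRecording":
        return replace(self, **kwargs)

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples in the closed-open window [start, end)."""
        start, end = window_ms
        return (self.times >= start) & (self.times < end)


@dataclass
class GazeRecording:
    """Epoched 2-D gaze position (horizontal, vertical) in degrees visual angle.

    Same trial alignment and time conventions as :class:`EpochedRecording`;
    the channel dimension is fixed at 2 (x, y).
    """

    data: np.ndarray
    times: np.ndarray
    srate: float
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValueError("gaze data must be [n_trials, 2, n_times]")
        if self.data.shape[2] != len(self.times):
            raise ConsistencyError("gaze data/time-axis length mismatch")
        _check_times(self.times, self.srate)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        start, end = window_ms
        return (self.times >= start) & (self.times < end)
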