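"""Native on-disk container for per-participant epoched data.

One participant = one directory holding

* ``header.json``   — sampling rate, time axis, channel labels, participant id
* ``data.npy``      — float64 array ``[n_trials, n_channels, n_times]``
* ``trials.tsv``    — per-trial metadata table
* ``gaze.npy``      — optional ``[n_trials, 2, n_times]`` gaze traces
                      (time axis under ``gaze`` in the header)

The format is lossless for 64-bit floats (NaN included) and round-trips
bitwise through :func:`write_dataset` / :func:`read_dataset`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ConsistencyError,
    EpochedRecording,
    GazeRecording,
    validate_trial_table,
)

__all__ = ["read_dataset", "write_dataset", "read_gaze", "write_gaze"]

_HEADER = "header.json"
_DATA = "data.npy"
_TRIALS = "trials.tsv"
_GAZE = "gaze.npy"


class FormatError(ValueError):
    """Malformed or incomplete container."""


def write_dataset(
    rec: EpochedRecording,
    table: pd.DataFrame,
    path: str | Path,
    gaze: GazeRecording | None = None,
) -> Path:
    """Write one participant's recording (and optional gaze) to ``path``."""
    validate_trial_table(table)
    if rec.n_trials != len(table):
        raise ConsistencyError(
            f"recording has {rec.n_trials} trials but table has {len(table)} rows"
        )
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "participant_id": rec.participant_id,
        "srate": rec.srate,
        "times": rec.times.tolist(),
        "channel_labels": list(rec.channel_labels),
        "n_trials": int(rec.n_trials),
    }
    if gaze is not None:
        if gaze.n_trials != rec.n_trials:
            raise ConsistencyError("gaze/EEG trial count mismatch")
        header["gaze"] = {"srate": gaze.srate, "times": gaze.times.tolist()}
        np.save(path / _GAZE, np.asarray(gaze.data, dtype=np.float64))
    with open(path / _HEADER, "w") as fh:
        json.dump(header, fh, indent=1)
    np.save(path / _DATA, np.asarray(rec.data, dtype=np.float64))
    table.to_csv(path / _TRIALS, sep="\t", index=False)
    return path


def _load_header(path: Path) -> dict:
    header_path = path / _HEADER
    if not header_path.exists():
        raise FormatError(f"missing {_HEADER} in {path}")
    with open(header_path) as fh:
        header = json.load(fh)
    for key in ("participant_id", "srate", "times", "channel_labels", "n_trials"):
        if key not in header:
            raise FormatError(f"header is missing required field {key!r}")
    return header


def read_dataset(path: str | Path) -> tuple[EpochedRecording, pd.DataFrame]:
    """Read one participant's container; all container invariants are checked."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = _load_header(path)
    data = np.load(path / _DATA)
    table = pd.read_csv(
        path / _TRIALS,
        sep="\t",
        dtype={"participant_id": str, "availability": str, "relevance": str},
    )
    if len(table) == 0:
        # an empty TSV loses dtypes; normalise the boolean column
        table["correct"] = table["correct"].astype(bool)
    validate_trial_table(table)
    if data.shape[0] != len(table):
        raise ConsistencyError(
            f"data holds {data.shape[0]} trials but trials.tsv has "
            f"{len(table)} rows"
        )
    if data.shape[0] != header["n_trials"]:
        raise ConsistencyError("header n_trials disagrees with data")
    rec = EpochedRecording(
        data=data,
        times=np.asarray(header["times"], dtype=float),
        srate=float(header["srate"]),
        channel_labels=list(header["channel_labels"]),
        participant_id=str(header["participant_id"]),
    )
    return rec, table


def write_gaze(gaze: GazeRecording, path: str | Path) -> Path:
    """Add/overwrite gaze traces in an existing participant container."""
    path = Path(path)
    header = _load_header(path)
    if gaze.n_trials != header["n_trials"]:
        raise ConsistencyError("gaze trial count disagrees with container")
    header["gaze"] = {"srate": gaze.srate, "times": gaze.times.tolist()}
    with open(path / _HEADER, "w") as fh:
        json.dump(header, fh, indent=1)
    np.save(path / _GAZE, np.asarray(gaze.data, dtype=np.float64))
    return path


def read_gaze(path: str | Path) -> GazeRecording:
    path = Path(path)
    header = _load_header(path)
    if "gaze" not in header or not (path / _GAZE).exists():
        raise FormatError(f"container at {path} holds no gaze data")
    return GazeRecording(
        data=np.load(path / _GAZE),
        times=np.asarray(header["gaze"]["times"], dtype=float),
        srate=float(header["gaze"]["srate"]),
        participant_id=str(header["participant_id"]),
    )
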