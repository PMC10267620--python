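"""Deterministic epoch conditioning ahead of decoding.

Order of the canonical pipeline: channel selection, baseline correction,
zero-phase Butterworth lowpass, integer-ratio downsampling, correct-trial
filtering, equal-count class binning, and per-class trial-count
equalisation.  Every step is per-trial, so preprocessing commutes with any
trial subsetting.

Time windows are closed-open ``[start, end)`` in milliseconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochedRecording

__all__ = [
    "BinSpec",
    "select_channels",
    "rereference",
    "baseline_correct",
    "lowpass_filter",
    "resample",
    "filter_correct",
    "bin_feature",
    "equalize_classes",
    "preprocess_pipeline",
]


@dataclass
class BinSpec:
    """Equal-count binning of a continuous feature into ordered classes."""

    n_bins: int = 4
    method: str = "equal-count"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.method != "equal-count":
            raise ValueError(f"unknown binning method {self.method!r}")


def select_channels(rec: EpochedRecording, labels) -> EpochedRecording:
    """Restrict and reorder channels to ``labels`` (analysis order)."""
    labels = list(labels)
    missing = [lab for lab in labels if lab not in rec.channel_labels]
    if missing:
        raise KeyError(f"channels not present in recording: {missing}")
    idx = [rec.channel_labels.index(lab) for lab in labels]
    return rec.copy_with(data=rec.data[:, idx, :], channel_labels=labels)


def rereference(rec: EpochedRecording, reference_labels=("T7", "T8")) -> EpochedRecording:
    """Re-reference to the mean of the named channels (full-montage input).

    Optional: synthetic 20-channel data are generated reference-free and
    skip this step.
    """
    missing = [lab for lab in reference_labels if lab not in rec.channel_labels]
    if missing:
        raise KeyError(f"reference channels not present: {missing}")
    idx = [rec.channel_labels.index(lab) for lab in reference_labels]
    ref = rec.data[:, idx, :].mean(axis=1, keepdims=True)
    return rec.copy_with(data=rec.data - ref)


def baseline_correct(rec: EpochedRecording, window_ms=(-500.0, 0.0)) -> EpochedRecording:
    """Subtract the per-trial, per-channel mean over ``[start, end)`` ms."""
    mask = rec.time_mask(window_ms)
    if not mask.any():
        raise ValueError(
            f"baseline window {window_ms} contains no samples of the time axis"
        )
    baseline = rec.data[:, :, mask].mean(axis=2, keepdims=True)
    return rec.copy_with(data=rec.data - baseline)


def lowpass_filter(
    rec: EpochedRecording, cutoff_hz: float, order: int = 5
) -> EpochedRecording:
    """Zero-phase (forward-backward) Butterworth lowpass, DC gain 1."""
    if cutoff_hz >= rec.srate / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist ({rec.srate / 2} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.srate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=2)
    return rec.copy_with(data=np.ascontiguousarray(filtered))


def resample(rec: EpochedRecording, target_hz: float) -> EpochedRecording:
    """Downsample by decimation (keep every k-th sample, starting at the first).

    The caller is responsible for having lowpassed at or below
    ``target_hz / 2``; with the 8 Hz analysis filter applied, dropping
    samples to 50 Hz introduces no aliasing.
    """
    ratio = rec.srate / target_hz
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"srate {rec.srate} Hz is not an integer multiple of {target_hz} Hz"
        )
    if k == 1:
        return rec
    return rec.copy_with(
        data=np.ascontiguousarray(rec.data[:, :, ::k]),
        times=rec.times[::k].copy(),
        srate=target_hz,
    )


def filter_correct(
    rec: EpochedRecording, table: pd.DataFrame
) -> tuple[EpochedRecording, pd.DataFrame]:
    """Keep only correct-response trials, preserving order."""
    keep = table["correct"].to_numpy(dtype=bool)
    if not keep.any():
        raise ValueError("no correct trials remain")
    return (
        rec.copy_with(data=rec.data[keep]),
        table.loc[keep].reset_index(drop=True),
    )


def bin_feature(values, spec: BinSpec = BinSpec()) -> np.ndarray:
    """Assign equal-count (quantile) class labels 1..n_bins to ``values``.

    Class sizes differ by at most one (earlier classes get the extra trial),
    class index increases with value, and ties keep their original order
    (stable sort).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < spec.n_bins:
        raise ValueError(f"need at least {spec.n_bins} values, got {n}")
    order = np.argsort(values, kind="stable")
    classes = np.empty(n, dtype=int)
    start = 0
    for b, chunk in enumerate(np.array_split(np.arange(n), spec.n_bins), start=1):
        classes[order[start : start + len(chunk)]] = b
        start += len(chunk)
    return classes


def equalize_classes(
    rec: EpochedRecording, table: pd.DataFrame, seed: int
) -> tuple[EpochedRecording, pd.DataFrame]:
    """Subsample every class (seeded, without replacement) to the minimum count.

    Retained trials keep their original order.
    """
    classes = table["sf_class"].to_numpy()
    if np.any(classes == 0):
        raise ValueError("sf_class is unset on some trials; bin first")
    labels = np.unique(classes)
    counts = {int(c): int((classes == c).sum()) for c in labels}
    m = min(counts.values())
    if m == 0:
        raise ValueError("a class has no trials")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in labels:
        idx = np.flatnonzero(classes == c)
        keep.append(rng.choice(idx, size=m, replace=False))
    keep_idx = np.sort(np.concatenate(keep))
    return (
        rec.copy_with(data=rec.data[keep_idx]),
        table.iloc[keep_idx].reset_index(drop=True),
    )


def preprocess_pipeline(
    rec: EpochedRecording,
    table: pd.DataFrame,
    cfg,
    select: bool = True,
) -> tuple[EpochedRecording, pd.DataFrame]:
    """Canonical conditioning: select -> baseline -> lowpass -> resample.

    Correct-trial filtering, binning and equalisation are condition-specific
    and left to the decoding drivers.  ``select=False`` skips channel
    selection (synthetic data already carry exactly the analysis montage).
    """
    if select:
        rec = select_channels(rec, cfg.channels)
    rec = baseline_correct(rec, cfg.baseline_window_ms)
    rec = lowpass_filter(rec, cfg.lowpass_cutoff_hz, cfg.filter_order)
    rec = resample(rec, cfg.decode_srate_hz)
    return rec, table
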