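"""Gaze-position decoding: the eye-movement confound control.

If systematic eye movements carried stimulus-class information, EEG
decoding could reflect ocular rather than neural signals.  The control
decodes the stimulus class from the 2-D gaze position alone, with exactly
the same fold-average / one-versus-all / sign-and-normalise machinery as
the EEG pipeline (shared code path, feature space = horizontal and
vertical position), evaluated on the diagonal only (train time = test
time).  A gaze-decoding cluster that does not overlap the EEG cluster
dissociates the two sources.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GazeRecording, condition_key
from .decode import ScoreTensor, run_decoding
from .preprocess import BinSpec, bin_feature, filter_correct

__all__ = ["gaze_baseline", "decode_gaze", "saccade_summary"]


def gaze_baseline(gaze: GazeRecording, window_ms=(-500.0, 0.0)) -> GazeRecording:
    """Remove slow drift: subtract the per-trial, per-axis baseline mean."""
    mask = gaze.time_mask(window_ms)
    if not mask.any():
        raise ValueError(f"baseline window {window_ms} contains no samples")
    baseline = gaze.data[:, :, mask].mean(axis=2, keepdims=True)
    return GazeRecording(
        data=gaze.data - baseline,
        times=gaze.times,
        srate=gaze.srate,
        participant_id=gaze.participant_id,
    )


def decode_gaze(
    gaze: GazeRecording,
    table: pd.DataFrame,
    availability: str,
    relevance: str,
    cfg,
    seed,
    train_window_ms=None,
    correct_only: bool = True,
    pixels_per_degree: float = 43.0,
) -> ScoreTensor:
    """Diagonal-only class decoding from baseline-corrected gaze position.

    Classes are assigned exactly as in the EEG pipeline (equal-count
    spatial-frequency bins per participant and condition); given the same
    seed and trial set, fold assignments are identical to the EEG run,
    enabling paired confound checks.

    Positions are fed to the classifier in screen pixels — the tracker's
    native unit — via ``pixels_per_degree`` (default 43, a 2560-px-wide
    27-inch display at 58 cm).  The unit matters: a fixed-penalty SVM on
    features far below the margin scale collapses to the majority-class
    solution, whose constant negative score the label-signing step would
    turn into a spurious positive bias at timepoints where gaze barely
    varies.
    """
    if gaze.data.shape[1] != 2:
        raise ValueError(
            f"gaze decoding requires exactly 2 features (x, y); "
            f"got {gaze.data.shape[1]}"
        )
    condition_key(availability, relevance)
    ss = np.random.SeedSequence(seed)
    eq_seed, dec_seed = (int(c.generate_state(1)[0]) for c in ss.spawn(2))

    keep = np.ones(len(table), dtype=bool)
    if correct_only:
        keep &= table["correct"].to_numpy(dtype=bool)
    keep &= (
        (table["availability"] == availability) & (table["relevance"] == relevance)
    ).to_numpy()
    if not keep.any():
        raise ValueError(f"no trials in condition {availability}-{relevance}")
    data = gaze.data[keep]
    sub = table.loc[keep].reset_index(drop=True).copy()
    classes = bin_feature(sub["sf_value"].to_numpy(), BinSpec(n_bins=cfg.n_classes))

    # per-class equalisation, mirroring the EEG path
    rng = np.random.default_rng(eq_seed)
    labels = np.unique(classes)
    m = min(int((classes == c).sum()) for c in labels)
    keep_idx = np.sort(
        np.concatenate(
            [
                rng.choice(np.flatnonzero(classes == c), size=m, replace=False)
                for c in labels
            ]
        )
    )
    return run_decoding(
        data[keep_idx] * pixels_per_degree,
        classes[keep_idx],
        gaze.times,
        cfg,
        dec_seed,
        mode="diagonal",
        train_window_ms=train_window_ms,
    )


def saccade_summary(events: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-condition saccade counts and amplitudes.

    ``events`` is an externally detected saccade table with at least
    ``trial``, ``condition`` and ``amplitude_dva`` columns (this package
    does not detect saccades).  Returns mean saccades/trial and mean
    amplitude per condition.
    """
    required = {"trial", "condition", "amplitude_dva"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"saccade table is missing columns: {sorted(missing)}")
    grouped = events.groupby("condition")
    per_trial = grouped.apply(
        lambda g: len(g) / g["trial"].nunique(), include_groups=False
    )
    return pd.DataFrame(
        {
            "saccades_per_trial": per_trial,
            "mean_amplitude_dva": grouped["amplitude_dva"].mean(),
        }
    )
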