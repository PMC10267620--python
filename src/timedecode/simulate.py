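"""Synthetic epoched EEG + gaze datasets with known representational structure.

The generator emulates a 2 x 2 blocked design crossing perceptual
*availability* (``short``: stimulus visible 150 ms; ``long``: visible
1850 ms) with feature *relevance* (``sf``: the decoded spatial frequency is
task-relevant; ``color``: it is irrelevant).  Each trial's EEG is

    envelope(t, condition) * class_pattern[class]
  + relevance_term(t)      * relevance_pattern     (feature-relevant trials)
  + AR(1) spatially-mixed noise

where the envelope is a Gaussian onset transient plus a sustained box whose
amplitude and duration are per-condition knobs — the ground-truth control of
representational strength and persistence that downstream decoding must
recover.  Class patterns and the condition-discriminating relevance pattern
are mutually orthogonal unit-norm topographies, so class information and
relevance information occupy independent spatial subspaces.

Gaze traces are random-walk drift; an optional class-coupled deflection
switching on late in the trial (off by default) provides the eye-movement
confound scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .config import POSTERIOR_CHANNELS
from .containers import CONDITIONS, EpochedRecording, GazeRecording

__all__ = [
    "SyntheticConfig",
    "PatternBank",
    "make_pattern_bank",
    "signal_envelope",
    "simulate_participant",
    "generate_dataset",
    "null_config",
    "paper_shaped_config",
]

#: 48 spatial frequencies, equally spaced on [1, 4] cycles/degree.
SF_GRID = np.linspace(1.0, 4.0, 48)


def _default_durations() -> dict:
    # sustained representation persists longest when the stimulus is
    # relevant and only briefly available, shortest when irrelevant
    return {
        "short-sf": 1200.0,
        "long-sf": 650.0,
        "short-color": 400.0,
        "long-color": 400.0,
    }


def _default_amplitudes() -> dict:
    # total pattern energy across the montage; ~0.9 µV per channel against
    # 3 µV stationary noise — calibrated once so that, at the default
    # 24-participant design, per-condition decoding and the
    # between-condition duration contrast are both adequately powered
    return {c: 4.0 for c in CONDITIONS}


@dataclass
class SyntheticConfig:
    """Ground-truth generative parameters.

    Amplitudes are in microvolts (of the unit-norm spatial pattern, i.e.
    total pattern energy), durations and times in milliseconds, gaze in
    degrees visual angle.
    """

    n_participants: int = 24
    n_trials_per_condition: int = 128
    n_channels: int = 20
    srate_hz: float = 100.0
    epoch_window_ms: tuple[float, float] = (-1500.0, 3500.0)
    transient_amplitude: float = 3.0
    transient_peak_ms: float = 120.0
    transient_sd_ms: float = 40.0
    sustained_amplitude: dict = field(default_factory=_default_amplitudes)
    sustained_duration_ms: dict = field(default_factory=_default_durations)
    relevance_pattern_amplitude: float = 2.5
    noise_sd: float = 3.0
    ar_coefficient: float = 0.9
    spatial_mixing_strength: float = 0.5
    gaze_drift_sd: float = 0.5
    gaze_coupling_amplitude: float = 0.0
    gaze_coupling_onset_ms: float = 1400.0
    accuracy: float = 0.75
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        for name in (
            "transient_amplitude",
            "relevance_pattern_amplitude",
            "noise_sd",
            "gaze_drift_sd",
            "gaze_coupling_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        missing = set(CONDITIONS) - set(self.sustained_amplitude)
        if missing:
            raise ValueError(f"sustained_amplitude missing conditions: {missing}")
        missing = set(CONDITIONS) - set(self.sustained_duration_ms)
        if missing:
            raise ValueError(f"sustained_duration_ms missing conditions: {missing}")
        lo, hi = self.epoch_window_ms
        for cond, dur in self.sustained_duration_ms.items():
            if dur < 0 or dur > hi:
                raise ValueError(
                    f"sustained duration for {cond} ({dur} ms) exceeds epoch window"
                )
            if self.sustained_amplitude[cond] < 0:
                raise ValueError("sustained amplitudes must be non-negative")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def null_config(**kwargs) -> SyntheticConfig:
    """Signal-free configuration: pure noise, amplitudes all zero."""
    base = dict(
        transient_amplitude=0.0,
        sustained_amplitude={c: 0.0 for c in CONDITIONS},
        relevance_pattern_amplitude=0.0,
    )
    base.update(kwargs)
    return SyntheticConfig(**base)


def paper_shaped_config(**kwargs) -> SyntheticConfig:
    """The default condition profile (sustained 1200/650/400/400 ms)."""
    return SyntheticConfig(**kwargs)


@dataclass
class PatternBank:
    """Orthonormal spatial patterns: one row per class plus a relevance row."""

    class_patterns: np.ndarray  # [n_classes, n_channels]
    relevance_pattern: np.ndarray  # [n_channels]

    def __post_init__(self) -> None:
        rows = np.vstack([self.class_patterns, self.relevance_pattern])
        norms = np.linalg.norm(rows, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ValueError("pattern rows must be unit-norm")
        gram = rows @ rows.T
        off = gram - np.diag(np.diag(gram))
        if np.max(np.abs(off)) > 1e-10:
            raise ValueError("pattern rows must be mutually orthogonal")

    @property
    def n_classes(self) -> int:
        return self.class_patterns.shape[0]


def make_pattern_bank(n_channels: int, n_classes: int, seed: int) -> PatternBank:
    """Draw ``n_classes + 1`` mutually orthogonal unit-norm topographies."""
    if n_channels < n_classes + 1:
        raise ValueError(
            f"need n_channels >= n_classes + 1 orthogonal directions; "
            f"got {n_channels} channels for {n_classes} classes"
        )
    rng = np.random.default_rng(seed)
    gauss = rng.normal(size=(n_channels, n_classes + 1))
    q, r = np.linalg.qr(gauss)
    q = q * np.sign(np.diag(r))  # fix the sign convention for determinism
    rows = q.T
    return PatternBank(class_patterns=rows[:n_classes], relevance_pattern=rows[-1])


def signal_envelope(t, condition: str, cfg: SyntheticConfig) -> np.ndarray:
    """Class-signal amplitude (µV) at time(s) ``t`` ms for one condition.

    Zero before stimulus onset; afterwards a Gaussian transient centred at
    ``transient_peak_ms`` plus a sustained box over
    ``[0, sustained_duration_ms[condition])``.
    """
    if condition not in cfg.sustained_amplitude:
        raise KeyError(f"unknown condition {condition!r}")
    t = np.asarray(t, dtype=float)
    post = t >= 0
    transient = cfg.transient_amplitude * np.exp(
        -((t - cfg.transient_peak_ms) ** 2) / (2 * cfg.transient_sd_ms**2)
    )
    box = (post & (t < cfg.sustained_duration_ms[condition])) * cfg.sustained_amplitude[
        condition
    ]
    return np.where(post, transient + box, 0.0)


def _relevance_envelope(t, condition: str, cfg: SyntheticConfig) -> np.ndarray:
    """Unit-shaped transient + box scaled by the relevance-pattern amplitude."""
    t = np.asarray(t, dtype=float)
    post = t >= 0
    shape = np.exp(-((t - cfg.transient_peak_ms) ** 2) / (2 * cfg.transient_sd_ms**2))
    shape = shape + (post & (t < cfg.sustained_duration_ms[condition])) * 1.0
    return np.where(post, cfg.relevance_pattern_amplitude * shape, 0.0)


def _make_noise(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    noise_sd: float,
    phi: float,
    mixing: np.ndarray,
) -> np.ndarray:
    """AR(1)-in-time noise with spatially correlated innovations.

    Innovations are ``mixing @ z`` with unit-row-norm ``mixing`` (per-channel
    unit variance), scaled by ``noise_sd * sqrt(1 - phi^2)`` so the
    stationary standard deviation is ``noise_sd``.
    """
    n_trials, n_ch, n_t = shape
    z = rng.standard_normal(shape)
    innov = np.einsum("cd,ndt->nct", mixing, z)
    innov *= noise_sd * np.sqrt(1.0 - phi**2)
    if phi == 0.0:
        return innov
    # x_t = phi x_{t-1} + e_t with a stationary draw at t = 0
    x0 = innov[:, :, 0] / np.sqrt(1.0 - phi**2)
    rest, _ = _signal.lfilter(
        [1.0], [1.0, -phi], innov[:, :, 1:], axis=2, zi=phi * x0[:, :, None]
    )
    return np.concatenate([x0[:, :, None], rest], axis=2)


def _mixing_matrix(rng: np.random.Generator, n_channels: int, strength: float) -> np.ndarray:
    m = np.eye(n_channels) + strength * rng.standard_normal((n_channels, n_channels)) / np.sqrt(
        n_channels
    )
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def _channel_labels(n_channels: int) -> list[str]:
    if n_channels == len(POSTERIOR_CHANNELS):
        return list(POSTERIOR_CHANNELS)
    return [f"CH{i + 1:02d}" for i in range(n_channels)]


#: Fixed 2-D deflection directions per stimulus class (gaze coupling).
_GAZE_DIRECTIONS = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])


def true_class_of_sf(sf_value) -> np.ndarray:
    """Ground-truth quartile class (1..4) of grid spatial frequencies."""
    idx = np.rint((np.asarray(sf_value, dtype=float) - 1.0) / 3.0 * 47).astype(int)
    return idx // 12 + 1


def simulate_participant(
    cfg: SyntheticConfig,
    bank: PatternBank,
    participant_id: str,
    seed: int,
) -> tuple[EpochedRecording, GazeRecording, pd.DataFrame]:
    """Simulate one participant's epochs, gaze and trial table.

    Trials are generated condition-blocked (all four availability x
    relevance cells, ``n_trials_per_condition`` each); spatial frequencies
    are drawn uniformly from the 48-point grid and the response-correct flag
    is Bernoulli(``accuracy``), independent of the EEG by construction.
    """
    rng = np.random.default_rng(seed)
    lo, hi = cfg.epoch_window_ms
    step = 1000.0 / cfg.srate_hz
    times = np.arange(lo, hi, step)
    n_t = len(times)
    n_cond = len(CONDITIONS)
    n_trials = n_cond * cfg.n_trials_per_condition

    sf_idx = rng.integers(0, len(SF_GRID), size=n_trials)
    sf_value = SF_GRID[sf_idx]
    true_class = sf_idx // (len(SF_GRID) // 4) + 1
    color_index = rng.integers(1, 49, size=n_trials)
    correct = rng.random(n_trials) < cfg.accuracy
    availability = np.repeat(
        [c.split("-")[0] for c in CONDITIONS], cfg.n_trials_per_condition
    )
    relevance = np.repeat(
        [c.split("-")[1] for c in CONDITIONS], cfg.n_trials_per_condition
    )

    mixing = _mixing_matrix(rng, cfg.n_channels, cfg.spatial_mixing_strength)
    data = _make_noise(
        rng,
        (n_trials, cfg.n_channels, n_t),
        cfg.noise_sd,
        cfg.ar_coefficient,
        mixing,
    )

    for ci, cond in enumerate(CONDITIONS):
        sl = slice(ci * cfg.n_trials_per_condition, (ci + 1) * cfg.n_trials_per_condition)
        env = signal_envelope(times, cond, cfg)  # [n_t]
        cls = true_class[sl]
        # class-specific signal: envelope x class pattern
        data[sl] += env[None, None, :] * bank.class_patterns[cls - 1][:, :, None]
        if cond.endswith("-sf") and cfg.relevance_pattern_amplitude > 0:
            rel = _relevance_envelope(times, cond, cfg)
            data[sl] += rel[None, None, :] * bank.relevance_pattern[None, :, None]

    # gaze: random-walk drift, optional class-coupled late deflection
    steps = rng.standard_normal((n_trials, 2, n_t)) * (
        cfg.gaze_drift_sd / np.sqrt(n_t)
    )
    gaze_data = np.cumsum(steps, axis=2)
    if cfg.gaze_coupling_amplitude > 0:
        late = times >= cfg.gaze_coupling_onset_ms
        offsets = _GAZE_DIRECTIONS[(true_class - 1) % 4] * cfg.gaze_coupling_amplitude
        gaze_data += offsets[:, :, None] * late[None, None, :]

    table = pd.DataFrame(
        {
            "sf_value": sf_value,
            "sf_class": np.zeros(n_trials, dtype=int),  # unset; binning is downstream
            "color_index": color_index,
            "availability": availability,
            "relevance": relevance,
            "correct": correct,
            "participant_id": participant_id,
        }
    )
    rec = EpochedRecording(
        data=data,
        times=times,
        srate=cfg.srate_hz,
        channel_labels=_channel_labels(cfg.n_channels),
        participant_id=participant_id,
    )
    gaze = GazeRecording(
        data=gaze_data, times=times.copy(), srate=cfg.srate_hz, participant_id=participant_id
    )
    return rec, gaze, table


def iter_dataset(cfg: SyntheticConfig):
    """Lazily simulate ``cfg.n_participants`` independent participants.

    All participants share one pattern bank (a common "head model"); each
    gets an independent seed derived from ``cfg.rng_seed``, so the dataset
    is reproducible as a whole and per participant.  Yields
    ``(EpochedRecording, GazeRecording, trial table)`` triples one at a
    time (a full multi-participant dataset is ~1 GB in memory).
    """
    ss = np.random.SeedSequence(cfg.rng_seed)
    bank = make_pattern_bank(cfg.n_channels, 4, seed=ss.spawn(1)[0].generate_state(1)[0])
    child_seeds = ss.spawn(cfg.n_participants + 1)[1:]
    for i, child in enumerate(child_seeds):
        pid = f"sim{i + 1:02d}"
        yield simulate_participant(cfg, bank, pid, seed=int(child.generate_state(1)[0]))


def generate_dataset(
    cfg: SyntheticConfig,
) -> list[tuple[EpochedRecording, GazeRecording, pd.DataFrame]]:
    """Eager form of :func:`iter_dataset`: a list of participant triples."""
    return list(iter_dataset(cfg))
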