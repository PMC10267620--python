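"""Analysis configuration: the procedural constants of the decoding pipeline.

Defaults follow the published analysis protocol this pipeline reimplements:
20 posterior channels, 8 Hz lowpass, 50 Hz decoding rate, 3-fold
cross-validation with 10 shuffle repetitions, 4 stimulus classes,
10 000 permutations at alpha = 0.05 with a 95 % decision quantile,
a [-500, 0) ms baseline, an 87-150 ms early training window and a
0-2000 ms statistical analysis window.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "POSTERIOR_CHANNELS", "load_config"]

#: The 20 posterior/occipital channels used for decoding, in analysis order.
POSTERIOR_CHANNELS = (
    "PO7", "PO3", "O1", "Oz", "POz", "Iz", "PO8", "PO4", "O2",
    "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "P9", "P10", "Pz",
)


@dataclass
class AnalysisConfig:
    """Tunable constants for preprocessing, decoding and inference."""

    channels: tuple[str, ...] = POSTERIOR_CHANNELS
    lowpass_cutoff_hz: float = 8.0
    filter_order: int = 5
    decode_srate_hz: float = 50.0
    n_folds: int = 3
    n_shuffles: int = 10
    n_classes: int = 4
    n_permutations: int = 10_000
    cluster_alpha: float = 0.05
    decision_quantile: float = 0.95
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0)
    early_train_window_ms: tuple[float, float] = (87.0, 150.0)
    analysis_window_ms: tuple[float, float] = (0.0, 2000.0)
    svm_c: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cluster_alpha < 1.0:
            raise ValueError("cluster_alpha must lie in (0, 1)")
        if not 0.0 < self.decision_quantile < 1.0:
            raise ValueError("decision_quantile must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be at least 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be at least 1")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        lo, hi = self.early_train_window_ms
        alo, ahi = self.analysis_window_ms
        if not (alo <= lo < hi <= ahi):
            raise ValueError(
                "early_train_window_ms must lie within analysis_window_ms"
            )

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)


_TUPLE_FIELDS = {
    "channels",
    "baseline_window_ms",
    "early_train_window_ms",
    "analysis_window_ms",
}


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a TOML or YAML file.

    Unspecified keys take the defaults above; unknown keys raise
    ``ValueError`` (no silent typo tolerance).
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(raw):
        raw[key] = tuple(raw[key])
    return AnalysisConfig(**raw)
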