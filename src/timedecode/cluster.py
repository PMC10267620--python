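"""Nonparametric cluster-based permutation inference on decoding time series.

Two tests operate on group-level signed distance-to-bound series:

* **within-condition** — is decoding above chance anywhere?  The observed
  statistic is the mass (summed t values) of the largest cluster of
  consecutive suprathreshold timepoints of the group one-sample t series.
  The null is built by randomly sign-flipping each evaluation's *entire*
  score time series (preserving temporal autocorrelation) and recomputing
  the largest cluster mass.
* **between-condition** — does decoding differ between two paired
  conditions?  The observed statistic is the difference of the two
  conditions' largest cluster masses; the null swaps both conditions' data
  for a random half of the participants.

Decisions use the configured null quantile (default 95 %); Monte-Carlo
p-values use the add-one rule so they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupScoreSeries",
    "Cluster",
    "ClusterTestResult",
    "one_sample_t_series",
    "find_clusters",
    "max_cluster_mass",
    "within_condition_test",
    "between_condition_test",
    "group_from_tensors",
]


@dataclass
class GroupScoreSeries:
    """Group-level decoding scores on a common time axis.

    ``evaluation_scores`` (``[n_participants, n_evaluations, n_times]``)
    are retained because the sign-flip null randomises at the evaluation
    level; ``participant_means`` is their evaluation average.
    """

    participant_means: np.ndarray  # [n_participants, n_times]
    evaluation_scores: np.ndarray  # [n_participants, n_evaluations, n_times]
    times: np.ndarray

    def __post_init__(self) -> None:
        pm = np.asarray(self.participant_means, dtype=float)
        ev = np.asarray(self.evaluation_scores, dtype=float)
        if ev.ndim != 3 or pm.shape != (ev.shape[0], ev.shape[2]):
            raise ValueError("participant_means/evaluation_scores shape mismatch")
        if not np.allclose(pm, ev.mean(axis=1), atol=1e-12):
            raise ValueError(
                "participant_means must equal the evaluation average (1e-12)"
            )
        self.participant_means = pm
        self.evaluation_scores = ev
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_participants(self) -> int:
        return self.participant_means.shape[0]


def group_from_tensors(tensors, times=None) -> GroupScoreSeries:
    """Stack per-participant diagonal ScoreTensors into a GroupScoreSeries."""
    tensors = list(tensors)
    ev = np.stack([t.diagonal_series() for t in tensors])
    if times is None:
        times = tensors[0].test_times
    return GroupScoreSeries(
        participant_means=ev.mean(axis=1), evaluation_scores=ev, times=times
    )


def one_sample_t_series(participant_means: np.ndarray) -> np.ndarray:
    """Per-timepoint one-sample t against 0, df = n - 1; zero variance -> 0."""
    x = np.asarray(participant_means, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants for a t statistic")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=sd > 0)
    return t


@dataclass
class Cluster:
    """A maximal run of consecutive suprathreshold timepoints."""

    start_ms: float
    end_ms: float  # time of the last suprathreshold sample
    start_idx: int
    end_idx: int  # inclusive
    mass: float


def _runs(above: np.ndarray):
    """(start, end) index pairs (inclusive) of True runs."""
    padded = np.concatenate([[False], above, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return zip(starts, ends)


def find_clusters(
    t_series: np.ndarray,
    df: int,
    alpha: float,
    times: np.ndarray | None = None,
    window_ms=None,
    two_sided_clusters: bool = False,
) -> list[Cluster]:
    """Positive clusters of the t series exceeding the per-timepoint threshold.

    The threshold is the upper ``1 - alpha/2`` quantile of t(df) (the
    two-sided per-timepoint test); by default only above-chance (positive)
    clusters are formed.  ``window_ms`` restricts clustering to the
    configured analysis window.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    t_series = np.asarray(t_series, dtype=float)
    if times is None:
        times = np.arange(len(t_series), dtype=float)
    times = np.asarray(times, dtype=float)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    mask = np.ones(len(t_series), dtype=bool)
    if window_ms is not None:
        start, end = window_ms
        mask = (times >= start) & (times < end)
    above = (t_series > t_crit) & mask
    if two_sided_clusters:
        above |= (t_series < -t_crit) & mask
    clusters = []
    for s, e in _runs(above):
        clusters.append(
            Cluster(
                start_ms=float(times[s]),
                end_ms=float(times[e]),
                start_idx=int(s),
                end_idx=int(e),
                mass=float(t_series[s : e + 1].sum()),
            )
        )
    return clusters


def max_cluster_mass(clusters) -> float:
    """Mass of the largest |mass| cluster; 0.0 when there is none."""
    if not clusters:
        return 0.0
    return max((c.mass for c in clusters), key=abs)


@dataclass
class ClusterTestResult:
    """Observed clusters, permutation null and decision for one test."""

    t_series: np.ndarray
    times: np.ndarray
    clusters: list[Cluster]
    observed_max_mass: float
    null_masses: np.ndarray
    p_value: float
    reject: bool
    alpha: float
    quantile_threshold: float
    statistic: str = "max_cluster_mass"
    extra: dict = field(default_factory=dict)

    @property
    def largest_cluster(self) -> Cluster | None:
        if not self.clusters:
            return None
        return max(self.clusters, key=lambda c: abs(c.mass))


def _null_max_masses_vectorised(
    t_matrix: np.ndarray, df: int, alpha: float, times, window_ms
) -> np.ndarray:
    """Largest positive cluster mass for each row of a [n_perm, T] t matrix."""
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    mask = np.ones(t_matrix.shape[1], dtype=bool)
    if window_ms is not None:
        start, end = window_ms
        times = np.asarray(times, dtype=float)
        mask = (times >= start) & (times < end)
    above = (t_matrix > t_crit) & mask
    out = np.zeros(t_matrix.shape[0])
    for p in range(t_matrix.shape[0]):
        row_above = above[p]
        if not row_above.any():
            continue
        best = 0.0
        for s, e in _runs(row_above):
            m = t_matrix[p, s : e + 1].sum()
            if m > best:
                best = m
        out[p] = best
    return out


def _t_rows(x: np.ndarray) -> np.ndarray:
    """One-sample t along axis 1 of [n_perm, n_participants, T]."""
    n = x.shape[1]
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=sd > 0)
    return t


def within_condition_test(
    group: GroupScoreSeries,
    cfg,
    seed,
    n_permutations: int | None = None,
    flip_unit: str = "evaluation",
) -> ClusterTestResult:
    """Sign-flip cluster permutation test of above-chance decoding.

    Each permutation multiplies every evaluation's whole score series by an
    independent random sign (``flip_unit="participant"`` flips whole
    participants instead), recomputes participant means, the group t series
    and the largest positive cluster mass inside the analysis window.
    """
    if flip_unit not in ("evaluation", "participant"):
        raise ValueError(f"unknown flip_unit {flip_unit!r}")
    n_perm = cfg.n_permutations if n_permutations is None else n_permutations
    alpha = cfg.cluster_alpha
    window = cfg.analysis_window_ms
    ev = group.evaluation_scores
    n_p, n_e, n_t = ev.shape
    df = n_p - 1

    t_obs = one_sample_t_series(group.participant_means)
    clusters = find_clusters(t_obs, df, alpha, group.times, window)
    observed = max_cluster_mass(clusters)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    # chunked so signs/means stay modest in memory at 10 000 permutations
    chunk = max(1, min(n_perm, int(2e8 // max(1, n_p * n_e * n_t))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        if flip_unit == "evaluation":
            signs = rng.integers(0, 2, size=(b, n_p, n_e)) * 2.0 - 1.0
            means = np.einsum("bpe,pet->bpt", signs, ev) / n_e
        else:
            signs = rng.integers(0, 2, size=(b, n_p)) * 2.0 - 1.0
            means = signs[:, :, None] * group.participant_means[None, :, :]
        t_null = _t_rows(means)
        null[done : done + b] = _null_max_masses_vectorised(
            t_null, df, alpha, group.times, window
        )
        done += b

    threshold = float(np.quantile(null, cfg.decision_quantile))
    p_value = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return ClusterTestResult(
        t_series=t_obs,
        times=group.times,
        clusters=clusters,
        observed_max_mass=observed,
        null_masses=null,
        p_value=float(p_value),
        reject=bool(observed > threshold),
        alpha=alpha,
        quantile_threshold=threshold,
        extra={"flip_unit": flip_unit, "n_permutations": n_perm},
    )


def between_condition_test(
    group_a: GroupScoreSeries,
    group_b: GroupScoreSeries,
    cfg,
    seed,
    n_permutations: int | None = None,
    signed: bool = True,
) -> ClusterTestResult:
    """Paired cluster-mass-difference permutation test between two conditions.

    The observed statistic is the (signed) difference ``D = M_A - M_B``,
    where each ``M`` is that condition's largest positive cluster mass from
    its own one-sample cluster pipeline; the test is one-sided for
    "condition A decodes more/longer than B", matching the veridical-
    difference-vs-null-quantile construction.  ``signed=False`` tests the
    absolute difference instead (direction-agnostic).  Each permutation
    exchanges condition A and B series for a seeded random half
    (``floor(n/2)``) of the participants.
    """
    if group_a.n_participants != group_b.n_participants:
        raise ValueError("paired design requires the same participants")
    if not np.array_equal(group_a.times, group_b.times):
        raise ValueError("conditions must share one time axis")
    n_perm = cfg.n_permutations if n_permutations is None else n_permutations
    alpha = cfg.cluster_alpha
    window = cfg.analysis_window_ms
    times = group_a.times
    n_p = group_a.n_participants
    df = n_p - 1

    def mass_of(means: np.ndarray) -> float:
        t = one_sample_t_series(means)
        return max_cluster_mass(find_clusters(t, df, alpha, times, window))

    def stat(ma: np.ndarray, mb: np.ndarray) -> float:
        d = mass_of(ma) - mass_of(mb)
        return d if signed else abs(d)

    a = group_a.participant_means
    b = group_b.participant_means
    observed = stat(a, b)
    t_a = one_sample_t_series(a)
    clusters = find_clusters(t_a, df, alpha, times, window)

    rng = np.random.default_rng(seed)
    half = n_p // 2
    null = np.empty(n_perm)
    for i in range(n_perm):
        swap = rng.choice(n_p, size=half, replace=False)
        pa, pb = a.copy(), b.copy()
        pa[swap], pb[swap] = b[swap], a[swap]
        null[i] = stat(pa, pb)

    threshold = float(np.quantile(null, cfg.decision_quantile))
    p_value = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return ClusterTestResult(
        t_series=t_a,
        times=times,
        clusters=clusters,
        observed_max_mass=observed,
        null_masses=null,
        p_value=float(p_value),
        reject=bool(observed > threshold),
        alpha=alpha,
        quantile_threshold=threshold,
        statistic="max_mass_difference" if signed else "abs_max_mass_difference",
        extra={"n_permutations": n_perm},
    )
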