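"""High-level simulation studies: calibration, power and confound checks.

Each study runs the full pipeline on generated data at a stated problem
size and reduces the outcome to a scalar summary (a rejection rate, an
ordering fraction, a grand-mean score).  They back the package's
reproducibility script and acceptance tests and double as usage examples
of the library API.

Problem sizes are desk-scale choices: power studies use the full 24
participants and 128 trials per condition with 2 shuffle repetitions and
500 permutations; the type-I study uses synthetic score series directly
(the sign-flip null operates on scores, not raw EEG).  docs/methods.md
discusses these choices.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal

from .cluster import (
    ClusterTestResult,
    GroupScoreSeries,
    between_condition_test,
    group_from_tensors,
    within_condition_test,
)
from .config import AnalysisConfig
from .containers import CONDITIONS
from .decode import decode_condition, prepare_condition, run_decoding
from .gaze import decode_gaze, gaze_baseline
from .preprocess import preprocess_pipeline
from .simulate import SyntheticConfig, iter_dataset, paper_shaped_config

__all__ = [
    "type_one_error_study",
    "availability_power_study",
    "chance_level_study",
    "gaze_dissociation_study",
    "significant_offset_ms",
]

#: Analysis settings shared by the simulation studies: protocol constants
#: with 2 shuffle repetitions (decoding cost scales linearly in shuffles;
#: the group-level statistics are participant-driven).
STUDY_CFG = AnalysisConfig(n_shuffles=2)


def significant_offset_ms(result: ClusterTestResult) -> float:
    """Offset (end time, ms) of the largest significant cluster, else 0."""
    lc = result.largest_cluster
    if not result.reject or lc is None:
        return 0.0
    return lc.end_ms


def _null_evaluation_scores(
    rng: np.random.Generator,
    n_participants: int,
    n_evaluations: int,
    n_times: int,
    ar: float = 0.7,
) -> np.ndarray:
    """Signal-free evaluation score series with AR(1) autocorrelation,
    mimicking the temporal smoothness of real decoding scores."""
    innov = rng.standard_normal((n_participants, n_evaluations, n_times))
    innov *= np.sqrt(1.0 - ar**2)
    x0 = innov[:, :, 0] / np.sqrt(1.0 - ar**2)
    rest, _ = _signal.lfilter(
        [1.0], [1.0, -ar], innov[:, :, 1:], axis=2, zi=ar * x0[:, :, None]
    )
    return np.concatenate([x0[:, :, None], rest], axis=2)


def type_one_error_study(
    n_datasets: int = 200,
    n_participants: int = 24,
    n_evaluations: int = 120,
    n_times: int = 100,
    n_permutations: int = 500,
    seed: int = 0,
    cfg: AnalysisConfig | None = None,
) -> dict:
    """False-positive calibration of the within-condition sign-flip test.

    Applies the test to ``n_datasets`` independent signal-free score
    datasets (default: 24 participants x 120 evaluations, the shuffle x
    fold x class evaluation count of the full protocol) and reports the
    rejection rate, which should match the nominal alpha.
    """
    cfg = cfg or AnalysisConfig()
    times = np.arange(n_times) * 20.0  # 50 Hz grid over [0, 2000) ms
    rng = np.random.default_rng(seed)
    rejections = 0
    for i in range(n_datasets):
        ev = _null_evaluation_scores(rng, n_participants, n_evaluations, n_times)
        group = GroupScoreSeries(
            participant_means=ev.mean(axis=1), evaluation_scores=ev, times=times
        )
        res = within_condition_test(
            group, cfg, seed=seed + 7919 * (i + 1), n_permutations=n_permutations
        )
        rejections += res.reject
    return {
        "rejection_rate": rejections / n_datasets,
        "n_datasets": n_datasets,
        "alpha": cfg.cluster_alpha,
    }


def _decode_group(
    dataset,
    cfg: AnalysisConfig,
    availability: str,
    relevance: str,
    base_seed: int,
) -> GroupScoreSeries:
    tensors = []
    for i, (rec, _, table) in enumerate(dataset):
        tensors.append(
            decode_condition(
                rec,
                table,
                availability,
                relevance,
                cfg,
                seed=base_seed + i,
                mode="diagonal",
                train_window_ms=cfg.analysis_window_ms,
            )
        )
    return group_from_tensors(tensors)


def availability_power_study(
    n_runs: int = 20,
    n_permutations: int = 500,
    seed: int = 0,
    syn_cfg: SyntheticConfig | None = None,
    cfg: AnalysisConfig | None = None,
) -> dict:
    """Recovery of the condition profile from end-to-end simulated runs.

    Each run simulates the full 24-participant design with the default
    sustained-duration profile (1200/650/400/400 ms for short-relevant /
    long-relevant / short-irrelevant / long-irrelevant), decodes every
    condition, and tests (a) whether the significant-decoding offsets
    recover the ordering short-relevant > long-relevant > irrelevant and
    (b) whether the between-condition test separates short- from
    long-availability in the feature-relevant conditions.
    """
    cfg = cfg or STUDY_CFG
    ordering_hits = 0
    between_rejections = 0
    offsets_acc: dict[str, list[float]] = {c: [] for c in CONDITIONS}
    for r in range(n_runs):
        run_seed = seed + 1000 * (r + 1)
        syn = (syn_cfg or paper_shaped_config()).replace(rng_seed=run_seed)
        dataset = []
        for rec, _, table in iter_dataset(syn):
            rec_p, table_p = preprocess_pipeline(rec, table, cfg, select=False)
            dataset.append((rec_p, None, table_p))
        groups = {}
        offsets = {}
        for cond in CONDITIONS:
            availability, relevance = cond.split("-")
            g = _decode_group(dataset, cfg, availability, relevance, run_seed)
            groups[cond] = g
            res = within_condition_test(
                g, cfg, seed=run_seed + 17, n_permutations=n_permutations
            )
            offsets[cond] = significant_offset_ms(res)
            offsets_acc[cond].append(offsets[cond])
        if (
            offsets["short-sf"]
            > offsets["long-sf"]
            > max(offsets["short-color"], offsets["long-color"])
        ):
            ordering_hits += 1
        bt = between_condition_test(
            groups["short-sf"],
            groups["long-sf"],
            cfg,
            seed=run_seed + 29,
            n_permutations=n_permutations,
        )
        between_rejections += bt.reject
    return {
        "n_runs": n_runs,
        "ordering_fraction": ordering_hits / n_runs,
        "between_rejection_fraction": between_rejections / n_runs,
        "mean_offsets_ms": {c: float(np.mean(v)) for c, v in offsets_acc.items()},
    }


def chance_level_study(
    n_seeds: int = 50,
    seed: int = 0,
    cfg: AnalysisConfig | None = None,
) -> dict:
    """Grand-mean signed score under label shuffling (must be ~0).

    Decodes one simulated condition repeatedly with randomly permuted class
    labels; the signed, normalised score is chance-centred at 0 by
    construction, so the grand mean over all repetitions must sit within
    sampling error of 0.
    """
    cfg = cfg or STUDY_CFG
    n_participants = max(1, n_seeds // 10)
    syn = paper_shaped_config(
        n_participants=n_participants, n_trials_per_condition=48, rng_seed=seed
    )
    means = []
    s = 0
    for rec, _, table in iter_dataset(syn):
        rec, table = preprocess_pipeline(rec, table, cfg, select=False)
        data, classes = prepare_condition(
            rec, table, "short", "sf", cfg, seed=seed + s
        )
        for _ in range(n_seeds // n_participants):
            rng = np.random.default_rng(seed + 31 * s + 1)
            st = run_decoding(
                data,
                rng.permutation(classes),
                rec.times,
                cfg,
                seed=seed + s,
                mode="diagonal",
                train_window_ms=(0.0, 1000.0),
            )
            means.append(st.scores.mean())
            s += 1
    return {
        "grand_mean_score": float(np.mean(means)),
        "n_seeds": len(means),
    }


def gaze_dissociation_study(
    n_runs: int = 20,
    n_participants: int = 10,
    n_permutations: int = 500,
    coupling_onset_ms: float = 1400.0,
    seed: int = 0,
    cfg: AnalysisConfig | None = None,
) -> dict:
    """EEG-vs-gaze cluster dissociation under late gaze-class coupling.

    Gaze becomes class-informative only from ``coupling_onset_ms``; the EEG
    class signal (long-availability relevant condition, 650 ms sustained)
    ends well before it.  A run succeeds when both cluster tests reject,
    the largest (tested) gaze cluster starts at or after the coupling onset
    and the largest EEG cluster ends before it.  (Secondary observed
    clusters are descriptive only; isolated suprathreshold timepoints are
    expected at rate alpha.)
    """
    cfg = cfg or STUDY_CFG
    # gaze clusters can extend past the EEG analysis window; follow them
    # through the delay period's end
    gaze_window = (0.0, 2800.0)
    gaze_cfg = cfg.replace(analysis_window_ms=gaze_window)
    hits = 0
    details = []
    for r in range(n_runs):
        run_seed = seed + 500 * (r + 1)
        syn = paper_shaped_config(
            n_participants=n_participants,
            gaze_coupling_amplitude=0.3,
            gaze_coupling_onset_ms=coupling_onset_ms,
            rng_seed=run_seed,
        )
        eeg_tensors, gaze_tensors = [], []
        for i, (rec, gaze, table) in enumerate(iter_dataset(syn)):
            rec_p, table_p = preprocess_pipeline(rec, table, cfg, select=False)
            eeg_tensors.append(
                decode_condition(
                    rec_p, table_p, "long", "sf", cfg, seed=run_seed + i,
                    mode="diagonal", train_window_ms=cfg.analysis_window_ms,
                )
            )
            g = gaze_baseline(gaze, cfg.baseline_window_ms)
            gaze_tensors.append(
                decode_gaze(
                    g, table, "long", "sf", cfg, seed=run_seed + i,
                    train_window_ms=gaze_window,
                )
            )
        eeg_res = within_condition_test(
            group_from_tensors(eeg_tensors), cfg, seed=run_seed + 3,
            n_permutations=n_permutations,
        )
        gaze_res = within_condition_test(
            group_from_tensors(gaze_tensors), gaze_cfg, seed=run_seed + 5,
            n_permutations=n_permutations,
        )
        eeg_end = significant_offset_ms(eeg_res)
        gaze_largest = gaze_res.largest_cluster
        gaze_start = gaze_largest.start_ms if (gaze_res.reject and gaze_largest) else None
        # cluster edges are defined to one sample; compare at that resolution
        sample_ms = float(np.diff(gaze_res.times[:2])[0]) if len(gaze_res.times) > 1 else 0.0
        ok = (
            eeg_res.reject
            and gaze_res.reject
            and 0.0 < eeg_end < coupling_onset_ms
            and gaze_start is not None
            and gaze_start >= coupling_onset_ms - sample_ms
        )
        hits += ok
        details.append(
            {"eeg_offset_ms": eeg_end, "gaze_cluster_start_ms": gaze_start, "ok": ok}
        )
    return {
        "n_runs": n_runs,
        "dissociation_fraction": hits / n_runs,
        "details": details,
    }
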