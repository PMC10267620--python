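"""Fold-averaged time-resolved multiclass decoding with temporal generalization.

The procedure, per participant and condition:

1. correct-response trials are binned into equal-count stimulus classes and
   the class counts equalised;
2. within each class, trials are randomly partitioned into ``n_folds``
   groups and averaged into fold exemplars (pseudo-trials);
3. at every training timepoint, one-versus-all linear SVMs (one per class)
   are fitted on the ``(n_folds - 1) * n_classes`` training exemplars and
   applied to the held-out fold's exemplars at every testing timepoint,
   yielding signed distances to the decision boundary;
4. distances are z-scored per classifier, signed by the true class label
   (+1 own class, -1 other), and averaged over classifiers, so chance is 0;
5. the whole procedure repeats for every fold rotation and for
   ``n_shuffles`` random repartitions.

Averaging the resulting score tensor over evaluations gives the temporal
generalization matrix (TGM); its diagonal is the timepoint-by-timepoint
decoding series used for cluster statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochedRecording, condition_key
from .preprocess import BinSpec, bin_feature, equalize_classes, filter_correct
from .svm import decision_values, fit_linear_svm_batch

__all__ = [
    "FoldSet",
    "ScoreTensor",
    "TemporalGeneralizationMatrix",
    "TimepointModel",
    "assign_folds",
    "average_folds",
    "fit_timepoint_model",
    "evaluate_generalization",
    "zscore",
    "sign_and_normalize",
    "run_decoding",
    "diagonal_of",
    "prepare_condition",
    "decode_condition",
    "cross_condition_early_train",
    "binary_condition_decoding",
]

_DEGENERATE_TOL = 1e-12


# ---------------------------------------------------------------------------
# fold machinery


@dataclass
class FoldSet:
    """Per-(fold, class) averaged exemplars for one cross-validation split."""

    exemplars: np.ndarray  # [n_folds, n_classes, n_features, n_times]
    fold_assignment: np.ndarray  # per-trial fold index, -1 = dropped
    class_labels: np.ndarray  # sorted class labels, 1..n_classes

    @property
    def n_folds(self) -> int:
        return self.exemplars.shape[0]

    @property
    def n_classes(self) -> int:
        return self.exemplars.shape[1]


def assign_folds(classes: np.ndarray, n_folds: int, seed) -> np.ndarray:
    """Seeded random partition of each class's trials into equal-size folds.

    Returns a per-trial fold index (0..n_folds-1); trials beyond the largest
    multiple of ``n_folds`` within a class are dropped (index -1, seeded
    random choice via the shuffle).
    """
    classes = np.asarray(classes)
    rng = np.random.default_rng(seed)
    assignment = np.full(len(classes), -1, dtype=int)
    for c in np.unique(classes):
        idx = np.flatnonzero(classes == c)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {c} has {len(idx)} trials; needs at least {n_folds}"
            )
        perm = rng.permutation(idx)
        per_fold = len(idx) // n_folds
        used = perm[: per_fold * n_folds]
        assignment[used] = np.repeat(np.arange(n_folds), per_fold)
    return assignment


def average_folds(data: np.ndarray, classes: np.ndarray, assignment: np.ndarray) -> FoldSet:
    """Average assigned trials into per-(fold, class) exemplars."""
    classes = np.asarray(classes)
    labels = np.unique(classes[assignment >= 0])
    n_folds = int(assignment.max()) + 1
    n, n_feat, n_t = data.shape
    ex = np.empty((n_folds, len(labels), n_feat, n_t))
    for ki, c in enumerate(labels):
        for f in range(n_folds):
            sel = (classes == c) & (assignment == f)
            if not sel.any():
                raise ValueError(f"empty (fold {f}, class {c}) cell")
            ex[f, ki] = data[sel].mean(axis=0)
    return FoldSet(exemplars=ex, fold_assignment=assignment, class_labels=labels)


# ---------------------------------------------------------------------------
# per-timepoint model (reference API; the driver below batches the same math)


@dataclass
class TimepointModel:
    """One-versus-all linear classifiers at a single training timepoint."""

    weights: np.ndarray  # [n_classes, n_features]
    bias: np.ndarray  # [n_classes]
    class_labels: np.ndarray
    degenerate: bool = False

    def distances(self, X: np.ndarray) -> np.ndarray:
        """Signed distance to bound, ``[n_points, n_classes]``."""
        X = np.atleast_2d(X)
        if X.shape[1] != self.weights.shape[1]:
            raise ValueError(
                f"feature mismatch: model has {self.weights.shape[1]}, "
                f"input has {X.shape[1]}"
            )
        if self.degenerate:
            return np.zeros((X.shape[0], len(self.class_labels)))
        return X @ self.weights.T + self.bias


def fit_timepoint_model(
    train_exemplars: np.ndarray,
    class_labels=None,
    C: float = 1.0,
) -> TimepointModel:
    """Fit one-versus-all linear SVMs on ``[n_train_folds, n_classes, F]``.

    A training set whose exemplars are all identical is flagged degenerate
    and scores zero (permutation loops must not abort on rare degenerate
    resamples).
    """
    ex = np.asarray(train_exemplars, dtype=float)
    if ex.ndim != 3:
        raise ValueError("train_exemplars must be [n_train_folds, n_classes, F]")
    n_tf, K, F = ex.shape
    if class_labels is None:
        class_labels = np.arange(1, K + 1)
    class_labels = np.asarray(class_labels)
    X = ex.reshape(n_tf * K, F)
    sample_class = np.tile(class_labels, n_tf)
    if np.ptp(X, axis=0).max() < _DEGENERATE_TOL:
        return TimepointModel(
            weights=np.zeros((K, F)),
            bias=np.zeros(K),
            class_labels=class_labels,
            degenerate=True,
        )
    Xb = np.broadcast_to(X, (K, *X.shape))
    y = np.where(sample_class[None, :] == class_labels[:, None], 1.0, -1.0)
    W, b = fit_linear_svm_batch(Xb, y, C=C)
    return TimepointModel(weights=W, bias=b, class_labels=class_labels)


def evaluate_generalization(model: TimepointModel, test_exemplars: np.ndarray) -> np.ndarray:
    """Apply one training-timepoint model to test exemplars at all times.

    ``test_exemplars``: ``[n_test_classes, n_features, n_times]``; returns
    raw signed distances ``[n_test_classes, n_model_classes, n_times]``.
    """
    te = np.asarray(test_exemplars, dtype=float)
    if te.ndim != 3:
        raise ValueError("test_exemplars must be [n_classes, n_features, n_times]")
    if te.shape[1] != model.weights.shape[1]:
        raise ValueError(
            f"feature mismatch: model has {model.weights.shape[1]} features, "
            f"test exemplars have {te.shape[1]}"
        )
    if model.degenerate:
        return np.zeros((te.shape[0], len(model.class_labels), te.shape[2]))
    return np.einsum("cf,kft->kct", model.weights, te) + model.bias[None, :, None]


# ---------------------------------------------------------------------------
# score normalisation


def zscore(x: np.ndarray, axis=None) -> np.ndarray:
    """Standardise to mean 0, sample sd 1 (ddof=1); zero variance -> zeros."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    n = x.size if axis is None else np.prod([x.shape[a] for a in np.atleast_1d(axis)])
    if n < 2:
        return np.zeros_like(x)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out


def sign_and_normalize(
    raw: np.ndarray, true_classes: np.ndarray, class_labels: np.ndarray
) -> np.ndarray:
    """Z-score per classifier, sign by true class, average over classifiers.

    ``raw``: ``[n_units, n_classifiers, *time_axes]`` — all evaluation units
    in one normalisation scope.  Each classifier's scores are z-scored over
    every unit and timepoint in scope, multiplied by +1 where the unit's
    true class is that classifier's positive class (else -1), and averaged
    over classifiers.  Chance level is 0 by construction.
    """
    raw = np.asarray(raw, dtype=float)
    true_classes = np.asarray(true_classes)
    class_labels = np.asarray(class_labels)
    n_units, n_clf = raw.shape[0], raw.shape[1]
    if len(true_classes) != n_units:
        raise ValueError("one true class per evaluation unit is required")
    scope_axes = (0, *range(2, raw.ndim))
    z = zscore(raw, axis=scope_axes)
    signs = np.where(
        true_classes[:, None] == class_labels[None, :n_clf], 1.0, -1.0
    )
    signs = signs.reshape(n_units, n_clf, *([1] * (raw.ndim - 2)))
    return (z * signs).mean(axis=1)


# ---------------------------------------------------------------------------
# results containers


@dataclass
class TemporalGeneralizationMatrix:
    """Evaluation-averaged decoding score per (train time, test time)."""

    tgm: np.ndarray  # [n_train_times, n_test_times]
    train_times: np.ndarray
    test_times: np.ndarray


@dataclass
class ScoreTensor:
    """Signed, normalised distance-to-bound scores per evaluation.

    ``scores`` is ``[n_evaluations, n_train_times, n_test_times]`` (TGM
    mode) or ``[n_evaluations, n_times]`` (diagonal mode, train = test).
    One evaluation = one (shuffle repetition, fold rotation, test-exemplar
    class); ``evaluation_index`` lists these in score order.
    """

    scores: np.ndarray
    evaluation_index: pd.DataFrame
    train_times: np.ndarray
    test_times: np.ndarray

    @property
    def diagonal_mode(self) -> bool:
        return self.scores.ndim == 2

    @property
    def n_evaluations(self) -> int:
        return self.scores.shape[0]

    def mean_tgm(self) -> TemporalGeneralizationMatrix:
        if self.diagonal_mode:
            raise ValueError("diagonal-mode scores have no full TGM")
        return TemporalGeneralizationMatrix(
            tgm=self.scores.mean(axis=0),
            train_times=self.train_times,
            test_times=self.test_times,
        )

    def diagonal_series(self) -> np.ndarray:
        """Per-evaluation diagonal score series ``[n_evaluations, n_times]``."""
        if self.diagonal_mode:
            return self.scores
        return diagonal_of_scores(self)


def diagonal_of(tgm: TemporalGeneralizationMatrix) -> np.ndarray:
    """Timepoint-by-timepoint series ``s(t) = tgm(t, t)``."""
    if tgm.tgm.shape[0] != tgm.tgm.shape[1] or not np.array_equal(
        tgm.train_times, tgm.test_times
    ):
        raise ValueError("diagonal requires a square TGM on a common time axis")
    return np.diagonal(tgm.tgm).copy()


def diagonal_of_scores(tensor: ScoreTensor) -> np.ndarray:
    if tensor.scores.shape[1] != tensor.scores.shape[2] or not np.array_equal(
        tensor.train_times, tensor.test_times
    ):
        raise ValueError("diagonal requires square score tensor on a common axis")
    return np.diagonal(tensor.scores, axis1=1, axis2=2).copy()


# ---------------------------------------------------------------------------
# the decoding driver


def _window_indices(times: np.ndarray, window_ms) -> np.ndarray:
    if window_ms is None:
        return np.arange(len(times))
    start, end = window_ms
    return np.flatnonzero((times >= start) & (times < end))


def run_decoding(
    data: np.ndarray,
    classes: np.ndarray,
    times: np.ndarray,
    cfg,
    seed,
    mode: str = "tgm",
    train_window_ms=None,
    test_window_ms=None,
) -> ScoreTensor:
    """Full fold-averaged decoding for one participant x condition.

    Parameters
    ----------
    data
        Preprocessed trials ``[n_trials, n_features, n_times]`` restricted
        to one condition, correct responses only.
    classes
        Equalised integer class labels per trial.
    times
        Time axis in ms (after downsampling).
    cfg
        :class:`~timedecode.config.AnalysisConfig`; uses ``n_folds``,
        ``n_shuffles``, ``svm_c``.
    seed
        Seeds the ``n_shuffles`` fold repartitions.
    mode
        ``"tgm"``: train at every training timepoint, test at every testing
        timepoint.  ``"diagonal"``: train time = test time only (cheaper).
    train_window_ms, test_window_ms
        Optional closed-open [ms, ms) restrictions of the two time axes.
    """
    if mode not in ("tgm", "diagonal"):
        raise ValueError(f"unknown mode {mode!r}")
    data = np.asarray(data, dtype=float)
    classes = np.asarray(classes)
    labels = np.unique(classes)
    K = len(labels)
    S, n_folds = cfg.n_shuffles, cfg.n_folds
    tr_idx = _window_indices(times, train_window_ms)
    if mode == "diagonal":
        te_idx = tr_idx
    else:
        te_idx = _window_indices(times, test_window_ms)
    if len(tr_idx) == 0:
        raise ValueError("empty training window after discretisation")
    Ttr, Tte = len(tr_idx), len(te_idx)

    ss = np.random.SeedSequence(seed)
    shuffle_seeds = [int(c.generate_state(1)[0]) for c in ss.spawn(S)]

    # fold exemplars for every shuffle: [S, n_folds, K, F, T]
    fold_sets = []
    for s in range(S):
        assignment = assign_folds(classes, n_folds, shuffle_seeds[s])
        fold_sets.append(average_folds(data, classes, assignment))
    ex = np.stack([fs.exemplars for fs in fold_sets])  # [S, folds, K, F, T]
    F = ex.shape[3]

    # training sets: for rotation r the training folds are all but r
    n_tr = (n_folds - 1) * K
    train_sets = np.empty((S, n_folds, Ttr, n_tr, F))
    for r in range(n_folds):
        others = [f for f in range(n_folds) if f != r]
        # [S, n_others, K, F, Ttr] -> [S, Ttr, n_others*K, F]
        block = ex[:, others][:, :, :, :, tr_idx]
        train_sets[:, r] = block.reshape(S, n_tr, F, Ttr).transpose(0, 3, 1, 2)
    sample_class = np.tile(labels, n_folds - 1)

    flatX = train_sets.reshape(S * n_folds * Ttr, n_tr, F)
    degenerate = np.ptp(flatX, axis=1).max(axis=1) < _DEGENERATE_TOL

    # one batched fit per one-versus-all classifier
    W = np.empty((K, S * n_folds * Ttr, F))
    B = np.empty((K, S * n_folds * Ttr))
    for ki, c in enumerate(labels):
        y = np.where(sample_class == c, 1.0, -1.0)
        W[ki], B[ki] = fit_linear_svm_batch(flatX, y, C=cfg.svm_c)
    W[:, degenerate] = 0.0
    B[:, degenerate] = 0.0
    W = W.reshape(K, S, n_folds, Ttr, F)
    B = B.reshape(K, S, n_folds, Ttr)

    # evaluate and normalise per shuffle
    out_scores = np.empty(
        (S, n_folds, K, Ttr) if mode == "diagonal" else (S, n_folds, K, Ttr, Tte)
    )
    for s in range(S):
        test_ex = ex[s][:, :, :, te_idx]  # [folds, K, F, Tte]
        if mode == "diagonal":
            # raw[r, k_test, c, t] with train time == test time
            raw = np.einsum("crtf,rkft->rkct", W[:, s], test_ex) + np.transpose(
                B[:, s], (1, 0, 2)
            )[:, None, :, :]
        else:
            raw = np.einsum("crtf,rkfu->rkctu", W[:, s], test_ex) + np.transpose(
                B[:, s], (1, 0, 2)
            )[:, None, :, :, None]
        # scope: per classifier, across folds, test classes and all times
        units = raw.reshape(n_folds * K, K, *raw.shape[3:])
        true_cls = np.repeat(np.arange(n_folds), K), np.tile(labels, n_folds)
        signed = sign_and_normalize(units, true_cls[1], labels)
        out_scores[s] = signed.reshape(n_folds, K, *raw.shape[3:])

    n_eval = S * n_folds * K
    eval_index = pd.DataFrame(
        {
            "shuffle": np.repeat(np.arange(S), n_folds * K),
            "fold": np.tile(np.repeat(np.arange(n_folds), K), S),
            "test_class": np.tile(labels, S * n_folds),
        }
    )
    return ScoreTensor(
        scores=out_scores.reshape(n_eval, *out_scores.shape[3:]),
        evaluation_index=eval_index,
        train_times=times[tr_idx].copy(),
        test_times=times[te_idx].copy(),
    )


# ---------------------------------------------------------------------------
# condition-level drivers


def prepare_condition(
    rec: EpochedRecording,
    table: pd.DataFrame,
    availability: str,
    relevance: str,
    cfg,
    seed,
    correct_only: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Select one design cell and return (data, equalised class labels).

    Applies correct-trial filtering, restricts to the requested
    availability x relevance cell, bins spatial frequency into equal-count
    classes (per participant, per condition) and equalises class counts.
    """
    condition_key(availability, relevance)
    if correct_only:
        rec, table = filter_correct(rec, table)
    sel = (
        (table["availability"] == availability) & (table["relevance"] == relevance)
    ).to_numpy()
    if not sel.any():
        raise ValueError(f"no trials in condition {availability}-{relevance}")
    sub = rec.copy_with(data=rec.data[sel])
    sub_table = table.loc[sel].reset_index(drop=True).copy()
    sub_table["sf_class"] = bin_feature(
        sub_table["sf_value"].to_numpy(), BinSpec(n_bins=cfg.n_classes)
    )
    sub, sub_table = equalize_classes(sub, sub_table, seed)
    return sub.data, sub_table["sf_class"].to_numpy()


def decode_condition(
    rec: EpochedRecording,
    table: pd.DataFrame,
    availability: str,
    relevance: str,
    cfg,
    seed,
    mode: str = "diagonal",
    train_window_ms=None,
    test_window_ms=None,
) -> ScoreTensor:
    """End-to-end decoding of one design cell for one participant."""
    ss = np.random.SeedSequence(seed)
    eq_seed, dec_seed = (int(c.generate_state(1)[0]) for c in ss.spawn(2))
    data, classes = prepare_condition(rec, table, availability, relevance, cfg, eq_seed)
    return run_decoding(
        data,
        classes,
        rec.times,
        cfg,
        dec_seed,
        mode=mode,
        train_window_ms=train_window_ms,
        test_window_ms=test_window_ms,
    )


def cross_condition_early_train(
    rec: EpochedRecording,
    table: pd.DataFrame,
    cfg,
    seed,
    relevance: str = "sf",
    test_window_ms=None,
) -> dict[str, ScoreTensor]:
    """Early-window training on pooled availability conditions.

    Trials from both availability conditions (same relevance) are pooled;
    folds are stratified by class x availability so every fold contains
    both conditions for every class.  Classifiers are fitted at each
    training timepoint inside ``cfg.early_train_window_ms`` on pooled fold
    exemplars, then tested at all timepoints separately per condition.
    Per-condition scores are averaged over training timepoints, so each
    returned ScoreTensor holds ``[n_evaluations, n_test_times]``.
    """
    ss = np.random.SeedSequence(seed)
    eq_seed, dec_seed = (int(c.generate_state(1)[0]) for c in ss.spawn(2))
    rec_c, table_c = filter_correct(rec, table)
    sel = (table_c["relevance"] == relevance).to_numpy()
    if not sel.any():
        raise ValueError(f"no trials with relevance {relevance!r}")
    data = rec_c.data[sel]
    sub = table_c.loc[sel].reset_index(drop=True).copy()
    sub["sf_class"] = bin_feature(sub["sf_value"].to_numpy(), BinSpec(cfg.n_classes))
    avail = sub["availability"].to_numpy()
    classes = sub["sf_class"].to_numpy()

    # equalise counts over the class x availability cells so stratified
    # folding is balanced
    cell = np.array([f"{a}|{c}" for a, c in zip(avail, classes)])
    counts = pd.Series(cell).value_counts()
    m = int(counts.min())
    rng = np.random.default_rng(eq_seed)
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(np.flatnonzero(cell == lab), size=m, replace=False)
                for lab in np.unique(cell)
            ]
        )
    )
    data, classes, avail, cell = data[keep], classes[keep], avail[keep], cell[keep]

    times = rec.times
    tr_idx = _window_indices(times, cfg.early_train_window_ms)
    if len(tr_idx) == 0:
        raise ValueError("empty early training window after discretisation")
    te_idx = _window_indices(times, test_window_ms)
    labels = np.unique(classes)
    K = len(labels)
    S, n_folds = cfg.n_shuffles, cfg.n_folds
    Ttr, Tte = len(tr_idx), len(te_idx)
    avail_levels = sorted(set(avail))

    shuffle_seeds = [int(c.generate_state(1)[0]) for c in np.random.SeedSequence(dec_seed).spawn(S)]
    # strata codes for fold assignment: class x availability
    strata = pd.factorize(cell)[0]

    per_cond_scores = {
        a: np.empty((S, n_folds, K, Tte)) for a in avail_levels
    }
    for s in range(S):
        assignment = assign_folds(strata, n_folds, shuffle_seeds[s])
        pooled = average_folds(data, classes, assignment)  # pooled exemplars
        # per-condition test exemplars within each fold
        cond_ex = {}
        for a in avail_levels:
            mask_a = avail == a
            cond_ex[a] = average_folds(
                data[mask_a], classes[mask_a], assignment[mask_a]
            ).exemplars[:, :, :, te_idx]
        n_tr = (n_folds - 1) * K
        sample_class = np.tile(labels, n_folds - 1)
        train_sets = np.empty((n_folds, Ttr, n_tr, data.shape[1]))
        for r in range(n_folds):
            others = [f for f in range(n_folds) if f != r]
            block = pooled.exemplars[others][:, :, :, tr_idx]
            train_sets[r] = block.reshape(n_tr, data.shape[1], Ttr).transpose(2, 0, 1)
        flatX = train_sets.reshape(n_folds * Ttr, n_tr, data.shape[1])
        degenerate = np.ptp(flatX, axis=1).max(axis=1) < _DEGENERATE_TOL
        W = np.empty((K, n_folds * Ttr, data.shape[1]))
        B = np.empty((K, n_folds * Ttr))
        for ki, c in enumerate(labels):
            y = np.where(sample_class == c, 1.0, -1.0)
            W[ki], B[ki] = fit_linear_svm_batch(flatX, y, C=cfg.svm_c)
        W[:, degenerate] = 0.0
        B[:, degenerate] = 0.0
        W = W.reshape(K, n_folds, Ttr, data.shape[1])
        B = B.reshape(K, n_folds, Ttr)

        # raw[a][r, k, c, t_train, t_test]; both conditions share one z scope
        raws = []
        for a in avail_levels:
            raw = np.einsum("crtf,rkfu->rkctu", W, cond_ex[a]) + np.transpose(
                B, (1, 0, 2)
            )[:, None, :, :, None]
            raws.append(raw)
        stacked = np.stack(raws)  # [n_avail, folds, K, K, Ttr, Tte]
        units = stacked.reshape(len(avail_levels) * n_folds * K, K, Ttr, Tte)
        true_cls = np.tile(labels, len(avail_levels) * n_folds)
        signed = sign_and_normalize(units, true_cls, labels)
        signed = signed.reshape(len(avail_levels), n_folds, K, Ttr, Tte)
        for ai, a in enumerate(avail_levels):
            per_cond_scores[a][s] = signed[ai].mean(axis=2)  # avg train times

    out = {}
    eval_index = pd.DataFrame(
        {
            "shuffle": np.repeat(np.arange(S), n_folds * K),
            "fold": np.tile(np.repeat(np.arange(n_folds), K), S),
            "test_class": np.tile(labels, S * n_folds),
        }
    )
    for a in avail_levels:
        out[a] = ScoreTensor(
            scores=per_cond_scores[a].reshape(S * n_folds * K, Tte),
            evaluation_index=eval_index.copy(),
            train_times=times[te_idx].copy(),
            test_times=times[te_idx].copy(),
        )
    return out


def binary_condition_decoding(
    data_a: np.ndarray,
    data_b: np.ndarray,
    times: np.ndarray,
    cfg,
    seed,
    mode: str = "diagonal",
    train_window_ms=None,
    test_window_ms=None,
) -> ScoreTensor:
    """Binary decoding of condition membership, regardless of stimulus class.

    ``data_a``/``data_b``: preprocessed trials from the two conditions; the
    larger set is subsampled (seeded) so counts are equalised, then the
    standard machinery runs with classes = {1: A, 2: B}.
    """
    ss = np.random.SeedSequence(seed)
    eq_seed, dec_seed = (int(c.generate_state(1)[0]) for c in ss.spawn(2))
    rng = np.random.default_rng(eq_seed)
    m = min(len(data_a), len(data_b))
    if m < cfg.n_folds:
        raise ValueError("too few trials per condition for the fold count")
    a_idx = np.sort(rng.choice(len(data_a), size=m, replace=False))
    b_idx = np.sort(rng.choice(len(data_b), size=m, replace=False))
    data = np.concatenate([np.asarray(data_a)[a_idx], np.asarray(data_b)[b_idx]])
    classes = np.repeat([1, 2], m)
    return run_decoding(
        data,
        classes,
        times,
        cfg,
        dec_seed,
        mode=mode,
        train_window_ms=train_window_ms,
        test_window_ms=test_window_ms,
    )
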