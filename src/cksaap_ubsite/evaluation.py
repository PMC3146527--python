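"""Performance assessment: confusion metrics, ROC/AUC, k-fold
cross-validation and mean +/- SD aggregation over negative resamplings.

The evaluation protocol mirrors the predictor's study design: a balanced
(1:1) set of positive and resampled negative sites is scored by k-fold
cross-validation (100 folds by default, so folds of 5-6 samples on ~526);
out-of-fold decision scores are pooled into one ROC, and single-point
Ac/Sn/Sp/MCC are taken at the SVM's natural decision boundary (score 0).
The whole procedure is repeated over several seeded negative subsets and
each metric is reported as mean +/- sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .encoding import encode_dataset, padded_window
from .model import SvmParams, stratified_folds, train_svm
from .sequence_io import SiteDataset

METRIC_NAMES = ("Ac", "Sn", "Sp", "MCC")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and Matthews correlation
    coefficient of a confusion matrix.

    ``Sn = tp/(tp+fn)``, ``Sp = tn/(tn+fp)``, ``Ac = (tp+tn)/total`` and
    ``MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))``, with MCC
    defined as 0 when any factor of the denominator vanishes.
    """
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("confusion metrics need at least one sample per class")
    total = c.tp + c.fp + c.fn + c.tn
    sn = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    ac = (c.tp + c.tn) / total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom)
    return {"Ac": ac, "Sn": sn, "Sp": sp, "MCC": float(mcc)}


def counts_at_threshold(
    scores: np.ndarray, y: np.ndarray, threshold: float = 0.0
) -> ConfusionCounts:
    """Confusion counts calling positive iff ``score >= threshold``."""
    scores = np.asarray(scores)
    y = np.asarray(y)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
    )


def roc_and_auc(
    scores: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC from scores and 0/1 labels.

    The curve sweeps every distinct score threshold (tied scores form a
    single step), starts at (0, 0) and ends at (1, 1).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores), drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class CVResult:
    """Pooled out-of-fold evaluation of one balanced dataset."""

    scores: np.ndarray  # out-of-fold score per sample, input order
    y: np.ndarray
    fold_of: np.ndarray  # fold index each sample was tested in
    metrics: dict[str, float]
    confusion: ConfusionCounts
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 100,
    params: SvmParams = SvmParams(),
    seed: int = 0,
) -> CVResult:
    """Seeded stratified k-fold cross-validation.

    Each sample is scored exactly once, by the model trained on the other
    folds; pooled scores give a single ROC/AUC, and confusion metrics are
    computed at the natural threshold 0.  ``folds == n`` is the jackknife
    (leave-one-out) limit.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    fold_indices = stratified_folds(y, folds, seed)
    scores = np.empty(len(y))
    fold_of = np.empty(len(y), dtype=int)
    for f, test_idx in enumerate(fold_indices):
        if len(test_idx) == 0:
            continue
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        clf = train_svm(X[train_mask], y[train_mask], params)
        scores[test_idx] = clf.decision_function(X[test_idx])
        fold_of[test_idx] = f
    confusion = counts_at_threshold(scores, y, 0.0)
    fpr, tpr, auc = roc_and_auc(scores, y)
    return CVResult(
        scores=scores,
        y=y,
        fold_of=fold_of,
        metrics=confusion_metrics(confusion),
        confusion=confusion,
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc=auc,
    )


@dataclass
class EvaluationReport:
    """Per-repeat metrics plus mean +/- SD aggregates over negative
    resamplings."""

    per_repeat: pd.DataFrame  # columns: repeat, seed, Ac, Sn, Sp, MCC, AUC
    mean: pd.Series
    sd: pd.Series
    cv_results: list[CVResult] = field(default_factory=list)


def repeated_resampling_eval(
    X_pos: np.ndarray,
    X_neg_pool: np.ndarray,
    repeats: int = 10,
    folds: int = 100,
    params: SvmParams = SvmParams(),
    seed: int = 0,
) -> EvaluationReport:
    """Repeat balanced cross-validation over seeded negative resamplings.

    Each repeat draws ``|positives|`` negatives from the pool without
    replacement, runs :func:`cross_validate`, and contributes one row of
    metrics; aggregates are the mean and sample SD (``ddof=1``; 0 when
    ``repeats == 1``) across repeats.
    """
    X_pos = np.asarray(X_pos)
    X_neg_pool = np.asarray(X_neg_pool)
    n_pos = len(X_pos)
    if len(X_neg_pool) < n_pos:
        raise ValueError("negative pool smaller than positive set")
    rng = np.random.default_rng(seed)
    repeat_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=repeats)]
    rows = []
    cv_results = []
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_pos, dtype=int)])
    for r, rseed in enumerate(repeat_seeds):
        idx = np.random.default_rng(rseed).choice(
            len(X_neg_pool), size=n_pos, replace=False
        )
        X = np.vstack([X_pos, X_neg_pool[idx]])
        cv = cross_validate(X, y, folds=folds, params=params, seed=rseed)
        cv_results.append(cv)
        rows.append({"repeat": r, "seed": rseed, **cv.metrics, "AUC": cv.auc})
    per_repeat = pd.DataFrame(rows)
    metric_cols = list(METRIC_NAMES) + ["AUC"]
    mean = per_repeat[metric_cols].mean()
    sd = (
        per_repeat[metric_cols].std(ddof=1)
        if repeats > 1
        else pd.Series(0.0, index=metric_cols)
    )
    return EvaluationReport(per_repeat=per_repeat, mean=mean, sd=sd, cv_results=cv_results)


def position_enrichment(
    dataset: SiteDataset, alpha: float = 0.05, bonferroni: bool = False
) -> pd.DataFrame:
    """Per-(window position, residue) enrichment/depletion around the
    central lysine.

    For each non-center window position (relative coordinates -n..+n) and
    each residue, the 0/1 occurrence indicator is compared between positive
    and negative fragments with a two-sample pooled-variance t-test.  The
    result has one row per (position, residue) seen in the data, with the
    composition difference, t statistic, P-value, direction
    (``enriched``/``depleted`` in positives) and a significance flag at
    ``alpha`` (Bonferroni-corrected across rows when requested).
    """
    pos_idx = dataset.positives
    neg_idx = dataset.negatives
    if not pos_idx or not neg_idx:
        raise ValueError("position enrichment requires both classes")
    window = dataset.window
    n = (window - 1) // 2
    padded = [padded_window(f, window) for f in dataset.fragments]
    rows = []
    for j in range(window):
        if j == n:
            continue
        rel = j - n
        col = np.array([p[j] for p in padded])
        for res in sorted(set(col) - {"O"}):
            ind = (col == res).astype(float)
            a, b = ind[pos_idx], ind[neg_idx]
            if a.std() == 0 and b.std() == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=True)
            delta = float(a.mean() - b.mean())
            rows.append(
                {
                    "position": rel,
                    "residue": res,
                    "delta": delta,
                    "t": float(t),
                    "p": float(p),
                    "direction": "enriched" if delta > 0 else "depleted",
                }
            )
    df = pd.DataFrame(rows)
    cutoff = alpha / len(df) if bonferroni and len(df) else alpha
    df["significant"] = df["p"] < cutoff
    return df


def evaluate_dataset(
    dataset: SiteDataset,
    repeats: int = 10,
    folds: int = 100,
    params: SvmParams = SvmParams(),
    k_max: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Convenience wrapper: encode a labeled dataset and run the repeated
    balanced-resampling evaluation."""
    X = encode_dataset(dataset, k_max=k_max)
    pos = dataset.positives
    neg = dataset.negatives
    return repeated_resampling_eval(
        X[pos], X[neg], repeats=repeats, folds=folds, params=params, seed=seed
    )
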