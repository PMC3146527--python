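"""RBF-kernel SVM training, hyperparameter grid search, the negative-
resampling ensemble and FPR-calibrated decision thresholds.

Positive (ubiquitination) sites are heavily outnumbered by candidate
negatives, so a single balanced training set wastes most of the negative
pool.  The predictor therefore trains ``n_members`` SVMs (10 by default),
each on all positives plus a different seeded random negative subset of
equal size, and scores a query by the arithmetic mean of the members' signed
decision values.  The kernel is ``K(u, v) = exp(-gamma * ||u - v||^2)``
(the libsvm / SVM-light convention: gamma multiplies the squared distance);
raw decision values are used as scores, with no probability calibration.

Operating thresholds are calibrated empirically: for a requested false
positive rate level (2% and 10% by default), the threshold is the smallest
score cutoff whose empirical FPR on a reference negative set does not exceed
the level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .encoding import cksaap_encode, encode_dataset

#: grid-search defaults: C in [0.5, 8.0], gamma in [0.5, 16.0], step 0.5
DEFAULT_C_RANGE = (0.5, 8.0)
DEFAULT_GAMMA_RANGE = (0.5, 16.0)
DEFAULT_GRID_STEP = 0.5

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SvmParams:
    """RBF-SVM hyperparameters (defaults are the tool's optimum)."""

    c: float = 2.0
    gamma: float = 8.0

    def __post_init__(self) -> None:
        if not (self.c > 0 and np.isfinite(self.c)):
            raise ValueError(f"C must be positive finite, got {self.c}")
        if not (self.gamma > 0 and np.isfinite(self.gamma)):
            raise ValueError(f"gamma must be positive finite, got {self.gamma}")


def train_svm(X: np.ndarray, y: np.ndarray, params: SvmParams = SvmParams()) -> SVC:
    """Fit a C-SVC with RBF kernel; returns the fitted classifier whose
    ``decision_function`` gives the real-valued score (higher = more
    ubiquitination-like).  Deterministic given the data and parameters."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    clf = SVC(kernel="rbf", C=params.c, gamma=params.gamma)
    clf.fit(np.asarray(X), y)
    return clf


def stratified_folds(
    y: np.ndarray, folds: int, seed: int
) -> list[np.ndarray]:
    """Seeded stratified partition of sample indices into ``folds`` parts.

    Each class is shuffled and dealt round-robin, so folds stay close to the
    overall class balance.  Unlike scikit-learn's StratifiedKFold this
    remains valid down to leave-one-out (``folds == n``), where some folds
    are single-class singletons.
    """
    y = np.asarray(y)
    n = len(y)
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds sample count ({n})")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    slot = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i in idx:
            assignment[i] = slot % folds
            slot += 1
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def param_grid(
    c_range: tuple[float, float] = DEFAULT_C_RANGE,
    gamma_range: tuple[float, float] = DEFAULT_GAMMA_RANGE,
    step: float = DEFAULT_GRID_STEP,
) -> list[SvmParams]:
    """Enumerate the (C, gamma) grid, both ends inclusive.  The defaults give
    16 x 32 = 512 points."""
    cs = np.arange(c_range[0], c_range[1] + step / 2, step)
    gammas = np.arange(gamma_range[0], gamma_range[1] + step / 2, step)
    if cs.size == 0 or gammas.size == 0:
        raise ValueError("empty parameter range")
    return [SvmParams(float(c), float(g)) for c in cs for g in gammas]


def grid_search(
    data: tuple[np.ndarray, np.ndarray] | Sequence[tuple[np.ndarray, np.ndarray]],
    c_range: tuple[float, float] = DEFAULT_C_RANGE,
    gamma_range: tuple[float, float] = DEFAULT_GAMMA_RANGE,
    step: float = DEFAULT_GRID_STEP,
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[SvmParams, np.ndarray]:
    """Pick (C, gamma) by cross-validated mean accuracy over the grid.

    ``data`` is a single ``(X, y)`` pair or a list of them (e.g. the balanced
    sets from several negative resamplings); the criterion is the accuracy
    averaged over every fold of every dataset, and the argmax is returned
    together with the per-point mean accuracies in grid order.  Ties go to
    the earliest grid point, so the result is deterministic under a seed.
    """
    if isinstance(data, tuple):
        datasets = [data]
    else:
        datasets = list(data)
    grid = param_grid(c_range, gamma_range, step)
    fold_plans = [
        (np.asarray(X), np.asarray(y), stratified_folds(y, cv_folds, seed + 31 * j))
        for j, (X, y) in enumerate(datasets)
    ]
    accuracies = np.zeros(len(grid))
    for gi, params in enumerate(grid):
        correct = 0
        total = 0
        for X, y, folds in fold_plans:
            for test_idx in folds:
                train_mask = np.ones(len(y), dtype=bool)
                train_mask[test_idx] = False
                clf = train_svm(X[train_mask], y[train_mask], params)
                pred = (clf.decision_function(X[test_idx]) > 0).astype(int)
                correct += int((pred == y[test_idx]).sum())
                total += len(test_idx)
        accuracies[gi] = correct / total
    return grid[int(np.argmax(accuracies))], accuracies


@dataclass
class ModelEnsemble:
    """The trained predictor: member SVMs sharing hyperparameters and
    encoder configuration, plus calibrated score thresholds."""

    members: list[SVC]
    member_seeds: list[int]
    member_negative_indices: list[np.ndarray]
    params: SvmParams
    window: int = 27
    k_max: int = 5
    thresholds: dict[float, float] = field(default_factory=dict)
    master_seed: int | None = None

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Per-member decision values, shape (n_members, n_samples)."""
        X = np.atleast_2d(np.asarray(X))
        return np.vstack([m.decision_function(X) for m in self.members])

    def score(self, X: np.ndarray) -> np.ndarray:
        """Ensemble score: mean of member decision values."""
        return self.decision_values(X).mean(axis=0)


def train_ensemble(
    X_pos: np.ndarray,
    X_neg_pool: np.ndarray,
    n_members: int = 10,
    params: SvmParams = SvmParams(),
    seed: int = 0,
    window: int = 27,
    k_max: int = 5,
) -> ModelEnsemble:
    """Train the negative-resampling ensemble.

    Each member sees all positives plus a seeded random negative subset of
    size ``|positives|`` drawn without replacement from the pool (a balanced
    1:1 set).  Member seeds and subset indices are recorded so the model is
    fully reproducible.
    """
    X_pos = np.asarray(X_pos)
    X_neg_pool = np.asarray(X_neg_pool)
    n_pos = len(X_pos)
    if len(X_neg_pool) < n_pos:
        raise ValueError(
            f"negative pool ({len(X_neg_pool)}) smaller than positive set ({n_pos})"
        )
    rng = np.random.default_rng(seed)
    member_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_members)]
    members: list[SVC] = []
    subsets: list[np.ndarray] = []
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_pos, dtype=int)])
    for mseed in member_seeds:
        idx = np.random.default_rng(mseed).choice(
            len(X_neg_pool), size=n_pos, replace=False
        )
        idx.sort()
        subsets.append(idx)
        X = np.vstack([X_pos, X_neg_pool[idx]])
        members.append(train_svm(X, y, params))
    return ModelEnsemble(
        members=members,
        member_seeds=member_seeds,
        member_negative_indices=subsets,
        params=params,
        window=window,
        k_max=k_max,
        master_seed=seed,
    )


def predict_score(ensemble: ModelEnsemble, fragment_or_X) -> np.ndarray | float:
    """Score fragments with the ensemble (mean of member decision values).

    Accepts a :class:`~cksaap_ubsite.sequence_io.Fragment`, a list of them,
    or an already-encoded feature matrix.
    """
    from .sequence_io import Fragment  # local import to avoid cycle at import time

    if isinstance(fragment_or_X, Fragment):
        return float(ensemble.score(cksaap_encode(fragment_or_X, ensemble.k_max))[0])
    if (
        isinstance(fragment_or_X, (list, tuple))
        and fragment_or_X
        and isinstance(fragment_or_X[0], Fragment)
    ):
        X = encode_dataset(fragment_or_X, ensemble.k_max)
        return ensemble.score(X)
    return ensemble.score(np.asarray(fragment_or_X))


def calibrate_from_scores(
    negative_scores: np.ndarray, fpr_levels: Sequence[float] = (0.02, 0.10)
) -> dict[float, float]:
    """For each level, the smallest cutoff whose empirical FPR (fraction of
    negative scores >= cutoff) does not exceed the level."""
    neg = np.sort(np.asarray(negative_scores, dtype=float))
    if neg.size == 0:
        raise ValueError("threshold calibration requires negative samples")
    n = neg.size
    thresholds: dict[float, float] = {}
    # candidate cutoffs: each negative score, plus one past the maximum
    candidates = np.append(np.unique(neg), neg[-1] + 1.0)
    for level in fpr_levels:
        for cut in candidates:
            fpr = np.count_nonzero(neg >= cut) / n
            if fpr <= level:
                thresholds[level] = float(cut)
                break
    return thresholds


def calibrate_thresholds(
    ensemble: ModelEnsemble,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    fpr_levels: Sequence[float] = (0.02, 0.10),
    scores: np.ndarray | None = None,
) -> dict[float, float]:
    """Calibrate and store the ensemble's score cutoffs at the given FPR
    levels, using the negatives of the calibration set.  Pre-computed
    calibration scores (e.g. pooled out-of-fold scores) may be supplied via
    ``scores``."""
    y_cal = np.asarray(y_cal)
    if not np.any(y_cal == 0):
        raise ValueError("calibration set contains no negatives")
    if scores is None:
        scores = ensemble.score(np.asarray(X_cal))
    thresholds = calibrate_from_scores(np.asarray(scores)[y_cal == 0], fpr_levels)
    ensemble.thresholds.update(thresholds)
    return thresholds


def save_ensemble(ensemble: ModelEnsemble, path: str | Path) -> None:
    """Serialize the ensemble (members, seeds, params, thresholds, encoder
    config) to a single file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": {"c": ensemble.params.c, "gamma": ensemble.params.gamma},
        "window": ensemble.window,
        "k_max": ensemble.k_max,
        "thresholds": dict(ensemble.thresholds),
        "master_seed": ensemble.master_seed,
        "member_seeds": list(ensemble.member_seeds),
        "member_negative_indices": [
            np.asarray(i) for i in ensemble.member_negative_indices
        ],
        "members": ensemble.members,
    }
    joblib.dump(payload, path)


def load_ensemble(path: str | Path) -> ModelEnsemble:
    """Load an ensemble written by :func:`save_ensemble`."""
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format in {path}")
    return ModelEnsemble(
        members=payload["members"],
        member_seeds=payload["member_seeds"],
        member_negative_indices=payload["member_negative_indices"],
        params=SvmParams(**payload["params"]),
        window=payload["window"],
        k_max=payload["k_max"],
        thresholds=payload["thresholds"],
        master_seed=payload["master_seed"],
    )
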