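"""Chi-squared and information-gain rankings of CKSAAP features.

Composition features are sparse, so each feature is binarized to
presence (composition > 0) / absence before scoring against the class label:

* CHI — the chi-squared statistic of the 2x2 presence-by-class table,
  without continuity correction.
* IG — the mutual information between presence and class,
  ``H(class) - H(class | presence)``, in bits.

Both scores are 0 exactly when presence is independent of the class
in-sample.  Rankings must be computed on training folds only; callers pass a
fold-restricted feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class FeatureRanking:
    """Scores and the induced descending order for one ranking method."""

    method: str  # "CHI" or "IG"
    names: list[str]
    scores: np.ndarray
    order: list[str]  # names sorted by descending score, ties by name

    def top(self, n: int) -> list[str]:
        return self.order[:n]


def _presence_table(X: np.ndarray, y: np.ndarray):
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("feature scoring requires both classes present")
    pres = np.asarray(X) > 0
    a = pres[y == 1].sum(axis=0).astype(float)  # present, positive
    c = pres[y == 0].sum(axis=0).astype(float)  # present, negative
    n_pos = float((y == 1).sum())
    n_neg = float((y == 0).sum())
    return a, n_pos - a, c, n_neg - c  # a, b, c, d of the 2x2 table


def chi_squared_scores(
    X: np.ndarray, y: np.ndarray, names: Sequence[str]
) -> FeatureRanking:
    """Rank features by the chi-squared statistic of presence vs class."""
    a, b, c, d = _presence_table(X, y)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        num = n * (a * d - b * c) ** 2
        den = (a + b) * (c + d) * (a + c) * (b + d)
        scores = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return _build_ranking("CHI", names, scores)


def _bernoulli_entropy(p: np.ndarray) -> np.ndarray:
    """H(p) in bits, with 0 log 0 = 0."""
    p = np.clip(p, 0.0, 1.0)
    out = np.zeros_like(p)
    for q in (p, 1.0 - p):
        mask = q > 0
        out[mask] -= q[mask] * np.log2(q[mask])
    return out


def information_gain_scores(
    X: np.ndarray, y: np.ndarray, names: Sequence[str]
) -> FeatureRanking:
    """Rank features by information gain of the class given presence."""
    a, b, c, d = _presence_table(X, y)
    n = a + b + c + d
    h_class = _bernoulli_entropy(np.atleast_1d((a + b) / n))
    p_pres = (a + c) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h_pres = _bernoulli_entropy(np.where(a + c > 0, a / np.maximum(a + c, 1), 0.0))
        h_abs = _bernoulli_entropy(np.where(b + d > 0, b / np.maximum(b + d, 1), 0.0))
    scores = h_class - p_pres * h_pres - (1.0 - p_pres) * h_abs
    scores = np.maximum(scores, 0.0)  # clip tiny negative round-off
    return _build_ranking("IG", names, scores)


def _build_ranking(
    method: str, names: Sequence[str], scores: np.ndarray
) -> FeatureRanking:
    names = list(names)
    if len(names) != len(scores):
        raise ValueError("names and scores length mismatch")
    order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    return FeatureRanking(method, names, scores, [names[i] for i in order])


def top_features(ranking: FeatureRanking, n: int) -> list[str]:
    """The first ``n`` features of the ranking (all of them if ``n`` exceeds
    the feature count)."""
    return ranking.top(n)


def top_intersection(r1: FeatureRanking, r2: FeatureRanking, n: int) -> set[str]:
    """Features shared by the two rankings' top-``n`` lists."""
    return set(r1.top(n)) & set(r2.top(n))
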