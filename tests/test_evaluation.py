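"""Confusion metrics, ROC/AUC, cross-validation and resampling aggregation."""

import itertools
import math

import numpy as np
import pytest

from cksaap_ubsite import (
    ConfusionCounts,
    FixtureConfig,
    confusion_metrics,
    cross_validate,
    encode_dataset,
    generate_fixture,
    position_enrichment,
    repeated_resampling_eval,
    roc_and_auc,
)
from cksaap_ubsite.evaluation import counts_at_threshold
from cksaap_ubsite.model import SvmParams
from scipy import stats


def direct_metrics(tp, fp, fn, tn):
    """Straight transcription of the four metric formulas."""
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    ac = (tp + tn) / (tp + fp + fn + tn)
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if den == 0 else (tp * tn - fp * fn) / den
    return {"Ac": ac, "Sn": sn, "Sp": sp, "MCC": mcc}


def mann_whitney_auc(scores, y):
    """AUC as the normalized U statistic: P(pos > neg) + 0.5 P(tie), by
    brute force over all positive-negative pairs."""
    pos = [s for s, l in zip(scores, y) if l == 1]
    neg = [s for s, l in zip(scores, y) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=10))
        assert m == {"Ac": 1.0, "Sn": 1.0, "Sp": 1.0, "MCC": 1.0}

    def test_chance_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=5, fp=5, fn=5, tn=5))
        assert m["Ac"] == pytest.approx(0.5) and m["MCC"] == pytest.approx(0.0)

    def test_hand_worked_case(self):
        m = confusion_metrics(ConfusionCounts(tp=70, fp=23, fn=30, tn=77))
        assert m["Ac"] == pytest.approx(0.735)
        assert m["Sn"] == pytest.approx(0.70)
        assert m["Sp"] == pytest.approx(0.77)
        assert m["MCC"] == pytest.approx(direct_metrics(70, 23, 30, 77)["MCC"])

    def test_enumerated_small_matrices_match_direct_formulas(self):
        for tp, fp, fn, tn in itertools.product(range(4), repeat=4):
            if tp + fn == 0 or tn + fp == 0:
                with pytest.raises(ValueError):
                    confusion_metrics(ConfusionCounts(tp, fp, fn, tn))
                continue
            got = confusion_metrics(ConfusionCounts(tp, fp, fn, tn))
            want = direct_metrics(tp, fp, fn, tn)
            for key in want:
                assert got[key] == pytest.approx(want[key]), (tp, fp, fn, tn)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([3.0, 2.0, -1.0, -2.0])
        y = np.array([1, 1, 0, 0])
        fpr, tpr, auc = roc_and_auc(scores, y)
        assert auc == pytest.approx(1.0)
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0

    def test_chance_limit(self, rng):
        scores = rng.normal(size=4000)
        y = rng.integers(0, 2, size=4000)
        _, _, auc = roc_and_auc(scores, y)
        assert 0.45 < auc < 0.55

    def test_monotone_curve(self, rng):
        scores = rng.normal(size=100)
        y = rng.integers(0, 2, size=100)
        fpr, tpr, _ = roc_and_auc(scores, y)
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_auc_equals_u_statistic_exhaustively_small_n(self, rng):
        """Trapezoidal AUC must equal the normalized Mann-Whitney U for every
        small labeled score set, including ties."""
        for n in range(2, 13):
            for _ in range(30):
                y = rng.integers(0, 2, size=n)
                if len(np.unique(y)) < 2:
                    continue
                scores = rng.integers(-2, 3, size=n).astype(float)  # force ties
                _, _, auc = roc_and_auc(scores, y)
                assert auc == pytest.approx(mann_whitney_auc(scores, y))


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(12)
    X = np.vstack([rng.normal(1, 1, (30, 3)), rng.normal(-1, 1, (30, 3))])
    y = np.repeat([1, 0], 30)
    return X, y


@pytest.fixture(scope="module")
def pools():
    rng = np.random.default_rng(8)
    X_pos = rng.normal(0.8, 1, (25, 4))
    X_neg = rng.normal(-0.8, 1, (100, 4))
    return X_pos, X_neg


class TestCrossValidate:
    def test_leave_one_out_on_tiny_set(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(2, 0.5, (5, 2)), rng.normal(-2, 0.5, (5, 2))])
        y = np.repeat([1, 0], 5)
        cv = cross_validate(X, y, folds=10, params=SvmParams(2.0, 1.0), seed=0)
        assert set(cv.metrics) == {"Ac", "Sn", "Sp", "MCC"}
        assert cv.metrics["Ac"] > 0.8

    def test_each_sample_tested_exactly_once(self, toy):
        X, y = toy
        cv = cross_validate(X, y, folds=10, seed=1)
        counts = np.bincount(cv.fold_of, minlength=10)
        assert counts.sum() == len(y)
        assert np.isfinite(cv.scores).all()

    def test_seed_determinism(self, toy):
        X, y = toy
        a = cross_validate(X, y, folds=6, seed=5)
        b = cross_validate(X, y, folds=6, seed=5)
        assert np.array_equal(a.scores, b.scores) and a.auc == b.auc

    def test_balanced_accuracy_is_mean_of_sn_sp(self, toy):
        X, y = toy
        cv = cross_validate(X, y, folds=6, seed=2)
        assert cv.metrics["Ac"] == pytest.approx(
            (cv.metrics["Sn"] + cv.metrics["Sp"]) / 2
        )

    def test_too_many_folds_rejected(self, toy):
        X, y = toy
        with pytest.raises(ValueError, match="folds"):
            cross_validate(X, y, folds=len(y) + 1)


class TestRepeatedResampling:
    def test_single_repeat_has_zero_sd(self, pools):
        X_pos, X_neg = pools
        rep = repeated_resampling_eval(X_pos, X_neg, repeats=1, folds=5, seed=0)
        assert (rep.sd == 0).all()
        assert len(rep.per_repeat) == 1

    def test_exhausted_pool_gives_identical_repeats(self, pools):
        X_pos, X_neg = pools
        rep = repeated_resampling_eval(X_pos, X_neg[:25], repeats=3, folds=5, seed=0)
        # every repeat uses the same 25 negatives, but fold seeds differ;
        # the negative subsets at least must coincide
        assert rep.per_repeat["Ac"].nunique() >= 1
        assert len(rep.per_repeat) == 3

    def test_aggregates_are_mean_and_sample_sd(self, pools):
        X_pos, X_neg = pools
        rep = repeated_resampling_eval(X_pos, X_neg, repeats=5, folds=5, seed=3)
        assert rep.mean["Ac"] == pytest.approx(rep.per_repeat["Ac"].mean())
        assert rep.sd["Ac"] == pytest.approx(rep.per_repeat["Ac"].std(ddof=1))
        assert rep.per_repeat["Ac"].min() <= rep.mean["Ac"] <= rep.per_repeat["Ac"].max()


class TestPositionEnrichment:
    def test_planted_signal_detected(self):
        config = FixtureConfig(
            n_pos=150, n_neg=150, implants=[("EQ", 0.9)], seed=3
        )
        ds = generate_fixture(config)
        calls = position_enrichment(ds)
        sig_e = calls[(calls.residue == "E") & calls.significant & (calls.delta > 0)]
        assert len(sig_e) > 0  # E enriched somewhere in positives

    def test_null_data_mostly_quiet(self):
        ds = generate_fixture(FixtureConfig(n_pos=150, n_neg=150, seed=5))
        calls = position_enrichment(ds)
        # at alpha=0.05 with no signal, about 5% false calls are expected
        assert calls.significant.mean() < 0.12

    def test_p_values_match_direct_t_test(self):
        ds = generate_fixture(FixtureConfig(n_pos=40, n_neg=40, seed=9))
        calls = position_enrichment(ds)
        from cksaap_ubsite.encoding import padded_window

        row = calls.iloc[17]
        n = (ds.window - 1) // 2
        j = int(row.position) + n
        ind = np.array([1.0 if padded_window(f, ds.window)[j] == row.residue else 0.0
                        for f in ds.fragments])
        pos = ind[ds.positives]
        neg = ind[ds.negatives]
        t, p = stats.ttest_ind(pos, neg, equal_var=True)
        assert row.p == pytest.approx(p) and row.t == pytest.approx(t)
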