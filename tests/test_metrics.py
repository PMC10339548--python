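"""Evaluation metrics: AUC oracles, DeLong, calibration, DCA, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from nomostack.exceptions import ValidationError
from nomostack.metrics import (
    auc_mann_whitney,
    bootstrap_ci,
    calibration_curve,
    confusion_metrics,
    decision_curve,
    delong_test,
    delong_variance,
    multiclass_auc,
)


def _auc_pair_counting(pos: np.ndarray, neg: np.ndarray) -> float:
    """Brute-force all-pairs oracle: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for a in pos:
        for b in neg:
            wins += a > b
            ties += a == b
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAUC:
    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n1 = rng.integers(2, 25)
            n0 = rng.integers(2, 25)
            # integer scores force plenty of ties
            pos = rng.integers(0, 6, n1).astype(float)
            neg = rng.integers(0, 6, n0).astype(float)
            assert auc_mann_whitney(pos, neg) == pytest.approx(
                _auc_pair_counting(pos, neg), abs=1e-12
            )

    def test_agrees_with_sklearn_on_continuous_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        s = rng.normal(size=200) + y
        ours = auc_mann_whitney(s[y == 1], s[y == 0])
        assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_perfect_separation_is_one(self):
        assert auc_mann_whitney(np.array([3.0, 4.0]), np.array([1.0, 2.0])) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(2)
        y = rng.integers(1, 4, 2000)
        probs = rng.dirichlet(np.ones(3), size=2000)
        assert abs(multiclass_auc(y, probs, "macro_ovr") - 0.5) < 0.03
        assert abs(multiclass_auc(y, probs, "ordinal_score") - 0.5) < 0.03

    def test_six_observation_toy(self):
        # hand computation: pos = (4, 5, 6), neg = (1, 2, 4) -> U = 8.5 of 9
        pos, neg = np.array([4.0, 5.0, 6.0]), np.array([1.0, 2.0, 4.0])
        assert auc_mann_whitney(pos, neg) == pytest.approx(8.5 / 9)

    def test_absent_class_skipped_with_warning(self):
        y = np.array([1, 1, 2, 2])
        probs = np.tile([0.4, 0.4, 0.2], (4, 1))
        with pytest.warns(UserWarning, match="absent"):
            multiclass_auc(y, probs, "macro_ovr")


class TestConfusion:
    def test_perfect_prediction(self):
        y = np.repeat([1, 2, 3], 10)
        m = confusion_metrics(y, y)
        assert m == {"sensitivity": 1.0, "specificity": 1.0, "f1": 1.0}

    def test_constant_high_prediction(self):
        y = np.repeat([1, 2, 3], 10)
        m = confusion_metrics(y, np.full(30, 3))
        assert m["sensitivity"] == pytest.approx(1 / 3)

    def test_binary_collapse_matches_hand_built_table(self):
        y = np.array([1, 1, 1, 2, 2, 2, 2])
        yhat = np.array([1, 1, 2, 2, 2, 1, 2])
        # class 1: TP=2 FN=1 FP=1 TN=3; class 2: TP=3 FN=1 FP=1 TN=2
        m = confusion_metrics(y, yhat)
        assert m["sensitivity"] == pytest.approx((2 / 3 + 3 / 4) / 2)
        assert m["specificity"] == pytest.approx((3 / 4 + 2 / 3) / 2)
        assert m["f1"] == pytest.approx((4 / 6 + 6 / 8) / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion_metrics(np.array([1, 2]), np.array([1]))


class TestDeLong:
    def test_identical_scores_give_z_zero_p_one(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 100)
        s = rng.normal(size=100)
        auc_a, auc_b, z, p = delong_test(y, s, s)
        assert auc_a == auc_b
        assert (z, p) == (0.0, 1.0)

    def test_antisymmetric_in_score_order(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 150)
        a = rng.normal(size=150) + 0.8 * y
        b = rng.normal(size=150) + 0.3 * y
        _, _, z_ab, p_ab = delong_test(y, a, b)
        _, _, z_ba, p_ba = delong_test(y, b, a)
        assert z_ab == pytest.approx(-z_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_variance_nonnegative_and_matches_bootstrap(self):
        rng = np.random.default_rng(5)
        n = 120
        y = rng.integers(0, 2, n)
        a = rng.normal(size=n) + 0.9 * y
        b = 0.6 * a + rng.normal(size=n) * 0.8
        var_dl = delong_variance(y, a, b)
        assert var_dl >= 0
        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) < 2:
                continue
            diffs.append(
                auc_mann_whitney(a[idx][y[idx] == 1], a[idx][y[idx] == 0])
                - auc_mann_whitney(b[idx][y[idx] == 1], b[idx][y[idx] == 0])
            )
        assert var_dl == pytest.approx(np.var(diffs, ddof=1), rel=0.15)

    def test_null_p_values_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(500):
            y = np.repeat([0, 1], 100)
            base = rng.normal(size=200)
            a = base + rng.normal(size=200)
            b = base + rng.normal(size=200)
            pvals.append(delong_test(y, a, b)[3])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_all_tied_scores_rejected(self):
        y = np.repeat([0, 1], 10)
        with pytest.raises(ValidationError, match="tied"):
            delong_test(y, np.ones(20), np.ones(20))


class TestCalibration:
    @staticmethod
    def _logit_fit_predict(X: pd.DataFrame, event: np.ndarray):
        from sklearn.linear_model import LogisticRegression

        model = LogisticRegression(max_iter=2000).fit(X.to_numpy(), event)
        return lambda Z: model.predict_proba(Z.to_numpy())[:, 1]

    def test_well_specified_model_tracks_diagonal(self):
        from scipy.special import expit

        rng = np.random.default_rng(7)
        n = 2000
        X = pd.DataFrame({"x": rng.normal(size=n)})
        p_true = expit(1.2 * X["x"].to_numpy())
        event = (rng.uniform(size=n) < p_true).astype(int)
        curve = calibration_curve(self._logit_fit_predict, X, event, bins=10, n_boot=30, seed=0)
        assert np.abs(curve["predicted"] - curve["observed_apparent"]).mean() < 0.05

    def test_constant_prediction_single_bin_at_prevalence(self):
        X = pd.DataFrame({"x": np.zeros(100)})
        event = np.repeat([0, 1], 50)

        def constant_fit_predict(X_, e_):
            return lambda Z: np.full(len(Z), 0.5)

        curve = calibration_curve(constant_fit_predict, X, event, bins=1, n_boot=5, seed=0)
        assert len(curve) == 1
        assert curve["predicted"].iloc[0] == pytest.approx(0.5)
        assert curve["observed_apparent"].iloc[0] == pytest.approx(0.5)

    def test_overfit_model_shows_positive_optimism(self):
        # a fully grown tree memorizes the sample, so its apparent curve sits
        # exactly on the diagonal; bias correction must move off it
        from scipy.special import expit
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(8)
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        p_true = expit(0.5 * X["a"].to_numpy())
        event = (rng.uniform(size=n) < p_true).astype(int)

        def tree_fit_predict(X_, e_):
            m = DecisionTreeClassifier(random_state=0).fit(X_.to_numpy(), e_)
            return lambda Z: m.predict_proba(Z.to_numpy())[:, 1]

        curve = calibration_curve(tree_fit_predict, X, event, bins=5, n_boot=40, seed=0)
        dev_apparent = np.abs(curve["observed_apparent"] - curve["predicted"]).mean()
        dev_corrected = np.abs(curve["observed_corrected"] - curve["predicted"]).mean()
        assert dev_apparent == pytest.approx(0.0, abs=1e-12)
        assert dev_corrected > dev_apparent + 0.02

    def test_too_many_bins_rejected(self):
        X = pd.DataFrame({"x": np.zeros(10)})
        with pytest.raises(ValidationError):
            calibration_curve(self._logit_fit_predict, X, np.zeros(10, int), bins=9)


class TestDecisionCurve:
    def test_perfect_predictor_net_benefit_equals_prevalence(self):
        y = np.repeat([1, 2, 3], [50, 25, 25])
        p = (y >= 2).astype(float)
        dc = decision_curve(y, p)
        assert np.allclose(dc.net_benefit_model, 0.5)

    def test_treat_all_crosses_zero_at_prevalence(self):
        y = np.repeat([1, 3], [60, 40])  # prevalence 0.4
        dc = decision_curve(y, np.full(100, 0.5))
        i = np.argmin(np.abs(dc.thresholds - 0.4))
        assert dc.net_benefit_all[i] == pytest.approx(0.0, abs=1e-12)
        assert (np.diff(dc.net_benefit_all) < 0).all()

    def test_treat_none_is_identically_zero(self):
        y = np.repeat([1, 2], 20)
        dc = decision_curve(y, np.random.default_rng(9).uniform(size=40))
        assert np.all(dc.net_benefit_none == 0)

    def test_random_predictor_never_beats_envelope(self):
        rng = np.random.default_rng(10)
        exceed = []
        for _ in range(50):
            y = rng.integers(1, 4, 400)
            p = rng.uniform(size=400)
            dc = decision_curve(y, p)
            envelope = np.maximum(dc.net_benefit_all, 0.0)
            exceed.append((dc.net_benefit_model - envelope).max())
        assert np.median(exceed) < 0.02

    def test_model_net_benefit_bounded_by_prevalence(self):
        rng = np.random.default_rng(11)
        y = rng.integers(1, 4, 300)
        p = rng.uniform(size=300)
        dc = decision_curve(y, p)
        assert (dc.net_benefit_model <= (y >= 2).mean() + 1e-12).all()

    def test_invalid_thresholds_rejected(self):
        y = np.repeat([1, 3], 10)
        with pytest.raises(ValidationError):
            decision_curve(y, np.full(20, 0.5), thresholds=np.array([1.0]))
        with pytest.raises(ValidationError):
            decision_curve(y, np.full(20, 1.5))


class TestBootstrapCI:
    def test_coverage_for_the_mean(self):
        rng = np.random.default_rng(12)
        covered = 0
        for i in range(100):
            x = rng.normal(5.0, 2.0, 100)
            _, lo, hi = bootstrap_ci(np.mean, [x], n_boot=300, seed=i)
            covered += lo <= 5.0 <= hi
        assert 88 <= covered <= 99

    def test_single_resample_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            point, lo, hi = bootstrap_ci(np.mean, [np.arange(10.0)], n_boot=1, seed=0)
        assert point == lo == hi

    def test_reproducible_under_seed(self):
        x = np.random.default_rng(13).normal(size=80)
        a = bootstrap_ci(np.std, [x], n_boot=200, seed=5)
        b = bootstrap_ci(np.std, [x], n_boot=200, seed=5)
        assert a == b

    def test_stratified_resampling_preserves_class_counts(self):
        y = np.repeat([0, 1], [30, 10])

        def frac_pos(yy):
            return yy.mean()

        point, lo, hi = bootstrap_ci(frac_pos, [y], n_boot=100, seed=0, stratify=y)
        assert point == lo == hi == 0.25  # stratification fixes the class mix

    def test_failing_metric_raises(self):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] > 1:  # point estimate succeeds, resamples fail
                raise RuntimeError("resample failure")
            return float(np.mean(x))

        with pytest.raises(ValidationError, match="failed"):
            bootstrap_ci(flaky, [np.arange(10.0)], n_boot=50, seed=0)
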