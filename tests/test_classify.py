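import numpy as np
import pandas as pd
import pytest

from pupilcascade.classify import (
    ClassifierConfig,
    evaluate,
    loso_cv,
    oversample_minority,
    roc_points,
    train,
    trapezoid_auc,
    decision_scores,
)
from pupilcascade.core import compute_rates
from pupilcascade.features import FEATURE_NAMES


def make_dataset(rng, n_subjects=5, n_noise=20, n_hazard=4, sep=6.0):
    """Two Gaussian clouds in feature space, grouped by subject."""
    rows = []
    for s in range(n_subjects):
        for label, n, mu in (("noise", n_noise, 0.0), ("hazard", n_hazard, sep)):
            X = mu + rng.standard_normal((n, 7))
            for i, x in enumerate(X):
                rows.append(
                    {"subject": f"S{s}", "peak_time": float(len(rows)),
                     "label": label, **dict(zip(FEATURE_NAMES, x))}
                )
    return pd.DataFrame(rows)


class TestOversample:
    def test_duplicates_minority_to_parity(self, rng):
        X = rng.standard_normal((12, 3))
        y = np.array(["noise"] * 10 + ["hazard"] * 2)
        Xb, yb = oversample_minority(X, y, seed=0)
        assert (yb == "hazard").sum() == (yb == "noise").sum() == 10

    def test_balanced_input_unchanged(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.array(["a"] * 5 + ["b"] * 5)
        Xb, yb = oversample_minority(X, y, seed=0)
        np.testing.assert_array_equal(Xb, X)

    def test_missing_class_rejected(self, rng):
        with pytest.raises(ValueError, match="noise"):
            oversample_minority(rng.standard_normal((3, 2)), np.array(["noise"] * 3), 0)

    def test_distinct_minority_points_preserved_not_invented(self, rng):
        X = rng.standard_normal((15, 4))
        y = np.array(["noise"] * 12 + ["hazard"] * 3)
        Xb, yb = oversample_minority(X, y, seed=3)
        minority_rows = {tuple(r) for r in Xb[yb == "hazard"]}
        assert minority_rows == {tuple(r) for r in X[12:]}

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((12, 3))
        y = np.array(["noise"] * 9 + ["hazard"] * 3)
        a = oversample_minority(X, y, seed=11)
        b = oversample_minority(X, y, seed=11)
        np.testing.assert_array_equal(a[0], b[0])


class TestTrain:
    def test_separable_clouds_fit_almost_perfectly(self, rng):
        X = np.vstack([rng.standard_normal((100, 7)), 6.0 + rng.standard_normal((100, 7))])
        y = np.array(["noise"] * 100 + ["hazard"] * 100)
        model = train(X, y)
        assert (model.predict(X) == y).mean() >= 0.99

    def test_two_point_training_set(self):
        X = np.array([[0.0] * 7, [5.0] * 7])
        y = np.array(["noise", "hazard"])
        model = train(X, y)
        assert list(model.predict(X)) == ["noise", "hazard"]

    def test_identical_features_give_chance_accuracy(self, rng):
        X = np.tile(rng.standard_normal(7), (40, 1))
        y = np.array(["noise"] * 20 + ["hazard"] * 20)
        model = train(X, y)
        scores = decision_scores(model, X)
        assert np.all(np.abs(scores) < 1.0)  # everything near the margin

    def test_scores_positive_for_hazard_side(self, rng):
        X = np.vstack([rng.standard_normal((50, 7)), 6.0 + rng.standard_normal((50, 7))])
        y = np.array(["noise"] * 50 + ["hazard"] * 50)
        model = train(X, y)
        s = decision_scores(model, X)
        assert s[y == "hazard"].mean() > s[y == "noise"].mean()


class TestLosoCv:
    def test_one_fold_per_subject_without_leakage(self, rng):
        df = make_dataset(rng)
        folds = loso_cv(df)
        assert sorted(f.held_out_subject for f in folds) == [f"S{i}" for i in range(5)]
        assert sum(len(f.scores) for f in folds) == len(df)

    def test_predictions_invariant_to_subject_order(self, rng):
        df = make_dataset(rng)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = {f.held_out_subject: f.scores for f in loso_cv(df)}
        b = {f.held_out_subject: f.scores for f in loso_cv(shuffled)}
        for s in a:
            np.testing.assert_allclose(np.sort(a[s]), np.sort(b[s]), atol=1e-9)

    def test_separable_data_classified_correctly(self, rng):
        df = make_dataset(rng)
        report = evaluate(loso_cv(df))
        assert report.pooled.sensitivity >= 0.95
        assert report.pooled.specificity >= 0.95
        assert report.auc == pytest.approx(1.0, abs=1e-6)

    def test_missed_events_count_as_false_negatives(self, rng):
        df = make_dataset(rng)
        folds = loso_cv(df, missed_events={"S0": 2})
        report = evaluate(folds)
        m = report.per_subject["S0"]
        assert m.fn >= 2

    def test_fewer_than_two_subjects_rejected(self, rng):
        df = make_dataset(rng, n_subjects=1)
        with pytest.raises(ValueError):
            loso_cv(df)


class TestEvaluate:
    def test_metrics_match_hand_computed_values(self):
        m = compute_rates(tp=10, fp=2, tn=8, fn=1)
        assert m.sensitivity == pytest.approx(10 / 11, abs=5e-4)
        assert m.specificity == pytest.approx(0.800, abs=5e-4)
        assert m.precision == pytest.approx(10 / 12, abs=5e-4)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = compute_rates(tp=0, fp=0, tn=5, fn=3)
        assert m.precision is None
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0

    def test_all_noise_prediction(self):
        m = compute_rates(tp=0, fp=0, tn=10, fn=4)
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_roc_monotone_nondecreasing(self, rng):
        scores = rng.standard_normal(200)
        truth = rng.random(200) < 0.3
        pts = roc_points(scores, truth)
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)
        assert pts[0][:2] == (0.0, 0.0) and pts[-1][:2] == (1.0, 1.0)

    def test_trapezoid_auc_equals_rank_statistic(self, rng):
        """AUC by trapezoid over the ROC equals the Mann-Whitney statistic
        (ties contributing 1/2) computed directly from the scores."""
        for _ in range(20):
            n = int(rng.integers(20, 80))
            scores = np.round(rng.standard_normal(n), 1)  # force ties
            truth = rng.random(n) < 0.4
            if truth.all() or not truth.any():
                continue
            auc = trapezoid_auc(roc_points(scores, truth))
            pos, neg = scores[truth], scores[~truth]
            u = np.mean(
                (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
            )
            assert auc == pytest.approx(u, abs=1e-9)

    def test_threshold_monotonicity(self, rng):
        scores = rng.standard_normal(300)
        truth = rng.random(300) < 0.3
        sens = []
        for thr in np.linspace(-2, 2, 9):
            pred = scores > thr
            tp = np.sum(pred & truth)
            sens.append(tp / truth.sum())
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_perfect_scores_give_unit_auc(self):
        scores = np.array([1.0, 2.0, 3.0, -1.0, -2.0])
        truth = np.array([True, True, True, False, False])
        pts = roc_points(scores, truth)
        assert (0.0, 1.0) in [p[:2] for p in pts]
        assert trapezoid_auc(pts) == pytest.approx(1.0)


def test_classifier_config_validation():
    with pytest.raises(ValueError):
        ClassifierConfig(C=-1)
    with pytest.raises(ValueError):
        ClassifierConfig(gamma=0.0)
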