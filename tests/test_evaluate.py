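"""Classification metrics, bootstrap, McNemar, reconstruction metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sp_stats

from ecgrecon.errors import (
    InvalidArgumentError, NoDiscordanceError, UndefinedMetricError,
)
from ecgrecon.evaluate import (
    CLASSIFIER_KINDS, ClassifierSpec, bootstrap_accuracy,
    classification_metrics, cross_entropy, holm_adjust, mcnemar_test,
    reconstruction_metrics, train_classifier,
)


class TestCrossEntropy:
    def test_perfect_prediction_zero(self):
        y = np.eye(3)
        assert cross_entropy(y, y) == pytest.approx(0.0)

    def test_uniform_four_class(self):
        y = np.array([[1.0, 0, 0, 0]])
        p = np.full((1, 4), 0.25)
        assert cross_entropy(y, p) == pytest.approx(np.log(4))

    def test_hand_sum(self):
        """True-class probabilities 0.8 and 0.5: -(ln 0.8 + ln 0.5)."""
        y = np.array([[1.0, 0], [0, 1.0]])
        p = np.array([[0.8, 0.2], [0.5, 0.5]])
        assert cross_entropy(y, p) == pytest.approx(
            -(np.log(0.8) + np.log(0.5)))

    def test_shape_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            cross_entropy(np.eye(2), np.eye(3))


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    x = np.vstack([rng.normal(0, 0.1, (30, 4)),
                   rng.normal(5, 0.1, (30, 4))])
    y = np.array([0] * 30 + [1] * 30)
    return x, y


class TestClassifiers:
    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_separable_toy_fits(self, kind, separable):
        x, y = separable
        clf = train_classifier(ClassifierSpec(kind=kind, seed=0), x, y)
        assert (clf.predict(x) == y).mean() >= 0.99
        proba = clf.predict_proba(x)
        assert proba.shape == (60, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_seeded_retrain_identical_predictions(self, separable):
        x, y = separable
        rng = np.random.default_rng(1)
        x_test = rng.normal(2.5, 2.0, (40, 4))
        spec = ClassifierSpec(kind="random_forest", seed=5)
        a = train_classifier(spec, x, y).predict(x_test)
        b = train_classifier(spec, x, y).predict(x_test)
        assert np.array_equal(a, b)

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ClassifierSpec(kind="neural_network")

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            train_classifier(ClassifierSpec(kind="decision_tree"),
                             np.zeros((5, 2)), np.zeros(5))


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 1])
        m = classification_metrics(y, y)
        assert m["accuracy"] == m["precision"] == m["recall"] == m["f1"] == 1.0

    def test_confusion_matrix_hand_oracle(self):
        """TP=3, FP=1, FN=1, TN=5: class-1 precision=recall=F1=0.75."""
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        m = classification_metrics(y_true, y_pred)
        assert m["per_class_accuracy"][1] == pytest.approx(0.75)
        from sklearn.metrics import precision_recall_fscore_support
        p, r, f, _ = precision_recall_fscore_support(y_true, y_pred,
                                                     labels=[1],
                                                     average=None)
        assert (p[0], r[0], f[0]) == (0.75, 0.75, 0.75)

    def test_constant_prediction_on_balanced_set(self):
        y_true = np.array([0] * 25 + [1] * 25)
        y_pred = np.zeros(50, dtype=int)
        assert classification_metrics(y_true, y_pred)["accuracy"] == 0.5

    def test_weighted_f1_between_min_and_max_class_f1(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            y_true = rng.integers(0, 3, 60)
            y_pred = rng.integers(0, 3, 60)
            if len(np.unique(y_true)) < 2:
                continue
            from sklearn.metrics import f1_score
            per_class = f1_score(y_true, y_pred, average=None,
                                 labels=np.unique(y_true), zero_division=0)
            weighted = classification_metrics(y_true, y_pred)["f1"]
            assert per_class.min() - 1e-9 <= weighted <= per_class.max() + 1e-9

    def test_empty_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            classification_metrics([], [])


class TestReconstructionMetrics:
    def test_exact_reconstruction_zero(self):
        x = np.random.default_rng(0).random((10, 2))
        m = reconstruction_metrics(x, x)
        assert m["mae"] == m["mse"] == m["rmse"] == m["nrmse"] == 0.0

    def test_hand_arithmetic(self):
        m = reconstruction_metrics(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        assert m["mae"] == pytest.approx(0.5)
        assert m["mse"] == pytest.approx(0.5)
        assert m["rmse"] == pytest.approx(np.sqrt(0.5))
        assert m["nrmse"] == pytest.approx(np.sqrt(0.5))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(c=st.floats(0.01, 100.0))
    def test_nrmse_scale_invariant(self, c):
        x = np.array([0.0, 1.0, 3.0])
        xh = np.array([0.5, 1.5, 2.0])
        a = reconstruction_metrics(x, xh)["nrmse"]
        b = reconstruction_metrics(c * x, c * xh)["nrmse"]
        assert a == pytest.approx(b, rel=1e-9)

    def test_masked_selection(self):
        x = np.array([[0.0, 5.0], [1.0, 9.0]])
        xh = np.array([[1.0, -99.0], [1.0, -99.0]])
        sel = np.array([[True, False], [True, False]])
        assert reconstruction_metrics(x, xh, sel)["mae"] == pytest.approx(0.5)

    def test_zero_range_rejected(self):
        with pytest.raises(UndefinedMetricError):
            reconstruction_metrics(np.ones(4), np.zeros(4))


class TestBootstrap:
    def test_perfect_predictions(self):
        y = np.ones(50)
        mean, sd = bootstrap_accuracy(y, y, seed=0)
        assert mean == 1.0 and sd == 0.0

    def test_sd_matches_binomial_formula(self):
        """n=485, p=0.95: bootstrap SD within 20% of sqrt(p(1-p)/n)."""
        n, p = 485, 0.95
        y_true = np.ones(n)
        y_pred = np.ones(n)
        wrong = np.random.default_rng(1).choice(n, size=round(n * (1 - p)),
                                                replace=False)
        y_pred[wrong] = 0
        _, sd = bootstrap_accuracy(y_true, y_pred, n_iter=1000, seed=2)
        expected = np.sqrt(p * (1 - p) / n)
        assert abs(sd - expected) < 0.2 * expected

    def test_seeded_repeat_identical(self):
        y_true = np.arange(30) % 2
        y_pred = (np.arange(30) % 3 == 0).astype(int)
        assert bootstrap_accuracy(y_true, y_pred, seed=7) == \
            bootstrap_accuracy(y_true, y_pred, seed=7)

    def test_single_iteration_membership(self):
        """n_iter=1: the replicate accuracy is achievable from the sample."""
        y_true = np.array([1, 1, 0, 0])
        y_pred = np.array([1, 0, 0, 0])
        mean, _ = bootstrap_accuracy(y_true, y_pred, n_iter=1, seed=3)
        assert mean in {0.0, 0.25, 0.5, 0.75, 1.0}

    def test_empty_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bootstrap_accuracy([], [])


class TestMcNemar:
    def test_exact_binomial_enumeration(self):
        """b=10, c=2: p = 2 * P(X <= 2 | Binomial(12, 1/2)) = 79/2048."""
        a = np.array([True] * 10 + [False] * 2 + [True] * 20)
        b = np.array([False] * 10 + [True] * 2 + [True] * 20)
        p, bb, cc = mcnemar_test(a, b)
        enumerated = 2 * sum(sp_stats.binom.pmf(k, 12, 0.5) for k in range(3))
        assert (bb, cc) == (10, 2)
        assert p == pytest.approx(enumerated)
        assert p == pytest.approx(0.03857421875)

    def test_symmetric_discordance_capped_at_one(self):
        a = np.array([True, False, True, False, True])
        b = np.array([False, True, False, True, True])
        p, _, _ = mcnemar_test(a, b)
        assert p == 1.0

    def test_no_discordance_raises(self):
        same = np.array([True, False, True])
        with pytest.raises(NoDiscordanceError):
            mcnemar_test(same, same)

    def test_exact_chi2_boundary_consistency(self):
        """For b + c in [25, 40] the exact and corrected-chi2 p agree
        within 0.02."""
        for b in range(13, 25):
            for c in range(max(0, 25 - b), min(b, 41 - b)):
                n = b + c
                if not 25 <= n <= 40:
                    continue
                exact = min(1.0, 2 * sp_stats.binom.cdf(min(b, c), n, 0.5))
                chi2 = (abs(b - c) - 1.0) ** 2 / n
                approx = sp_stats.chi2.sf(chi2, df=1)
                assert abs(exact - approx) < 0.02, (b, c)

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            mcnemar_test([True], [True, False])


def test_holm_adjustment_monotone_and_bounded():
    ps = [0.001, 0.02, 0.04, 0.6]
    adj = holm_adjust(ps)
    assert all(a >= p for a, p in zip(adj, ps))
    assert all(0 < a <= 1 for a in adj)
    assert adj[0] == pytest.approx(0.004)
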