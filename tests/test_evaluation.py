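"""Evaluation battery: confusion metrics, exact binomial, bootstrap, baselines."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from neurohit.evaluation import (
    confusion_metrics,
    exact_binomial_test,
    bootstrap_compare,
    kfold_overfit_check,
    logistic_baseline,
    effect_stats,
    group_effect,
    correlation,
)
from conftest import toy_feature_frame


class TestConfusionMetrics:
    def test_study_design_counts(self):
        # 24 songs, 13 hits; one flop called a hit, everything else correct
        truth = ["hit"] * 13 + ["flop"] * 11
        pred = ["hit"] * 13 + ["hit"] + ["flop"] * 10
        c = confusion_metrics(truth, pred)
        assert c.accuracy == pytest.approx(23 / 24)
        assert c.sensitivity == 1.0
        assert c.specificity == pytest.approx(10 / 11)
        assert (c.tp, c.fp, c.tn, c.fn) == (13, 1, 10, 0)

    def test_perfect_predictions(self):
        c = confusion_metrics([1, 0, 1], [1, 0, 1])
        assert (c.accuracy, c.sensitivity, c.specificity) == (1.0, 1.0, 1.0)

    def test_degenerate_truth_flags_undefined_rate(self):
        with pytest.warns(RuntimeWarning, match="sensitivity"):
            c = confusion_metrics([0, 0, 0], [0, 1, 0])
        assert np.isnan(c.sensitivity)
        assert c.specificity == pytest.approx(2 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_metrics([1, 0], [1])


def enumerate_upper_tail(successes, n, p0):
    """Independent oracle: direct sum of the binomial upper tail."""
    return float(
        sum(comb(n, x, exact=True) * p0**x * (1 - p0) ** (n - x) for x in range(successes, n + 1))
    )


class TestExactBinomial:
    def test_zero_successes_full_tail(self):
        assert exact_binomial_test(0, 10, 0.3).p_value == pytest.approx(1.0)

    def test_nine_of_ten_worked_example(self):
        # 11 favorable outcomes out of 2^10 under p0 = 0.5
        assert exact_binomial_test(9, 10, 0.5).p_value == pytest.approx(11 / 1024)

    def test_matches_enumeration_on_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 21))
            s = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            assert exact_binomial_test(s, n, p0).p_value == pytest.approx(
                enumerate_upper_tail(s, n, p0), rel=1e-10
            )

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            exact_binomial_test(5, 4, 0.5)
        with pytest.raises(ValueError):
            exact_binomial_test(1, 4, 1.0)


class TestEffectStats:
    def test_identical_groups_null(self):
        e = group_effect([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert e.t == 0.0 and e.d == 0.0

    def test_hand_computed_example(self):
        # flop {0,2} vs hit {1,3}: pooled SD = sqrt(2), d = -1/sqrt(2)
        e = group_effect([0.0, 2.0], [1.0, 3.0])
        assert e.d == pytest.approx(-0.7071, abs=1e-4)
        assert e.t == pytest.approx(-0.7071, abs=1e-4)
        assert e.df == 2

    def test_sign_convention_is_flop_minus_hit(self, feature_table):
        e = effect_stats(feature_table, "avg_immersion")
        assert e.mean_hit > e.mean_flop  # hits are more immersive by design
        assert e.d < 0

    def test_zero_variance_unequal_means_flagged(self):
        e = group_effect([1.0, 1.0], [2.0, 2.0])
        assert e.infinite and np.isinf(e.d)

    def test_perfect_linear_correlation(self):
        x = np.arange(10.0)
        r, p = correlation(x, 3 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10


class TestLogisticBaseline:
    def test_uninformative_predictor_gives_majority_accuracy(self):
        # each predictor value appears once per class: P(hit|x) = 0.5 for all
        # x, so the MLE slope is 0 and classification is the majority rule
        vals = np.linspace(3.9, 4.3, 12)
        df = pd.DataFrame(
            {
                "label": ["hit"] * 12 + ["flop"] * 12,
                "avg_immersion": np.concatenate([vals, vals]),
            }
        )
        res = logistic_baseline(df, "model1")
        assert abs(res.params["avg_immersion"]) < 1e-5
        assert res.confusion.accuracy == pytest.approx(0.5)

    def test_separated_data_triggers_ridge_fallback(self):
        df = toy_feature_frame(n=20, n_hits=10, d=50.0, seed=4)
        with pytest.warns(RuntimeWarning, match="ridge"):
            res = logistic_baseline(df, "model1")
        assert res.ridge_fallback
        assert res.confusion.accuracy == 1.0

    def test_vif_closed_form_for_correlated_predictors(self):
        # construct predictors with empirical correlation exactly 0.51
        rng = np.random.default_rng(5)
        n = 40
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = z2 - z2.mean()
        z2 -= z1 * (z1 @ z2) / (z1 @ z1)  # orthogonalize
        z2 /= z2.std()
        r = 0.51
        x2 = r * z1 + np.sqrt(1 - r**2) * z2
        df = pd.DataFrame(
            {
                "label": ["hit", "flop"] * (n // 2),
                "avg_immersion": z1,
                "retreat": x2,
            }
        )
        res = logistic_baseline(df, "model2")
        assert res.vif["avg_immersion"] == pytest.approx(1 / (1 - 0.51**2), abs=1e-3)
        assert res.vif["retreat"] == pytest.approx(1.3515, abs=1e-3)

    def test_single_class_rejected(self):
        df = toy_feature_frame(n=10, n_hits=10)
        with pytest.raises(ValueError, match="both classes"):
            logistic_baseline(df, "model1")

    def test_model_specifications(self, feature_table):
        m1 = logistic_baseline(feature_table, "model1")
        m2 = logistic_baseline(feature_table, "Model 2")
        assert m1.predictors == ("avg_immersion",)
        assert m2.predictors == ("avg_immersion", "retreat")
        assert m2.lr_df == 2 and 0 <= m2.lr_p <= 1
        assert all(v >= 1 for v in m2.vif.values())


class _FixedAccuracy:
    """Predictor that is right with a fixed probability (test instrument)."""

    def __init__(self, accuracy, truth_fn, seed):
        self.accuracy = accuracy
        self.truth_fn = truth_fn
        self.rng = np.random.default_rng(seed)

    def predict(self, X):
        truth = self.truth_fn(X)
        flip = self.rng.random(len(truth)) > self.accuracy
        return np.where(flip, 1 - truth, truth)


class TestBootstrapCompare:
    @staticmethod
    def _pool(n=400, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        x = y * 2.0 + rng.normal(0, 0.3, n)
        return pd.DataFrame({"label": y, "avg_immersion": x, "retreat": rng.normal(0, 1, n)})

    def test_self_comparison_is_null(self):
        pool = self._pool()
        factory = lambda X, y, seed: _FixedAccuracy(0.8, lambda Xt: (Xt[:, 0] > 1).astype(int), seed)
        comp = bootstrap_compare(
            factory, factory, pool, iterations=60, train_n=100, test_n=100, seed=1
        )
        diff = np.mean(comp.accuracies_a["overall"]) - np.mean(comp.accuracies_b["overall"])
        assert abs(diff) < 0.05
        assert comp.t_stats["overall"]["df"] == 2 * 60 - 2

    def test_oracle_beats_coin_flip(self):
        pool = self._pool(seed=2)
        truth_fn = lambda Xt: (Xt[:, 0] > 1).astype(int)
        flip = lambda X, y, seed: _FixedAccuracy(0.5, truth_fn, seed)
        oracle = lambda X, y, seed: _FixedAccuracy(1.0, truth_fn, seed)
        comp = bootstrap_compare(
            flip, oracle, pool, iterations=50, train_n=80, test_n=80, seed=3
        )
        assert comp.ci_b["overall"] == (1.0, 1.0)
        assert comp.t_stats["overall"]["t"] < -10  # (flip - oracle) ordering
        assert comp.t_stats["overall"]["p"] < 1e-6

    def test_ci_shrinks_as_test_n_grows(self):
        pool = self._pool(seed=4)
        factory = lambda X, y, seed: _FixedAccuracy(0.8, lambda Xt: (Xt[:, 0] > 1).astype(int), seed)
        widths = []
        for test_n in (50, 800):
            comp = bootstrap_compare(
                factory, factory, pool, iterations=40, train_n=50, test_n=test_n, seed=5
            )
            lo, hi = comp.ci_a["overall"]
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_single_iteration_rejected(self):
        with pytest.raises(ValueError, match="iterations"):
            bootstrap_compare(None, None, self._pool(), iterations=1)


class TestKFoldOverfitCheck:
    @staticmethod
    def _knn_factory(X, y, seed):
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(n_neighbors=1).fit(X, y)

    def test_separable_duplicated_data_trains_and_tests_high(self):
        df = toy_feature_frame(n=30, n_hits=15, d=30.0, seed=6)
        df = pd.concat([df, df], ignore_index=True)
        check = kfold_overfit_check(self._knn_factory, df, df.head(30), k=10, seed=0)
        assert check.means()["train"] == 1.0
        assert check.means()["test"] > 0.9
        assert check.consistent

    def test_permuted_labels_give_chance_level_heldout(self):
        rng = np.random.default_rng(7)
        df = toy_feature_frame(n=200, n_hits=100, d=2.0, seed=7)
        df["label"] = rng.permutation(df["label"].to_numpy())
        check = kfold_overfit_check(self._knn_factory, df, df.head(24), k=10, seed=1)
        assert abs(check.means()["test"] - 0.5) < 0.12  # binomial noise around chance

    def test_k_larger_than_n_rejected(self):
        df = toy_feature_frame(n=10, n_hits=5)
        with pytest.raises(ValueError, match="k="):
            kfold_overfit_check(self._knn_factory, df, df, k=11)
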