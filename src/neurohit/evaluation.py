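"""Evaluation battery for hit/flop classifiers.

Confusion metrics (accuracy, hit sensitivity, flop specificity), the exact
binomial test of an accuracy against a base rate, a bootstrap comparison of
two classifiers (percentile CIs and a two-sample t across iterations),
a k-fold overfitting check, logistic baselines with a likelihood-ratio
overall test and VIF, and the descriptive two-group effect statistics
(Student's t, Cohen's d, Pearson r).

Sign conventions: two-group statistics order the groups (flop, hit), i.e.
``d = (mean_flop - mean_hit) / pooled SD``, so higher-immersion hits give a
negative immersion d and lower-retreat hits give a positive retreat d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .ensemble import encode_labels

__all__ = [
    "ConfusionSummary",
    "BinomialTestResult",
    "BootstrapComparison",
    "LogisticBaselineResult",
    "EffectStats",
    "KFoldCheck",
    "confusion_metrics",
    "exact_binomial_test",
    "bootstrap_compare",
    "kfold_overfit_check",
    "logistic_baseline",
    "effect_stats",
    "group_effect",
    "correlation",
]


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float  # hit recall; NaN when there are no true hits
    specificity: float  # flop recall; NaN when there are no true flops

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion_metrics(y_true, y_pred) -> ConfusionSummary:
    """Counts and rates for binary hit(1)/flop(0) predictions."""
    t = encode_labels(y_true)
    p = encode_labels(y_pred)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} truths vs {len(p)} predictions")
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fn = int(np.sum((t == 1) & (p == 0)))
    n = len(t)
    acc = (tp + tn) / n
    if tp + fn == 0:
        warnings.warn("no true hits: sensitivity undefined", RuntimeWarning, stacklevel=2)
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no true flops: specificity undefined", RuntimeWarning, stacklevel=2)
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    return ConfusionSummary(tp, fp, tn, fn, acc, sens, spec)


# ---------------------------------------------------------------------------
# Exact binomial test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinomialTestResult:
    successes: int
    n: int
    p0: float
    p_value: float  # exact upper-tail P(X >= successes), no approximation


def exact_binomial_test(successes: int, n: int, p0: float) -> BinomialTestResult:
    """Exact one-sided (upper-tail) binomial test against base rate ``p0``."""
    if not (0 <= successes <= n) or n < 1:
        raise ValueError(f"need 0 <= successes <= n, got {successes}/{n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    p = sps.binomtest(successes, n, p0, alternative="greater").pvalue
    return BinomialTestResult(successes, n, p0, float(p))


# ---------------------------------------------------------------------------
# Bootstrap comparison of two classifiers
# ---------------------------------------------------------------------------


@dataclass
class BootstrapComparison:
    """Per-metric accuracies across iterations and their comparison.

    ``accuracies_a/b`` map metric ("overall", "hit", "flop") to the per-
    iteration accuracy arrays; ``ci_a/b`` are 95% percentile intervals;
    ``t_stats`` carries the two-sample Student t (mean_a - mean_b),
    df = 2*iterations - 2, and its two-sided p.
    """

    iterations: int
    accuracies_a: dict
    accuracies_b: dict
    ci_a: dict
    ci_b: dict
    t_stats: dict  # metric -> {"t", "df", "p"}

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "ci_a": {k: list(v) for k, v in self.ci_a.items()},
            "ci_b": {k: list(v) for k, v in self.ci_b.items()},
            "t_stats": self.t_stats,
            "mean_a": {k: float(np.mean(v)) for k, v in self.accuracies_a.items()},
            "mean_b": {k: float(np.mean(v)) for k, v in self.accuracies_b.items()},
        }


def _class_accuracies(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    out = {"overall": float(np.mean(y_true == y_pred))}
    for name, cls in (("hit", 1), ("flop", 0)):
        mask = y_true == cls
        out[name] = float(np.mean(y_pred[mask] == cls)) if mask.any() else np.nan
    return out


def bootstrap_compare(
    model_a_factory,
    model_b_factory,
    pool: pd.DataFrame,
    iterations: int = 1000,
    train_n: int = 5000,
    test_n: int = 5000,
    seed: int = 0,
    feature_cols: tuple[str, ...] = ("avg_immersion", "retreat"),
    label_col: str = "label",
) -> BootstrapComparison:
    """Bootstrap two classifiers against each other on a synthetic pool.

    Each iteration draws a train set and a test set with replacement from the
    pool, fits both factories on the train draw and records their test
    accuracies (overall, hits-only, flops-only).  A factory is a callable
    ``(X_train, y_train, seed) -> predictor`` whose result has a
    ``predict(X) -> 0/1`` method.
    """
    if iterations < 2:
        raise ValueError("iterations must be at least 2")
    if len(pool) < 2:
        raise ValueError("pool too small to resample")
    rng = np.random.default_rng(seed)
    X_pool = pool[list(feature_cols)].to_numpy(dtype=float)
    y_pool = encode_labels(pool[label_col])
    acc_a = {k: np.empty(iterations) for k in ("overall", "hit", "flop")}
    acc_b = {k: np.empty(iterations) for k in ("overall", "hit", "flop")}
    for it in range(iterations):
        tr = rng.integers(0, len(pool), train_n)
        te = rng.integers(0, len(pool), test_n)
        # guard: a train draw must contain both classes
        while np.unique(y_pool[tr]).size < 2:
            tr = rng.integers(0, len(pool), train_n)
        it_seed = int(rng.integers(2**31))
        ma = model_a_factory(X_pool[tr], y_pool[tr], it_seed)
        mb = model_b_factory(X_pool[tr], y_pool[tr], it_seed)
        for store, model in ((acc_a, ma), (acc_b, mb)):
            pred = np.asarray(model.predict(X_pool[te])).astype(int)
            for k, v in _class_accuracies(y_pool[te], pred).items():
                store[k][it] = v
    ci = lambda arr: (
        float(np.nanpercentile(arr, 2.5)),
        float(np.nanpercentile(arr, 97.5)),
    )
    t_stats = {}
    for k in acc_a:
        a, b = acc_a[k], acc_b[k]
        t, p = sps.ttest_ind(a, b, equal_var=True, nan_policy="omit")
        t_stats[k] = {"t": float(t), "df": 2 * iterations - 2, "p": float(p)}
    return BootstrapComparison(
        iterations=iterations,
        accuracies_a=acc_a,
        accuracies_b=acc_b,
        ci_a={k: ci(v) for k, v in acc_a.items()},
        ci_b={k: ci(v) for k, v in acc_b.items()},
        t_stats=t_stats,
    )


# ---------------------------------------------------------------------------
# K-fold overfitting check
# ---------------------------------------------------------------------------


@dataclass
class KFoldCheck:
    train_accuracies: np.ndarray
    test_accuracies: np.ndarray
    observed_accuracies: np.ndarray
    consistent: bool
    band: float

    def means(self) -> dict:
        return {
            "train": float(self.train_accuracies.mean()),
            "test": float(self.test_accuracies.mean()),
            "observed": float(self.observed_accuracies.mean()),
        }

    def sds(self) -> dict:
        return {
            "train": float(self.train_accuracies.std(ddof=1)),
            "test": float(self.test_accuracies.std(ddof=1)),
            "observed": float(self.observed_accuracies.std(ddof=1)),
        }

    def to_dict(self) -> dict:
        return {
            "means": self.means(),
            "sds": self.sds(),
            "consistent": self.consistent,
            "band": self.band,
            "train": self.train_accuracies.tolist(),
            "test": self.test_accuracies.tolist(),
            "observed": self.observed_accuracies.tolist(),
        }

    def plot(self, ax=None):
        """Per-fold accuracy profiles for train, held-out and observed data."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        folds = np.arange(1, len(self.train_accuracies) + 1)
        ax.plot(folds, self.train_accuracies, "o-", label="train folds")
        ax.plot(folds, self.test_accuracies, "s-", label="held-out folds")
        ax.plot(folds, self.observed_accuracies, "^-", label="observed songs")
        ax.set_xlabel("fold")
        ax.set_ylabel("accuracy")
        ax.set_ylim(0, 1.05)
        ax.legend(frameon=False)
        return ax


def kfold_overfit_check(
    fit_fn,
    train_table: pd.DataFrame,
    observed_table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    band: float = 0.05,
    feature_cols: tuple[str, ...] = ("avg_immersion", "retreat"),
    label_col: str = "label",
) -> KFoldCheck:
    """Compare training-fold, held-out-fold and observed-data accuracy.

    ``fit_fn(X, y, seed) -> predictor`` is refit on each fold's training
    part; the check flags consistency when the three mean accuracies all lie
    within ``band`` of each other.
    """
    from sklearn.model_selection import KFold

    n = len(train_table)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be at least 2")
    X = train_table[list(feature_cols)].to_numpy(dtype=float)
    y = encode_labels(train_table[label_col])
    X_obs = observed_table[list(feature_cols)].to_numpy(dtype=float)
    y_obs = encode_labels(observed_table[label_col])
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    tr_acc, te_acc, ob_acc = [], [], []
    for f, (tr, te) in enumerate(kf.split(X)):
        model = fit_fn(X[tr], y[tr], seed + f)
        tr_acc.append(float(np.mean(np.asarray(model.predict(X[tr])).astype(int) == y[tr])))
        te_acc.append(float(np.mean(np.asarray(model.predict(X[te])).astype(int) == y[te])))
        ob_acc.append(float(np.mean(np.asarray(model.predict(X_obs)).astype(int) == y_obs)))
    tr_acc, te_acc, ob_acc = map(np.asarray, (tr_acc, te_acc, ob_acc))
    means = [tr_acc.mean(), te_acc.mean(), ob_acc.mean()]
    consistent = (max(means) - min(means)) <= band
    return KFoldCheck(tr_acc, te_acc, ob_acc, bool(consistent), band)


# ---------------------------------------------------------------------------
# Logistic baselines
# ---------------------------------------------------------------------------

MODEL_PREDICTORS = {
    "model1": ("avg_immersion",),
    "model2": ("avg_immersion", "retreat"),
}


@dataclass
class LogisticBaselineResult:
    model_id: str
    predictors: tuple[str, ...]
    params: dict  # coefficient estimates incl. intercept
    confusion: ConfusionSummary
    lr_chi2: float  # model-vs-null likelihood ratio
    lr_df: int
    lr_p: float
    vif: dict  # predictor -> VIF (empty for a single predictor)
    ridge_fallback: bool
    fitted_probabilities: np.ndarray = field(repr=False, default=None)

    def predict(self, X) -> np.ndarray:
        X = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
        beta = np.array([self.params["const"]] + [self.params[p] for p in self.predictors])
        return (1.0 / (1.0 + np.exp(-(X @ beta))) >= 0.5).astype(int)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "predictors": list(self.predictors),
            "params": self.params,
            "confusion": self.confusion.to_dict(),
            "lr_chi2": self.lr_chi2,
            "lr_df": self.lr_df,
            "lr_p": self.lr_p,
            "vif": self.vif,
            "ridge_fallback": self.ridge_fallback,
        }


def _binom_llf(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def logistic_baseline(
    features: pd.DataFrame,
    model_id: str = "model2",
    label_col: str = "label",
    threshold: float = 0.5,
    predictors: tuple[str, ...] | None = None,
) -> LogisticBaselineResult:
    """Logistic regression baseline (Model 1: immersion; Model 2: + retreat).

    Maximum-likelihood fit with an L2-ridge fallback under separation or
    non-convergence (logged as a warning).  Reports in-sample classification
    at the 0.5 threshold, a model-vs-null likelihood-ratio chi-square and,
    for multi-predictor models, the VIF of each predictor.
    """
    model_key = model_id.lower().replace(" ", "")
    if predictors is None:
        if model_key not in MODEL_PREDICTORS:
            raise ValueError(f"unknown model {model_id!r}; use model1/model2")
        predictors = MODEL_PREDICTORS[model_key]
    y = encode_labels(features[label_col])
    if np.unique(y).size < 2:
        raise ValueError("logistic baseline needs both classes")
    X = features[list(predictors)].to_numpy(dtype=float)
    X_design = sm.add_constant(X, has_constant="add")
    ridge = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X_design).fit(disp=0, maxiter=200)
            ok = res.mle_retvals.get("converged", False) and np.all(
                np.isfinite(res.bse)
            ) and np.max(np.abs(res.params)) < 1e3
        except Exception:
            ok = False
        if ok:
            beta = np.asarray(res.params)
        else:
            ridge = True
            glm = sm.GLM(y, X_design, family=sm.families.Binomial())
            beta = np.asarray(
                glm.fit_regularized(alpha=1e-3, L1_wt=0.0, maxiter=200).params
            )
    if ridge:
        warnings.warn(
            f"{model_id}: maximum likelihood unstable (separation?); "
            "fell back to a small L2 ridge",
            RuntimeWarning,
            stacklevel=2,
        )
    probs = 1.0 / (1.0 + np.exp(-(X_design @ beta)))
    llf = _binom_llf(y, probs)
    p_null = y.mean()
    ll0 = _binom_llf(y, np.full_like(probs, p_null))
    lr = max(0.0, 2.0 * (llf - ll0))
    lr_df = len(predictors)
    lr_p = float(sps.chi2.sf(lr, lr_df))
    preds = (probs >= threshold).astype(int)
    vif = {}
    if len(predictors) > 1:
        for i, name in enumerate(predictors):
            others = np.delete(X, i, axis=1)
            A = sm.add_constant(others, has_constant="add")
            resid = X[:, i] - A @ np.linalg.lstsq(A, X[:, i], rcond=None)[0]
            tss = float(np.sum((X[:, i] - X[:, i].mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0
            vif[name] = float(1.0 / (1.0 - r2)) if r2 < 1 else float("inf")
    params = {"const": float(beta[0])}
    params.update({p: float(b) for p, b in zip(predictors, beta[1:])})
    return LogisticBaselineResult(
        model_id=model_id,
        predictors=tuple(predictors),
        params=params,
        confusion=confusion_metrics(y, preds),
        lr_chi2=float(lr),
        lr_df=lr_df,
        lr_p=lr_p,
        vif=vif,
        ridge_fallback=ridge,
        fitted_probabilities=probs,
    )


# ---------------------------------------------------------------------------
# Descriptive effect statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectStats:
    t: float
    df: int
    p: float
    d: float  # Cohen's d, (mean_flop - mean_hit) / pooled SD
    mean_flop: float
    mean_hit: float
    infinite: bool = False  # zero pooled variance with unequal means

    def to_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p, "d": self.d,
            "mean_flop": self.mean_flop, "mean_hit": self.mean_hit,
        }


def group_effect(flop_values, hit_values) -> EffectStats:
    """Pooled-variance Student t and Cohen's d with groups ordered (flop, hit)."""
    a = np.asarray(flop_values, dtype=float)
    b = np.asarray(hit_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return EffectStats(0.0, df, 1.0, 0.0, float(a.mean()), float(b.mean()))
        return EffectStats(
            float(np.sign(diff) * np.inf), df, 0.0, float(np.sign(diff) * np.inf),
            float(a.mean()), float(b.mean()), infinite=True,
        )
    sp = np.sqrt(sp2)
    t = diff / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return EffectStats(float(t), int(df), float(p), float(diff / sp), float(a.mean()), float(b.mean()))


def effect_stats(
    features: pd.DataFrame, column: str, label_col: str = "label"
) -> EffectStats:
    """Hit-vs-flop effect statistics for one feature column."""
    y = encode_labels(features[label_col])
    vals = features[column].to_numpy(dtype=float)
    return group_effect(vals[y == 0], vals[y == 1])


def correlation(x, y) -> tuple[float, float]:
    """Pearson r with its t-based two-sided p-value."""
    r, p = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)
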