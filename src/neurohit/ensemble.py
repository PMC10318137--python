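"""Super-learner ("bagged") ensemble classifier.

Four candidate learners — logistic regression, k-nearest neighbors, a kernel
SVM with Platt-calibrated probabilities, and a one-hidden-layer neural net —
are combined into a convex ensemble.  Each learner's hyperparameters may be
tuned by stratified 5-fold cross-validated squared error over the grids of
the study design; out-of-fold class-1 probabilities ``Z[i, j]`` (row i,
learner j) are then collected so that every row is predicted by a model that
never saw it, and the ensemble weights solve

    min_{beta >= 0}  sum_i (y_i - sum_j beta_j Z[i, j])^2

by non-negative least squares, normalized to the simplex.  The ensemble
prediction for a new row is ``sum_j beta_j * learner_j(row)`` and the class
is "hit" when that probability reaches the threshold (ties go to "hit").

Because single learners are vertices of the simplex, the ensemble's
cross-validated risk can never exceed the best single learner's.

KNN, SVM and ANN see z-scored features (scaling constants learned on the
training data): average immersion (~4.1) and retreat (~0.17) differ by an
order of magnitude in scale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.model_selection import StratifiedKFold
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "LearnerSpec",
    "CrossValPredictions",
    "default_learners",
    "paper_selected_params",
    "build_estimator",
    "tune_learner",
    "cv_out_of_fold",
    "fit_ensemble_weights",
    "ensemble_probability",
    "SuperLearner",
    "SuperLearnerResults",
]

_SVM_KERNELS = {"radial": "rbf", "polynomial": "poly", "tanh": "sigmoid"}
_ANN_ACTIVATIONS = {"linear": "identity", "softmax": "logistic"}


@dataclass
class LearnerSpec:
    """A candidate learner and its hyperparameter grid."""

    name: str  # logistic | knn | svm | ann
    grid: dict[str, list] = field(default_factory=dict)

    def grid_points(self) -> list[dict]:
        """Grid points in declaration order (ties in tuning break this way)."""
        if not self.grid:
            return [{}]
        keys = list(self.grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*self.grid.values())]


def default_learners() -> list[LearnerSpec]:
    """The study design's four learners with their tuning grids."""
    return [
        LearnerSpec("logistic", {"cost": [1, 10, 100]}),
        LearnerSpec("knn", {"k": [3, 5, 8, 10]}),
        LearnerSpec("svm", {"cost": [1, 10, 100], "kernel": ["radial", "polynomial", "tanh"]}),
        LearnerSpec(
            "ann",
            {"activation": ["linear", "softmax"], "size": [1, 5, 10], "decay": [0, 1, 10]},
        ),
    ]


def paper_selected_params() -> dict[str, dict]:
    """Hyperparameters selected by the study's own 5-fold tuning run."""
    return {
        "logistic": {"cost": 1},
        "knn": {"k": 3},
        "svm": {"cost": 10, "kernel": "tanh"},
        "ann": {"activation": "softmax", "size": 5, "decay": 1},
    }


def build_estimator(name: str, params: dict, seed: int = 0):
    """Instantiate a learner; KNN/SVM/ANN are pipelined behind a z-scorer."""
    if name == "logistic":
        return LogisticRegression(C=float(params.get("cost", 1)), max_iter=1000)
    if name == "knn":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("knn", KNeighborsClassifier(n_neighbors=int(params.get("k", 3)))),
            ]
        )
    if name == "svm":
        kernel = _SVM_KERNELS[params.get("kernel", "radial")]
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svm",
                    SVC(
                        C=float(params.get("cost", 1)),
                        kernel=kernel,
                        probability=True,
                        random_state=seed,
                    ),
                ),
            ]
        )
    if name == "ann":
        activation = _ANN_ACTIVATIONS[params.get("activation", "softmax")]
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "ann",
                    MLPClassifier(
                        hidden_layer_sizes=(int(params.get("size", 5)),),
                        activation=activation,
                        alpha=float(params.get("decay", 1)) or 1e-8,
                        max_iter=500,
                        random_state=seed,
                    ),
                ),
            ]
        )
    raise ValueError(f"unknown learner {name!r}")


def _proba1(est, X: np.ndarray) -> np.ndarray:
    """Probability of class 1, robust to the classes_ ordering."""
    proba = est.predict_proba(X)
    classes = list(getattr(est, "classes_", est[-1].classes_ if hasattr(est, "__getitem__") else []))
    col = classes.index(1)
    return np.clip(proba[:, col], 0.0, 1.0)


def _check_two_classes(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")


def _fit_quiet(est, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        est.fit(X, y)
    return est


def tune_learner(
    spec: LearnerSpec,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Pick the grid point minimizing stratified V-fold CV squared error.

    The criterion is the mean squared error of predicted class-1
    probabilities against the 0/1 labels; ties keep the earliest grid point.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    if folds < 2:
        raise ValueError("folds must be at least 2")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_params, best_risk = None, np.inf
    for params in spec.grid_points():
        sq = np.empty_like(y, dtype=float)
        for train_idx, test_idx in splits:
            est = _fit_quiet(build_estimator(spec.name, params, seed), X[train_idx], y[train_idx])
            p = _proba1(est, X[test_idx])
            sq[test_idx] = (y[test_idx] - p) ** 2
        risk = float(sq.mean())
        if risk < best_risk - 1e-12:
            best_risk, best_params = risk, params
    return best_params


@dataclass
class CrossValPredictions:
    """Out-of-fold class-1 probabilities, one column per learner."""

    Z: np.ndarray  # (n, n_learners), entries in [0, 1]
    y: np.ndarray  # (n,)
    fold_assignment: np.ndarray  # (n,)
    learner_names: list[str]


def cv_out_of_fold(
    learners: list[tuple[str, dict]],
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> CrossValPredictions:
    """Out-of-fold predictions: each row is predicted by a model that never saw it.

    Stratified folds; if a degenerate split leaves a training fold with one
    class, folds are redrawn with a shifted seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    n = len(y)
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if folds > n:
        raise ValueError(f"folds={folds} exceeds n={n}")
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(X, y))
        if all(np.unique(y[tr]).size == 2 for tr, _ in splits):
            break
    else:
        raise ValueError("could not draw folds with both classes in every training fold")
    Z = np.empty((n, len(learners)))
    fold_assignment = np.empty(n, dtype=int)
    for f, (train_idx, test_idx) in enumerate(splits):
        fold_assignment[test_idx] = f
        for j, (name, params) in enumerate(learners):
            est = _fit_quiet(build_estimator(name, params, seed), X[train_idx], y[train_idx])
            Z[test_idx, j] = _proba1(est, X[test_idx])
    return CrossValPredictions(
        Z=Z, y=y, fold_assignment=fold_assignment, learner_names=[n_ for n_, _ in learners]
    )


def fit_ensemble_weights(cv: CrossValPredictions) -> tuple[np.ndarray, np.ndarray]:
    """Simplex weights by NNLS on out-of-fold predictions, plus per-learner risks.

    Solves min_{beta>=0} ||y - Z beta||^2 then normalizes beta to sum to 1
    (an all-zero solution falls back to uniform weights).  Per-learner risk
    is the mean squared error of that learner's out-of-fold column.
    """
    Z, y = cv.Z, cv.y
    if Z.ndim != 2 or Z.shape[1] < 1 or Z.shape[0] == 0:
        raise ValueError("Z must be a non-empty (n, n_learners) matrix")
    m = Z.shape[1]
    beta, _ = nnls(Z, y.astype(float))
    total = beta.sum()
    if total <= 0:
        beta = np.full(m, 1.0 / m)
    else:
        beta = beta / total
    if m > 1:
        beta = _simplex_polish(Z, y.astype(float), beta)
    risks = ((y[:, None] - Z) ** 2).mean(axis=0)
    return beta, risks


def _simplex_polish(Z: np.ndarray, y: np.ndarray, start: np.ndarray) -> np.ndarray:
    """Refine normalized-NNLS weights to the simplex-constrained LS optimum.

    Normalizing an NNLS solution rescales it off its own optimum, which can
    leave the ensemble risk slightly above the best single learner's; a short
    constrained solve from the NNLS start (also compared against every
    vertex) restores the guarantee that vertices are feasible.
    """
    from scipy.optimize import minimize

    m = Z.shape[1]
    ZtZ = Z.T @ Z / len(y)
    Zty = Z.T @ y / len(y)
    yty = float(y @ y) / len(y)
    risk = lambda b: yty - 2.0 * b @ Zty + b @ ZtZ @ b
    grad = lambda b: 2.0 * (ZtZ @ b - Zty)
    candidates = [start] + [np.eye(m)[j] for j in range(m)]
    best = min(candidates, key=risk)
    res = minimize(
        risk,
        best,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda b: b.sum() - 1.0}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    if res.success and risk(res.x) <= risk(best):
        best = np.clip(res.x, 0.0, None)
        best = best / best.sum()
    return best


def ensemble_probability(weights: np.ndarray, learner_probs: np.ndarray) -> np.ndarray:
    """Weighted probability sum_j beta_j p_j; weights must lie on the simplex."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < -1e-9) or abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError(
            f"weights must be non-negative and sum to 1, got {weights} (sum {weights.sum()})"
        )
    return np.clip(np.asarray(learner_probs, dtype=float) @ weights, 0.0, 1.0)


class SuperLearner:
    """Super-learner model over a song-feature table.

    Parameters
    ----------
    X, y : arrays
        Features and 0/1 labels (1 = hit).
    learners : list of LearnerSpec, optional
        Defaults to the four study learners.
    tune : bool
        Grid-tune each learner by stratified CV squared error; when False the
        study's selected settings are used directly.
    tune_subsample : int, optional
        Stratified subsample size used only for the tuning grid search.
    """

    def __init__(
        self,
        X,
        y,
        learners: list[LearnerSpec] | None = None,
        folds: int = 5,
        tune: bool = False,
        tune_subsample: int | None = None,
        threshold: float = 0.5,
        seed: int = 0,
        feature_names: list[str] | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        _check_two_classes(self.y)
        self.learners = learners if learners is not None else default_learners()
        self.folds = folds
        self.tune = tune
        self.tune_subsample = tune_subsample
        self.threshold = threshold
        self.seed = seed
        self.feature_names = feature_names

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_cols: tuple[str, ...] = ("avg_immersion", "retreat"),
        label_col: str = "label",
        **kwargs,
    ) -> "SuperLearner":
        y = encode_labels(df[label_col])
        X = df[list(feature_cols)].to_numpy(dtype=float)
        return cls(X, y, feature_names=list(feature_cols), **kwargs)

    def _tuning_view(self) -> tuple[np.ndarray, np.ndarray]:
        if self.tune_subsample is None or self.tune_subsample >= len(self.y):
            return self.X, self.y
        rng = np.random.default_rng(self.seed)
        idx = []
        for cls_ in np.unique(self.y):
            members = np.flatnonzero(self.y == cls_)
            take = max(2, int(round(self.tune_subsample * members.size / len(self.y))))
            idx.append(rng.choice(members, size=min(take, members.size), replace=False))
        idx = np.concatenate(idx)
        return self.X[idx], self.y[idx]

    def fit(self) -> "SuperLearnerResults":
        if self.tune:
            Xt, yt = self._tuning_view()
            selected = {
                spec.name: tune_learner(spec, Xt, yt, folds=self.folds, seed=self.seed)
                for spec in self.learners
            }
        else:
            defaults = paper_selected_params()
            selected = {
                spec.name: defaults.get(spec.name, spec.grid_points()[0])
                for spec in self.learners
            }
        pairs = [(spec.name, selected[spec.name]) for spec in self.learners]
        cv = cv_out_of_fold(pairs, self.X, self.y, folds=self.folds, seed=self.seed)
        weights, risks = fit_ensemble_weights(cv)
        ensemble_risk = float(((cv.y - cv.Z @ weights) ** 2).mean())
        fitted = [
            _fit_quiet(build_estimator(name, params, self.seed), self.X, self.y)
            for name, params in pairs
        ]
        return SuperLearnerResults(
            model=self,
            learner_names=[name for name, _ in pairs],
            selected_params={name: params for name, params in pairs},
            weights=weights,
            cv_risks=risks,
            ensemble_cv_risk=ensemble_risk,
            fitted_learners=fitted,
            threshold=self.threshold,
        )


@dataclass
class SuperLearnerResults:
    """Fitted super learner: simplex weights, risks and member models."""

    model: SuperLearner
    learner_names: list[str]
    selected_params: dict[str, dict]
    weights: np.ndarray
    cv_risks: np.ndarray
    ensemble_cv_risk: float
    fitted_learners: list
    threshold: float = 0.5

    def learner_probabilities(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack([_proba1(est, X) for est in self.fitted_learners])

    def predict_proba(self, X) -> np.ndarray:
        """Ensemble hit probability for each row."""
        return ensemble_probability(self.weights, self.learner_probabilities(X))

    def predict(self, X) -> np.ndarray:
        """0/1 labels; a probability exactly at the threshold counts as a hit."""
        return (self.predict_proba(X) >= self.threshold).astype(int)

    def predict_frame(self, df: pd.DataFrame) -> np.ndarray:
        cols = self.model.feature_names or ["avg_immersion", "retreat"]
        return self.predict(df[cols].to_numpy(dtype=float))

    def summary(self) -> str:
        lines = [
            "Super-learner ensemble (hit vs flop)",
            f"  rows: {len(self.model.y)}   folds: {self.model.folds}   "
            f"threshold: {self.threshold}",
            f"  ensemble CV risk (squared error): {self.ensemble_cv_risk:.4f}",
            f"  {'learner':<10}{'weight':>9}{'cv risk':>10}  params",
        ]
        for name, w, r in zip(self.learner_names, self.weights, self.cv_risks):
            lines.append(f"  {name:<10}{w:>9.4f}{r:>10.4f}  {self.selected_params[name]}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "learners": self.learner_names,
            "selected_params": self.selected_params,
            "weights": [float(w) for w in self.weights],
            "cv_risks": [float(r) for r in self.cv_risks],
            "ensemble_cv_risk": self.ensemble_cv_risk,
            "threshold": self.threshold,
        }

    def plot_weights(self, ax=None):
        """Bar plot of learner weights and cross-validated risks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        x = np.arange(len(self.learner_names))
        ax.bar(x - 0.2, self.weights, width=0.4, label="weight")
        ax.bar(x + 0.2, self.cv_risks, width=0.4, label="CV risk")
        ax.set_xticks(x, self.learner_names)
        ax.set_ylabel("weight / squared-error risk")
        ax.legend(frameon=False)
        return ax


def encode_labels(labels) -> np.ndarray:
    """Map hit/flop labels (or 0/1) to integers with hit = 1."""
    arr = pd.Series(labels)
    if arr.dtype == object or isinstance(arr.dtype, pd.CategoricalDtype):
        mapped = arr.str.lower().map({"hit": 1, "flop": 0})
        if mapped.isna().any():
            bad = arr[mapped.isna()].unique()
            raise ValueError(f"unknown labels {list(bad)}; expected hit/flop")
        return mapped.to_numpy(dtype=int)
    vals = arr.to_numpy()
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("numeric labels must be 0/1")
    return vals.astype(int)
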