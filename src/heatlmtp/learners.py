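"""Cross-validated stacked ensembles for outcome regressions and
density-ratio classifiers.

The stack is the canonical SuperLearner: V-fold cross-validated
predictions from a library of base learners, convex meta-weights chosen
by minimising the cross-validated loss over the probability simplex
(non-negative least squares for squared error, constrained log-loss
minimisation for binary probabilities), and a final refit of every
member on the full data.

Two libraries ship by default.  ``full`` mirrors a routine applied
library: main-effects linear model, ridge-shrunken (Bayesian-style)
linear model, L1-regularised linear model, penalised additive spline
model, random forest, extreme gradient boosting, and a constant-mean
benchmark.  ``fast`` (linear, lasso, gradient boosting, mean) is the
test-suite and simulation default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize, nnls
from sklearn.base import clone
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.linear_model import (
    BayesianRidge,
    LassoCV,
    LinearRegression,
    LogisticRegression,
    Ridge,
)
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from xgboost import XGBClassifier, XGBRegressor

Task = Literal["regression", "binary-probability"]

_PROB_EPS = 1e-12  # log-loss guard only; ratio clipping is handled upstream


@dataclass(frozen=True)
class LearnerSpec:
    name: str
    make_regressor: Callable[[int], object]
    make_classifier: Callable[[int], object]


def _xgb_params(seed: int, fast: bool) -> dict:
    return dict(
        n_estimators=30 if fast else 150,
        max_depth=3 if fast else 4,
        learning_rate=0.3 if fast else 0.1,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )


def _spec_linear() -> LearnerSpec:
    # scaling only conditions the solver; predictions are unchanged
    return LearnerSpec(
        "linear",
        lambda seed: LinearRegression(),
        lambda seed: make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000)
        ),
    )


def _spec_bayes() -> LearnerSpec:
    # shrunken linear model; the classifier analogue is ridge-penalised
    return LearnerSpec(
        "bayes_glm",
        lambda seed: BayesianRidge(),
        lambda seed: make_pipeline(
            StandardScaler(), LogisticRegression(C=0.5, max_iter=1000)
        ),
    )


def _spec_lasso() -> LearnerSpec:
    # penalty strength tuned by internal CV, as in routine glmnet usage
    return LearnerSpec(
        "lasso",
        lambda seed: make_pipeline(
            StandardScaler(), LassoCV(cv=3, alphas=30, max_iter=2000, tol=1e-3)
        ),
        lambda seed: make_pipeline(
            StandardScaler(),
            LogisticRegression(
                solver="liblinear", l1_ratio=1.0, C=1.0, max_iter=1000,
                random_state=seed,
            ),
        ),
    )


def _spec_splines() -> LearnerSpec:
    # additive penalised spline model (flexible smooth main effects)
    def reg(seed: int):
        return make_pipeline(
            SplineTransformer(n_knots=5, degree=3), Ridge(alpha=1.0)
        )

    def clf(seed: int):
        return make_pipeline(
            SplineTransformer(n_knots=5, degree=3),
            LogisticRegression(C=1.0, max_iter=2000),
        )

    return LearnerSpec("splines", reg, clf)


def _spec_forest() -> LearnerSpec:
    return LearnerSpec(
        "random_forest",
        lambda seed: RandomForestRegressor(
            n_estimators=200, min_samples_leaf=5, n_jobs=1, random_state=seed
        ),
        lambda seed: RandomForestClassifier(
            n_estimators=200, min_samples_leaf=5, n_jobs=1, random_state=seed
        ),
    )


def _spec_xgb(fast: bool) -> LearnerSpec:
    name = "xgboost"
    return LearnerSpec(
        name,
        lambda seed: XGBRegressor(**_xgb_params(seed, fast)),
        lambda seed: XGBClassifier(**_xgb_params(seed, fast)),
    )


def _spec_mean() -> LearnerSpec:
    return LearnerSpec(
        "mean",
        lambda seed: DummyRegressor(strategy="mean"),
        lambda seed: DummyClassifier(strategy="prior"),
    )


@dataclass
class LearnerLibrary:
    """An ordered collection of named base learners."""

    members: tuple[LearnerSpec, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a learner library needs at least one member")

    @property
    def member_names(self) -> list[str]:
        return [m.name for m in self.members]

    @classmethod
    def full(cls) -> "LearnerLibrary":
        return cls(
            (
                _spec_linear(),
                _spec_bayes(),
                _spec_lasso(),
                _spec_splines(),
                _spec_forest(),
                _spec_xgb(fast=False),
                _spec_mean(),
            ),
            name="full",
        )

    @classmethod
    def fast(cls) -> "LearnerLibrary":
        return cls(
            (_spec_linear(), _spec_lasso(), _spec_xgb(fast=True), _spec_mean()),
            name="fast",
        )

    @classmethod
    def mean_only(cls) -> "LearnerLibrary":
        """Constant-mean benchmark alone (used in robustness checks)."""
        return cls((_spec_mean(),), name="mean_only")

    @classmethod
    def named(cls, name: str) -> "LearnerLibrary":
        table = {"full": cls.full, "fast": cls.fast, "mean_only": cls.mean_only}
        try:
            return table[name]()
        except KeyError:
            raise ValueError(
                f"unknown library {name!r}; choose from {sorted(table)}"
            ) from None


@dataclass
class StackedModel:
    """A fitted convex combination of base learners."""

    task: Task
    specs: tuple[LearnerSpec, ...]
    fitted_members: list[object]
    meta_weights: np.ndarray
    cv_risks: np.ndarray
    cv_folds: int
    seed: int
    bounds: tuple[float, float] | None = None

    @property
    def member_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def predict(self, features: np.ndarray) -> np.ndarray:
        return predict_stack(self, features)


def _member_predict(model, X: np.ndarray, task: Task) -> np.ndarray:
    if task == "binary-probability":
        proba = model.predict_proba(X)
        classes = getattr(model, "classes_", None)
        if classes is not None and len(classes) == 2:
            return proba[:, list(classes).index(1)]
        if proba.shape[1] == 1:  # degenerate single-class fit
            return np.full(X.shape[0], float(classes[0]) if classes is not None else 0.5)
        return proba[:, -1]
    return np.asarray(model.predict(X), dtype=float)


def _log_loss(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _PROB_EPS, 1 - _PROB_EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _solve_weights_regression(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    w, _ = nnls(Z, y)
    total = w.sum()
    if total <= 0:
        return None  # caller falls back to the mean learner
    w = w / total
    # polish on the simplex: normalised NNLS is the canonical start but is
    # not the constrained optimum, and the oracle inequality (stack risk
    # <= best member risk) should hold exactly
    m = Z.shape[1]
    res = minimize(
        lambda v: float(np.mean((y - Z @ v) ** 2)),
        w,
        jac=lambda v: (2.0 / len(y)) * (Z.T @ (Z @ v - y)),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda v: v.sum() - 1.0}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    if res.success:
        candidate = np.clip(res.x, 0.0, None)
        if candidate.sum() > 0:
            candidate = candidate / candidate.sum()
            if np.mean((y - Z @ candidate) ** 2) <= np.mean((y - Z @ w) ** 2):
                w = candidate
    # never lose to the best single member
    risks = np.mean((y[:, None] - Z) ** 2, axis=0)
    best = int(np.argmin(risks))
    if np.mean((y - Z @ w) ** 2) > risks[best]:
        w = np.zeros(m)
        w[best] = 1.0
    return w


def _solve_weights_logloss(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    m = Z.shape[1]
    x0 = np.full(m, 1.0 / m)

    def objective(w):
        return _log_loss(y, Z @ w)

    res = minimize(
        objective,
        x0,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 200, "ftol": 1e-10},
    )
    w = np.clip(res.x, 0.0, None)
    total = w.sum()
    if not res.success or total <= 0:
        # fall back to the single best member by CV risk
        risks = [_log_loss(y, Z[:, j]) for j in range(m)]
        w = np.zeros(m)
        w[int(np.argmin(risks))] = 1.0
        return w
    return w / total


def fit_stack(
    features: np.ndarray,
    target: np.ndarray,
    library: LearnerLibrary,
    folds: int = 5,
    seed: int = 0,
    task: Task = "regression",
    bounds: tuple[float, float] | None = None,
) -> StackedModel:
    """Fit a cross-validated stack.

    Out-of-fold member predictions are collected over ``folds`` shuffled
    splits; meta-weights minimise squared error (regression) or log loss
    (binary probabilities) over the simplex; members are then refit on the
    full data.  A constant target collapses the stack onto the mean
    learner.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-d matrix")
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("features and target disagree on the sample size")
    if folds < 2:
        raise ValueError("need at least 2 cross-validation folds")
    if n < folds:
        raise ValueError("need at least as many rows as folds")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("features/target contain missing or non-finite values")

    specs = library.members
    names = [s.name for s in specs]

    if np.ptp(y) == 0.0:
        warnings.warn(
            "constant target: stack collapsed to the mean learner",
            stacklevel=2,
        )
        mean_spec = next((s for s in specs if s.name == "mean"), _spec_mean())
        fitted = _fit_member(mean_spec, X, y, task, seed)
        return StackedModel(
            task=task,
            specs=(mean_spec,),
            fitted_members=[fitted],
            meta_weights=np.array([1.0]),
            cv_risks=np.array([0.0]),
            cv_folds=folds,
            seed=seed,
            bounds=bounds,
        )

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    Z = np.empty((n, len(specs)), dtype=float)
    for train_idx, test_idx in kf.split(X):
        for j, spec in enumerate(specs):
            model = _fit_member(spec, X[train_idx], y[train_idx], task, seed)
            Z[test_idx, j] = _member_predict(model, X[test_idx], task)

    if task == "binary-probability":
        Z = np.clip(Z, 0.0, 1.0)
        cv_risks = np.array([_log_loss(y, Z[:, j]) for j in range(len(specs))])
        weights = _solve_weights_logloss(Z, y)
    else:
        cv_risks = np.array([float(np.mean((y - Z[:, j]) ** 2)) for j in range(len(specs))])
        weights = _solve_weights_regression(Z, y)
        if weights is None:
            weights = np.zeros(len(specs))
            mean_idx = names.index("mean") if "mean" in names else int(np.argmin(cv_risks))
            weights[mean_idx] = 1.0

    fitted = [_fit_member(spec, X, y, task, seed) for spec in specs]
    return StackedModel(
        task=task,
        specs=specs,
        fitted_members=fitted,
        meta_weights=weights,
        cv_risks=cv_risks,
        cv_folds=folds,
        seed=seed,
        bounds=bounds,
    )


def _fit_member(spec: LearnerSpec, X, y, task: Task, seed: int):
    if task == "binary-probability":
        model = clone(spec.make_classifier(seed))
        model.fit(X, y.astype(int))
    else:
        model = clone(spec.make_regressor(seed))
        model.fit(X, y)
    return model


def predict_stack(model: StackedModel, features: np.ndarray) -> np.ndarray:
    """Weighted combination of member predictions, clipped to any bounds."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-d matrix")
    n_features = _n_features(model.fitted_members[0])
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {n_features}, "
            f"got {X.shape[1]}"
        )
    pred = np.zeros(X.shape[0], dtype=float)
    for w, member in zip(model.meta_weights, model.fitted_members):
        if w == 0.0:
            continue
        pred += w * _member_predict(member, X, model.task)
    if model.task == "binary-probability":
        pred = np.clip(pred, 0.0, 1.0)
    elif model.bounds is not None:
        pred = np.clip(pred, model.bounds[0], model.bounds[1])
    return pred


def _n_features(member) -> int | None:
    if hasattr(member, "n_features_in_"):
        return int(member.n_features_in_)
    steps = getattr(member, "steps", None)
    if steps:
        return _n_features(steps[0][1])
    return None
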