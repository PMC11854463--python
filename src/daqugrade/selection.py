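"""Feature selection for the premium vs. first-grade (layer-2) task.

Four selectors produce per-feature importance scores and a retained subset:

* **RF-MDA** — random-forest mean decrease in accuracy: for each tree of a
  bootstrap ensemble, out-of-bag accuracy is compared with and without
  permuting a feature column; the drop, averaged over trees and repeats,
  is the importance.
* **RFE** — recursive feature elimination: repeatedly refit a base model
  and drop the weakest feature (by coefficient magnitude or impurity
  importance) until ``n_keep`` remain.
* **LASSO** — minimize sum of squared errors + lambda * sum |beta_j|; the L1
  penalty zeroes weak coefficients, so the selected set is the support.
* **Ridge** — minimize sum of squared errors + lambda * sum beta_j^2; scores
  are |beta_j| at the CV-optimal lambda.

Both regularized selectors choose lambda by k-fold cross-validated mean
squared error over a grid of 100 logarithmically spaced points spanning
[0.01, 100] (10 folds by default); lambda is on the raw
sum-of-squares loss scale throughout.  Binary labels are encoded {0, 1} so
the regression losses apply as written.  Features are standardized
(mean 0, unit population variance) before LASSO/ridge/RFE fits, and
scores are reported on the standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE as SkRFE
from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable

METHODS = ("rf_mda", "rfe", "lasso", "ridge")

#: cap on the retained subset size for score-thresholded selectors
DEFAULT_MAX_SELECTED = 20
#: scores are rounded at this resolution before the "> 0" retention rule
SCORE_ROUNDING = 1e-4


@dataclass
class SelectionResult:
    method: str
    scores: np.ndarray                   # per-feature importance / |coefficient|
    feature_names: Sequence[str]
    selected: list[str]
    lambda_opt: Optional[float] = None
    cv_curve: Optional[list[tuple[float, float]]] = None  # (lambda, mean CV MSE)
    ranking: Optional[np.ndarray] = None  # RFE elimination rank (1 = kept)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.scores) != len(self.feature_names):
            raise ValueError("scores length must equal number of features")
        unknown = set(self.selected) - set(self.feature_names)
        if unknown:
            raise ValueError(f"selected features not in table: {sorted(unknown)}")


def default_lambda_grid() -> np.ndarray:
    """100 logarithmically equally spaced regularization strengths in [0.01, 100]."""
    return np.logspace(np.log10(0.01), np.log10(100.0), 100)


def _check_table(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    X = table.matrix
    y = np.asarray(table.labels).astype(np.float64)
    if X.shape[1] == 0:
        raise ValueError("table has no features")
    if np.unique(y).size < 2:
        raise ValueError("labels are single-class; selection undefined")
    return X, y


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _top_scored(scores: np.ndarray, names: Sequence[str],
                cutoff: float = 0.0, cap: int = DEFAULT_MAX_SELECTED) -> list[str]:
    rounded = np.round(scores / SCORE_ROUNDING) * SCORE_ROUNDING
    order = np.argsort(-rounded, kind="stable")
    keep = [i for i in order if rounded[i] > cutoff][:cap]
    return [names[i] for i in sorted(keep)]


def rf_mda_importance(
    table: FeatureTable,
    n_trees: int = 200,
    n_repeats: int = 1,
    seed: int = 0,
    max_features: str | int | float = "sqrt",
) -> SelectionResult:
    """Out-of-bag permutation importance of a bootstrap tree ensemble.

    Importance of feature j = mean over trees (and ``n_repeats`` permutations
    per tree) of (OOB accuracy − OOB accuracy with column j permuted).  A
    constant column scores exactly 0 since permuting it is a no-op.
    """
    X, y = _check_table(table)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    n, p = X.shape
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    used = 0
    for t in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_features, random_state=int(rng.integers(2 ** 31))
        )
        tree.fit(X[boot], y[boot], sample_weight=table.weights[boot])
        X_oob = X[oob]
        y_oob = y[oob]
        base = float((tree.predict(X_oob) == y_oob).mean())
        for j in range(p):
            col = X_oob[:, j]
            if np.all(col == col[0]):
                continue  # permutation is a no-op; drop stays 0
            for _ in range(n_repeats):
                perm = rng.permutation(oob.size)
                Xp = X_oob.copy()
                Xp[:, j] = col[perm]
                drops[j] += base - float((tree.predict(Xp) == y_oob).mean())
        used += 1
    if used == 0:
        raise ValueError("no tree had out-of-bag samples")
    scores = drops / (used * n_repeats)
    names = list(table.feature_names)
    return SelectionResult(
        method="rf_mda", scores=scores, feature_names=names,
        selected=_top_scored(scores, names),
        extras={"n_trees": n_trees, "n_repeats": n_repeats, "oob_trees": used},
    )


def _base_estimator(spec: str, seed: int):
    if spec == "lr":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if spec == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown base estimator spec {spec!r}; use 'lr' or 'rf'")


def rfe_select(
    table: FeatureTable,
    base_estimator_spec: str = "lr",
    n_keep: int = DEFAULT_MAX_SELECTED,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination down to ``n_keep`` features.

    Scores encode the elimination order, rescaled to (0, 1]: the last
    surviving features score highest.
    """
    X, y = _check_table(table)
    p = X.shape[1]
    if not 1 <= n_keep <= p:
        raise ValueError(f"n_keep must be in [1, {p}], got {n_keep}")
    est = _base_estimator(base_estimator_spec, seed)
    Xs = _standardize(X) if base_estimator_spec == "lr" else X
    rfe = SkRFE(estimator=est, n_features_to_select=n_keep, step=1)
    rfe.fit(Xs, y)
    ranking = rfe.ranking_.astype(np.int64)
    scores = (p - ranking + 1) / p  # rank 1 (kept) -> 1.0
    names = list(table.feature_names)
    selected = [names[i] for i in range(p) if rfe.support_[i]]
    return SelectionResult(
        method="rfe", scores=scores, feature_names=names, selected=selected,
        ranking=ranking, extras={"base_estimator": base_estimator_spec, "n_keep": n_keep},
    )


def _cv_mse(make_model, lam_grid, X, y, cv_folds, seed):
    if cv_folds < 2 or cv_folds > len(y):
        raise ValueError("cv_folds must be in [2, n]")
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    curve = []
    for lam in lam_grid:
        errs = []
        for tr, te in splits:
            model = make_model(lam)
            model.fit(X[tr], y[tr])
            resid = y[te] - model.predict(X[te])
            errs.append(float(np.mean(resid ** 2)))
        curve.append((float(lam), float(np.mean(errs))))
    mses = np.array([m for _, m in curve])
    lambda_opt = float(lam_grid[int(np.argmin(mses))])  # ties -> smaller lambda
    return lambda_opt, curve


def lasso_select(
    table: FeatureTable,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """L1-regularized selection: support of the CV-optimal LASSO fit.

    lambda is on the sum-of-squares loss scale (loss = SSE + lambda * sum|beta|);
    the solver's internal parameterization divides the SSE by 2n, so
    alpha = lambda / (2n) under the hood.
    """
    X, y = _check_table(table)
    if np.unique(y).size < 2 or np.std(y) == 0:
        raise ValueError("constant response; LASSO undefined")
    lam_grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if lam_grid.size == 0:
        raise ValueError("lambda_grid must be non-empty")
    Xs = _standardize(X)
    n = len(y)

    def make(lam):
        return Lasso(alpha=max(lam, 1e-12) / (2 * n), fit_intercept=True, max_iter=50_000)

    lambda_opt, curve = _cv_mse(make, lam_grid, Xs, y, cv_folds, seed)
    model = make(lambda_opt).fit(Xs, y)
    coef = model.coef_
    names = list(table.feature_names)
    selected = [names[j] for j in range(len(names)) if coef[j] != 0.0]
    return SelectionResult(
        method="lasso", scores=np.abs(coef), feature_names=names, selected=selected,
        lambda_opt=lambda_opt, cv_curve=curve, extras={"coef": coef},
    )


def fit_lasso_fixed(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Coefficients minimizing SSE + lam * sum|beta| at a fixed lam (intercept fitted)."""
    n = len(y)
    model = Lasso(alpha=max(lam, 1e-12) / (2 * n), fit_intercept=True,
                  max_iter=200_000, tol=1e-10)
    model.fit(X, y)
    return model.coef_


def fit_ridge_fixed(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Coefficients minimizing SSE + lam * sum beta^2 at a fixed lam (intercept fitted)."""
    if lam == 0:
        return LinearRegression().fit(X, y).coef_
    model = Ridge(alpha=lam, fit_intercept=True, solver="cholesky")
    model.fit(X, y)
    return model.coef_


def ridge_select(
    table: FeatureTable,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    score_cutoff: float = SCORE_ROUNDING,
) -> SelectionResult:
    """L2-regularized selection: |coefficients| at the CV-optimal ridge fit.

    The default grid is 100 log-spaced lambdas in [0.01, 100] with 10-fold CV;
    retained features are those whose |beta| clears ``score_cutoff``, capped
    at the strongest 20.
    """
    X, y = _check_table(table)
    lam_grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if lam_grid.size == 0:
        raise ValueError("lambda_grid must be non-empty")
    Xs = _standardize(X)

    def make(lam):
        return Ridge(alpha=lam, fit_intercept=True) if lam > 0 else LinearRegression()

    lambda_opt, curve = _cv_mse(make, lam_grid, Xs, y, cv_folds, seed)
    coef = fit_ridge_fixed(Xs, y, lambda_opt)
    scores = np.abs(coef)
    names = list(table.feature_names)
    selected = _top_scored(scores, names, cutoff=score_cutoff - SCORE_ROUNDING / 2)
    return SelectionResult(
        method="ridge", scores=scores, feature_names=names, selected=selected,
        lambda_opt=lambda_opt, cv_curve=curve, extras={"coef": coef},
    )


def select(table: FeatureTable, method: str, config: dict | None = None) -> SelectionResult:
    """Dispatch to a selector by name with per-method defaults.

    ``config`` keys are forwarded to the selector; ``cutoff=-inf`` with a
    score-thresholded method retains every feature.
    """
    config = dict(config or {})
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown selection method {method!r}; choose from {METHODS}")
    cutoff = config.pop("cutoff", None)
    if method == "rf_mda":
        result = rf_mda_importance(table, **config)
    elif method == "rfe":
        result = rfe_select(table, **config)
    elif method == "lasso":
        result = lasso_select(table, **config)
    else:
        result = ridge_select(table, **config)
    if cutoff is not None and method != "lasso":
        names = list(table.feature_names)
        cap = len(names) if cutoff == -np.inf else DEFAULT_MAX_SELECTED
        result.selected = _top_scored(result.scores, names, cutoff=cutoff, cap=cap)
    return result
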