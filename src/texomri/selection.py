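"""LASSO-penalized logistic feature selection.

The screened features are de-correlated with an L1-penalized logistic
regression path: features are standardized internally, a log-spaced penalty
grid descends from lambda_max (the smallest penalty at which every
coefficient is zero), the penalty is chosen by k-fold cross-validated
deviance (minimum rule by default, one-standard-error rule behind a flag),
and the features with nonzero coefficients at the chosen penalty are the
selected subset.

The objective is the glmnet-style (1/n) sum of logistic losses plus
lambda * ||w||_1, solved per grid point by scikit-learn's liblinear
coordinate-descent solver (C = 1 / (n * lambda)); a large intercept scaling
keeps the intercept effectively unpenalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["LassoResult", "lasso_select", "lambda_max"]

_COEF_TOL = 1e-8


@dataclass
class LassoResult:
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray        # mean held-out deviance per lambda
    cv_deviance_se: np.ndarray
    lambda_chosen: float
    nonzero_features: Dict[str, float]   # name -> coefficient (standardized scale)
    coef_path: np.ndarray          # (n_lambda, n_features) full-data path
    seed: int

    @property
    def selected(self) -> List[str]:
        return list(self.nonzero_features)


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that zeroes every coefficient (standardized design)."""
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(y)
    return float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n)


def _l1_model() -> LogisticRegression:
    return LogisticRegression(
        l1_ratio=1.0,
        solver="liblinear",
        max_iter=200,
        tol=1e-4,
        C=1.0,
        random_state=0,  # liblinear shuffles coordinates internally
    )


def _null_deviance(y: np.ndarray) -> float:
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        return 1.0
    n = len(y)
    return float(-2 * n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar)))


def _fit_path(Xs: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """L1-logistic coefficients at each grid lambda.

    The descent down the grid terminates early once the explained-deviance
    ratio saturates (change < 1e-5 between grid points, or ratio > 0.999),
    the standard path-stopping rule; later grid points inherit the last
    fitted coefficients.
    """
    n = len(y)
    model = _l1_model()
    nulldev = _null_deviance(y)
    coefs = np.zeros((len(grid), Xs.shape[1]))
    prev_ratio = 0.0
    for k, lam in enumerate(grid):
        model.C = 1.0 / (n * lam)
        model.fit(Xs, y)
        coefs[k] = model.coef_[0]
        ratio = 1.0 - _deviance(model, Xs, y) / nulldev
        if k > 0 and (ratio - prev_ratio < 1e-5 or ratio > 0.999):
            coefs[k + 1 :] = coefs[k]
            break
        prev_ratio = ratio
    return coefs


def _deviance(model: LogisticRegression, Xs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(model.predict_proba(Xs)[:, 1], 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Optional[List[str]] = None,
    k_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    grid_decades: float = 4.0,
    one_se_rule: bool = False,
) -> LassoResult:
    """Cross-validated LASSO-logistic selection over a penalty path.

    Fold assignment is a deterministic function of `seed`; an empty feature
    matrix (nothing survived screening) returns an explicit empty selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    y01 = (y == classes.max()).astype(float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be (n_samples, n_features) matching y")
    if X.shape[1] == 0:
        return LassoResult(
            lambda_grid=np.array([]),
            cv_deviance=np.array([]),
            cv_deviance_se=np.array([]),
            lambda_chosen=float("nan"),
            nonzero_features={},
            coef_path=np.zeros((0, 0)),
            seed=seed,
        )
    if len(y) < 2 * k_folds:
        raise ValueError("need at least 2 samples per CV fold")
    names = feature_names if feature_names is not None else [
        f"x{i}" for i in range(X.shape[1])
    ]

    lmax = lambda_max(X, y01)
    if lmax == 0:  # degenerate: no feature correlates with the labels at all
        lmax = 1e-3
    grid = np.logspace(np.log10(lmax), np.log10(lmax) - grid_decades, n_lambdas)

    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_dev = np.zeros((k_folds, n_lambdas))
    for f, (tr, te) in enumerate(cv.split(X, y01)):
        Xtr, mu, sd = _standardize(X[tr])
        Xte = (X[te] - mu) / sd
        ytr, yte = y01[tr], y01[te]
        n_tr = len(tr)
        model = _l1_model()
        nulldev = _null_deviance(ytr)
        prev_ratio = 0.0
        for k, lam in enumerate(grid):
            model.C = 1.0 / (n_tr * lam)
            model.fit(Xtr, ytr)
            fold_dev[f, k] = _deviance(model, Xte, yte) / len(te)
            ratio = 1.0 - _deviance(model, Xtr, ytr) / nulldev
            if k > 0 and (ratio - prev_ratio < 1e-5 or ratio > 0.999):
                # path saturated: the model no longer changes down the grid
                fold_dev[f, k + 1 :] = fold_dev[f, k]
                break
            prev_ratio = ratio
    cv_dev = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(k_folds)

    best = int(np.argmin(cv_dev))
    if one_se_rule:
        limit = cv_dev[best] + cv_se[best]
        # most-penalized lambda whose deviance is within one SE of the minimum
        best = int(np.nonzero(cv_dev <= limit)[0][0])
    lam_chosen = float(grid[best])

    Xs, _, _ = _standardize(X)
    coef_path = _fit_path(Xs, y01, grid)
    chosen_coefs = coef_path[best]
    nonzero = {
        names[j]: float(chosen_coefs[j])
        for j in range(X.shape[1])
        if abs(chosen_coefs[j]) > _COEF_TOL
    }
    return LassoResult(
        lambda_grid=grid,
        cv_deviance=cv_dev,
        cv_deviance_se=cv_se,
        lambda_chosen=lam_chosen,
        nonzero_features=nonzero,
        coef_path=coef_path,
        seed=seed,
    )
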