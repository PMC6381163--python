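"""LASSO-penalized logistic feature selection with cross-validated lambda.

The model minimizes ``(1/n) * binomial deviance + lambda * ||beta||_1`` with
an unpenalized intercept on standardized features, along a glmnet-style grid
of 100 log-spaced lambda values from lambda_max (the smallest lambda with an
all-zero solution) down to 1e-4 * lambda_max, warm-started.  The optimal
lambda minimizes the mean held-out binomial deviance over stratified
10-fold cross-validation (minimum criterion, not 1-SE); the surviving
features are the nonzero support of the full-data refit at that lambda.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "standardize_features",
    "lambda_max",
    "make_lambda_grid",
    "fit_lasso_path",
    "choose_lambda_cv",
]


@dataclass
class SelectionResult:
    lambda_grid: np.ndarray                 # descending
    coefficient_path: pd.DataFrame          # features x grid
    cv_deviance_mean: np.ndarray
    cv_deviance_sd: np.ndarray
    lambda_opt: float
    selected_features: list[str]
    coefficients: pd.Series                 # nonzero support at lambda_opt
    intercept: float
    standardization: pd.DataFrame           # per-feature mean / sd
    seed: int | None = None
    dropped_constant: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "lambda_grid": self.lambda_grid.tolist(),
            "cv_deviance_mean": self.cv_deviance_mean.tolist(),
            "cv_deviance_sd": self.cv_deviance_sd.tolist(),
            "lambda_opt": self.lambda_opt,
            "selected_features": self.selected_features,
            "coefficients": self.coefficients.to_dict(),
            "intercept": self.intercept,
            "standardization": self.standardization.to_dict(),
            "seed": self.seed,
            "dropped_constant": self.dropped_constant,
        }


def standardize_features(X: pd.DataFrame, params: pd.DataFrame | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center/scale each column to mean 0, SD 1 (population SD).

    Returns the standardized matrix and the parameter table (mean, sd per
    feature) for application to held-out data.  Constant columns are dropped
    with a warning when fitting; with precomputed ``params``, columns are
    transformed as-is.
    """
    if params is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        constant = sd[sd == 0].index.tolist()
        if len(constant) == X.shape[1]:
            raise ValueError("all features are constant; nothing to standardize")
        if constant:
            logger.warning("dropping constant features: %s", constant)
            X = X.drop(columns=constant)
            mean = mean.drop(constant)
            sd = sd.drop(constant)
        params = pd.DataFrame({"mean": mean, "sd": sd})
    else:
        X = X[params.index]
    Z = (X - params["mean"]) / params["sd"]
    return Z, params


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every non-intercept coefficient is zero:
    ``max_j |x_j . (y - ybar)| / n`` for the intercept-only fit."""
    n = len(y)
    resid = y - y.mean()
    return float(np.max(np.abs(X.T @ resid)) / n)


def make_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int = 100,
                     ratio: float | None = None) -> np.ndarray:
    """Log-spaced descending grid from lambda_max.

    The smallest grid value is ``ratio * lambda_max``; by default 1e-4 when
    n > p and 1e-2 otherwise (the glmnet convention — with p >= n the
    near-unpenalized end of the path is ill-posed).
    """
    if ratio is None:
        n, p = X.shape
        ratio = 1e-4 if n > p else 1e-2
    lmax = lambda_max(X, y)
    return np.geomspace(lmax, lmax * ratio, n_lambdas)


def _solver(n: int, lam: float, warm: LogisticRegression | None
            ) -> LogisticRegression:
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (n * lam), solver="saga",
                             tol=1e-8, max_iter=5000, warm_start=True)
    if warm is not None:
        clf.coef_ = warm.coef_.copy()
        clf.intercept_ = warm.intercept_.copy()
    return clf


def _fit_path(X: np.ndarray, y: np.ndarray, lambda_grid: np.ndarray,
              truncate: bool) -> tuple[np.ndarray, np.ndarray, int]:
    """Warm-started path fit; returns (path, intercepts, n_valid).

    ``n_valid`` < len(grid) when the path was stopped early (glmnet-style):
    either the solver hit its iteration cap (quasi-separation at the
    near-unpenalized end) or the fit is essentially saturated (deviance
    ratio > 0.999).  With ``truncate`` False an early stop raises instead.
    """
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be binary 0/1")
    if np.any(np.diff(lambda_grid) > 0):
        raise ValueError("lambda grid must be descending")
    n, p = X.shape
    path = np.zeros((p, len(lambda_grid)))
    intercepts = np.zeros(len(lambda_grid))
    lmax = lambda_max(X, y)
    null_dev = _deviance(y, np.full(n, y.mean()))
    clf = None
    n_valid = len(lambda_grid)
    for idx, lam in enumerate(lambda_grid):
        if lam >= lmax:
            # full-shrinkage regime, known in closed form: all coefficients
            # exactly 0, intercept = log-odds of the class balance
            intercepts[idx] = np.log(y.mean() / (1 - y.mean()))
            continue
        clf = _solver(n, lam, clf)
        with warnings.catch_warnings():
            # the iteration cap is handled explicitly below
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X, y)
        if clf.n_iter_[0] >= clf.max_iter:
            if truncate:
                logger.info("lasso path stopped at lambda index %d "
                            "(iteration cap; quasi-separation)", idx)
                n_valid = idx
                break
            raise RuntimeError(f"LASSO path did not converge at lambda index {idx}")
        path[:, idx] = clf.coef_[0]
        intercepts[idx] = clf.intercept_[0]
        probs = 1.0 / (1.0 + np.exp(-(X @ path[:, idx] + intercepts[idx])))
        if truncate and null_dev > 0 and 1.0 - _deviance(y, probs) / null_dev > 0.999:
            n_valid = idx + 1
            break
    return path, intercepts, n_valid


def fit_lasso_path(X: np.ndarray, y: np.ndarray, lambda_grid: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient path (features x grid) and intercepts along a descending
    lambda grid, warm-started; non-convergence at any grid point is an
    error naming the lambda index."""
    path, intercepts, _ = _fit_path(X, y, lambda_grid, truncate=False)
    return path, intercepts


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance, -2 * mean log-likelihood."""
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def choose_lambda_cv(X: pd.DataFrame, y, folds: int = 10, seed: int = 0,
                     n_lambdas: int = 100) -> SelectionResult:
    """Pick lambda by stratified K-fold CV on mean held-out binomial deviance.

    Standardization is refit inside every training fold (no leakage); the
    returned support and coefficients come from a full-data refit at the
    chosen lambda.
    """
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be binary 0/1")
    if len(y) < folds:
        raise ValueError("need at least one subject per fold")
    if min(np.bincount(y)) < folds:
        raise ValueError("every fold must contain both classes; "
                         "smallest class is smaller than the fold count")

    Z_full, params = standardize_features(X)
    dropped = [c for c in X.columns if c not in params.index]
    grid = make_lambda_grid(Z_full.to_numpy(), y, n_lambdas=n_lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(grid)))
    n_valid = len(grid)
    for f, (tr, te) in enumerate(skf.split(Z_full, y)):
        Z_tr, p_tr = standardize_features(X.iloc[tr])
        Z_te, _ = standardize_features(X.iloc[te], params=p_tr)
        path, intercepts, nv = _fit_path(Z_tr.to_numpy(), y[tr], grid,
                                         truncate=True)
        n_valid = min(n_valid, nv)
        lin = Z_te.to_numpy() @ path + intercepts[None, :]
        probs = 1.0 / (1.0 + np.exp(-lin))
        for idx in range(len(grid)):
            dev[f, idx] = _deviance(y[te], probs[:, idx])

    full_path, full_intercepts, nv = _fit_path(Z_full.to_numpy(), y, grid,
                                               truncate=True)
    n_valid = max(1, min(n_valid, nv))
    mean_dev = dev.mean(axis=0)[:n_valid]
    sd_dev = dev.std(axis=0, ddof=1)[:n_valid]
    grid = grid[:n_valid]
    full_path = full_path[:, :n_valid]
    full_intercepts = full_intercepts[:n_valid]
    opt = int(np.argmin(mean_dev))
    coefs = pd.Series(full_path[:, opt], index=Z_full.columns)
    support = coefs[coefs != 0]
    return SelectionResult(
        lambda_grid=grid,
        coefficient_path=pd.DataFrame(full_path, index=Z_full.columns),
        cv_deviance_mean=mean_dev,
        cv_deviance_sd=sd_dev,
        lambda_opt=float(grid[opt]),
        selected_features=list(support.index),
        coefficients=support,
        intercept=float(full_intercepts[opt]),
        standardization=params,
        seed=seed,
        dropped_constant=dropped,
    )
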