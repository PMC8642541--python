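"""L1-penalized linear regression by cyclic coordinate descent.

Solves, for centered response y and standardized predictors X (M samples,
p predictors, no intercept),

    min_beta  (1/(2M)) * ||y - X beta||^2 + lambda * ||beta||_1

by cyclic coordinate descent with soft-thresholding on precomputed Gram
statistics (G = X'X / M, b = X'y / M), warm-starting along a descending
lambda path.  Centering the response and all predictors before the fit is
equivalent to carrying an unpenalized intercept, which the model
deliberately omits from the coefficient vector.

The analytic null threshold lambda_max = max_j |<x_j, y>| / M gives the
all-zero solution for every lambda >= lambda_max; the default path is
log-spaced from lambda_max down to lambda_max * 1e-4.

The inner kernel is numba-compiled: the repeated cross-validation loop of
the cluster-regulatory-network stage performs tens of thousands of
warm-started path fits on small designs, where per-call overhead dominates.
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit

__all__ = [
    "fit_sparse_model",
    "lambda_max",
    "lasso_path_gram",
    "standardize_design",
]

CONVERGENCE_TOL = 1e-7
MAX_SWEEPS = 100_000
# Held-out-error evaluation tolerates looser coefficients; with p close to n
# and tiny penalties the minimizer is non-unique and strict coefficient-change
# convergence stalls, so cross-validation path fits use these instead.
CV_TOL = 1e-4
CV_MAX_SWEEPS = 25


@njit(cache=False)
def _sweep(G, b, lam, beta, active_only):  # pragma: no cover - numba
    p = b.shape[0]
    max_delta = 0.0
    for j in range(p):
        gjj = G[j, j]
        if gjj <= 0.0:
            continue  # dropped (constant) predictor stays at zero
        old = beta[j]
        if active_only and old == 0.0:
            continue
        acc = 0.0
        for kk in range(p):
            bk = beta[kk]
            if bk != 0.0:
                acc += G[j, kk] * bk
        rho = b[j] - acc + gjj * old
        if rho > lam:
            new = (rho - lam) / gjj
        elif rho < -lam:
            new = (rho + lam) / gjj
        else:
            new = 0.0
        if new != old:
            beta[j] = new
            delta = abs(new - old)
            if delta > max_delta:
                max_delta = delta
    return max_delta


@njit(cache=False)
def _cd_path(G, b, lambdas, tol, max_sweeps):  # pragma: no cover - numba
    p = b.shape[0]
    n_lam = lambdas.shape[0]
    betas = np.zeros((n_lam, p))
    beta = np.zeros(p)
    for li in range(n_lam):
        lam = lambdas[li]
        sweeps = 0
        while sweeps < max_sweeps:
            # full sweep lets coordinates enter the active set
            full_delta = _sweep(G, b, lam, beta, False)
            sweeps += 1
            if full_delta < tol:
                break
            # then iterate on the active set only (glmnet-style)
            while sweeps < max_sweeps:
                if _sweep(G, b, lam, beta, True) < tol:
                    break
                sweeps += 1
        betas[li] = beta
    return betas


@njit(cache=False)
def _cv_sq_err(X, y, fold_labels, k, lambdas, tol, max_sweeps):  # pragma: no cover - numba
    """Held-out squared-error totals, one row per fold, one column per lambda.

    Each fold's training design is centered/standardized in place; constant
    training columns are dropped for that fold.  Predictions undo the
    centering via the implied intercept.
    """
    n, p = X.shape
    n_lam = lambdas.shape[0]
    err = np.zeros((k, n_lam))
    for f in range(k):
        n_te = 0
        for i in range(n):
            if fold_labels[i] == f:
                n_te += 1
        n_tr = n - n_te
        Xtr = np.empty((n_tr, p))
        ytr = np.empty(n_tr)
        Xte = np.empty((n_te, p))
        yte = np.empty(n_te)
        a = b = 0
        for i in range(n):
            if fold_labels[i] == f:
                Xte[b] = X[i]
                yte[b] = y[i]
                b += 1
            else:
                Xtr[a] = X[i]
                ytr[a] = y[i]
                a += 1
        xm = np.empty(p)
        xs = np.empty(p)
        for j in range(p):
            xm[j] = Xtr[:, j].mean()
            xs[j] = Xtr[:, j].std()
        ym = ytr.mean()
        Xs = np.zeros((n_tr, p))
        for j in range(p):
            if xs[j] > 0.0:
                Xs[:, j] = (Xtr[:, j] - xm[j]) / xs[j]
        yc = ytr - ym
        G = (Xs.T @ Xs) / n_tr
        bb = (Xs.T @ yc) / n_tr
        betas = _cd_path(G, bb, lambdas, tol, max_sweeps)
        for li in range(n_lam):
            for i in range(n_te):
                pred = ym
                for j in range(p):
                    if xs[j] > 0.0:
                        pred += betas[li, j] / xs[j] * (Xte[i, j] - xm[j])
                err[f, li] += (pred - yte[i]) ** 2
    return err


def standardize_design(X: np.ndarray, y: np.ndarray):
    """Center y, center and unit-sd-scale X columns (population sd).

    Constant columns get scale 0 and are excluded from the fit (their
    coefficient is fixed at zero).  Returns ``(Xs, yc, scale)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("design contains non-finite values")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    scale = Xc.std(axis=0)
    Xs = np.divide(Xc, scale, out=np.zeros_like(Xc), where=scale > 0)
    return Xs, yc, scale


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty for which the solution is identically zero."""
    Xs, yc, _ = standardize_design(X, y)
    m = X.shape[0]
    return float(np.abs(Xs.T @ yc).max() / m) if X.shape[1] else 0.0


def default_lambda_grid(lmax: float, n_points: int = 100, min_ratio: float = 1e-4) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to lambda_max * min_ratio."""
    if lmax <= 0:
        return np.array([0.0])
    return np.geomspace(lmax, lmax * min_ratio, n_points)


def lasso_path_gram(
    Xs: np.ndarray,
    yc: np.ndarray,
    lambdas: np.ndarray,
    tol: float = CONVERGENCE_TOL,
    max_sweeps: int = MAX_SWEEPS,
) -> np.ndarray:
    """Coefficient path on an already standardized design.

    ``lambdas`` must be descending for effective warm starts.  Returns an
    array of shape (len(lambdas), p) on the standardized scale.
    """
    m = Xs.shape[0]
    G = (Xs.T @ Xs) / m
    b = (Xs.T @ yc) / m
    return _cd_path(G, b, np.asarray(lambdas, dtype=float), tol, max_sweeps)


def fit_sparse_model(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = CONVERGENCE_TOL,
    max_sweeps: int = MAX_SWEEPS,
    warn_constant: bool = True,
) -> np.ndarray:
    """Fit the L1-penalized model at one penalty value.

    Predictors are standardized and the response centered internally;
    coefficients are returned on the original predictor scale.  Constant
    predictor columns are dropped (coefficient 0) with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Xs, yc, scale = standardize_design(X, y)
    if warn_constant and (scale == 0).any():
        warnings.warn(f"{int((scale == 0).sum())} constant predictor column(s) dropped")
    beta_std = lasso_path_gram(Xs, yc, np.array([lam]), tol=tol, max_sweeps=max_sweeps)[0]
    return np.divide(beta_std, scale, out=np.zeros_like(beta_std), where=scale > 0)
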