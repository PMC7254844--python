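"""Newton-Raphson logistic regression, vectorized across many single-SNP models.

A GWAS scan refits the same small logistic model once per variant, with only
one design column (the dosage) changing between fits.  Looping a generic GLM
implementation over tens of thousands of variants dominates runtime, so this
module solves all per-SNP Newton systems simultaneously with batched linear
algebra.  Estimates agree with a generic maximum-likelihood fit to full
numerical precision on non-degenerate data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeparationError",
    "fit_logistic",
    "fit_logistic_batch",
    "fit_logistic_per_snp",
]

# |log-odds| beyond this for a standardized predictor indicates (quasi-)separation
_BETA_CAP = 15.0


class SeparationError(RuntimeError):
    """Raised when a logistic fit diverges (perfect or quasi separation)."""


def _expit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    np.clip(x, -700, 700, out=out)
    return 1.0 / (1.0 + np.exp(-out))


def fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-12):
    """Maximum-likelihood logistic fit.

    Parameters
    ----------
    X : (n, p) design matrix including the intercept column.
    y : (n,) binary outcome.

    Returns
    -------
    beta : (p,) coefficient estimates.
    se : (p,) Wald standard errors from the observed information.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    beta = np.zeros(p)
    # intercept start at the marginal log-odds
    beta[np.where((X == 1).all(axis=0))[0][:1]] = np.log(y.mean() / (1 - y.mean()))
    for _ in range(max_iter):
        mu = _expit(X @ beta)
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:  # singular information
            raise SeparationError("singular information matrix") from exc
        beta = beta + step
        if not np.all(np.isfinite(beta)) or np.abs(beta).max() > _BETA_CAP * 10:
            raise SeparationError("logistic fit diverged (separation?)")
        if np.abs(step).max() < tol:
            break
    else:
        raise SeparationError("logistic fit did not converge")
    mu = _expit(X @ beta)
    w = mu * (1 - mu)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    return beta, np.sqrt(np.diag(cov))


def fit_logistic_batch(X: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-10):
    """Fit B independent logistic models with batched Newton iterations.

    X : (B, n, p) stack of design matrices; y : (B, n) outcomes.
    Returns (beta, se) of shapes (B, p); non-converged or separated fits are NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    B, n, p = X.shape
    beta = np.zeros((B, p))
    ok = np.ones(B, dtype=bool)
    for _ in range(max_iter):
        eta = np.einsum("bnp,bp->bn", X, beta)
        mu = _expit(eta)
        w = mu * (1 - mu)
        grad = np.einsum("bnp,bn->bp", X, y - mu)
        hess = np.einsum("bnp,bn,bnq->bpq", X, w, X)
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # retry per-batch, marking singular systems
            step = np.zeros_like(beta)
            for b in range(B):
                try:
                    step[b] = np.linalg.solve(hess[b], grad[b])
                except np.linalg.LinAlgError:
                    ok[b] = False
        beta = beta + step
        bad = ~np.isfinite(beta).all(axis=1) | (np.abs(beta).max(axis=1) > _BETA_CAP * 10)
        ok &= ~bad
        beta[~ok] = 0.0
        if np.abs(step[ok]).max(initial=0.0) < tol:
            break
    else:
        conv = np.abs(step).max(axis=1) < 1e-6
        ok &= conv
    eta = np.einsum("bnp,bp->bn", X, beta)
    w = _expit(eta) * (1 - _expit(eta))
    hess = np.einsum("bnp,bn,bnq->bpq", X, w, X)
    se = np.full((B, p), np.nan)
    cov = np.linalg.pinv(hess[ok])
    se[ok] = np.sqrt(np.einsum("bpp->bp", cov))
    beta = np.where(ok[:, None], beta, np.nan)
    return beta, se


def fit_logistic_per_snp(
    genotypes: np.ndarray,
    covariates: np.ndarray | None,
    y: np.ndarray,
    snp_ids=None,
    max_iter: int = 60,
    tol: float = 1e-10,
    chunk_size: int = 256,
) -> pd.DataFrame:
    """Per-SNP logistic scan: for each variant j fit y ~ intercept + g_j + covariates.

    Parameters
    ----------
    genotypes : (n, m) dosage matrix.
    covariates : (n, c) covariate matrix WITHOUT intercept, or None.
    y : (n,) binary outcome.

    Returns
    -------
    DataFrame with columns ``snp, beta, se, p, converged`` (one row per SNP,
    input order).  Monomorphic variants and fits showing separation or
    non-convergence have ``converged=False`` and NaN estimates.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    if y.min() == y.max():
        raise ValueError("degenerate outcome: single class")
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    c = C.shape[1]
    p = c + 1

    beta_out = np.full(m, np.nan)
    se_out = np.full(m, np.nan)
    conv_out = np.zeros(m, dtype=bool)

    poly = G.std(axis=0) > 0
    idx_all = np.where(poly)[0]

    b0 = np.zeros(p)
    b0[0] = np.log(y.mean() / (1 - y.mean()))

    for start in range(0, idx_all.size, chunk_size):
        idx = idx_all[start : start + chunk_size]
        Gc = G[:, idx]  # (n, k)
        k = idx.size
        beta = np.tile(b0, (k, 1))  # (k, p); layout [covs..., snp]
        ok = np.ones(k, dtype=bool)
        for _ in range(max_iter):
            eta = C @ beta[:, :c].T + Gc * beta[:, c]  # (n, k)
            mu = _expit(eta)
            w = mu * (1 - mu)
            resid = y[:, None] - mu
            grad = np.empty((k, p))
            grad[:, :c] = (C.T @ resid).T
            grad[:, c] = np.einsum("nk,nk->k", Gc, resid)
            hess = np.empty((k, p, p))
            hess[:, :c, :c] = np.einsum("nc,nk,nd->kcd", C, w, C)
            hg = np.einsum("nc,nk,nk->kc", C, w, Gc)
            hess[:, :c, c] = hg
            hess[:, c, :c] = hg
            hess[:, c, c] = np.einsum("nk,nk,nk->k", Gc, w, Gc)
            try:
                step = np.linalg.solve(hess, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = np.zeros_like(beta)
                for j in range(k):
                    try:
                        step[j] = np.linalg.solve(hess[j], grad[j])
                    except np.linalg.LinAlgError:
                        ok[j] = False
            beta = beta + step
            bad = ~np.isfinite(beta).all(axis=1) | (np.abs(beta[:, c]) > _BETA_CAP)
            ok &= ~bad
            beta[~ok] = 0.0
            if np.abs(step[ok]).max(initial=0.0) < tol:
                break
        else:
            ok &= np.abs(step).max(axis=1) < 1e-6
        eta = C @ beta[:, :c].T + Gc * beta[:, c]
        mu = _expit(eta)
        w = mu * (1 - mu)
        hess = np.empty((k, p, p))
        hess[:, :c, :c] = np.einsum("nc,nk,nd->kcd", C, w, C)
        hg = np.einsum("nc,nk,nk->kc", C, w, Gc)
        hess[:, :c, c] = hg
        hess[:, c, :c] = hg
        hess[:, c, c] = np.einsum("nk,nk,nk->k", Gc, w, Gc)
        se = np.full(k, np.nan)
        if ok.any():
            cov = np.linalg.pinv(hess[ok])
            se[ok] = np.sqrt(cov[:, p - 1, p - 1])
        beta_out[idx] = np.where(ok, beta[:, c], np.nan)
        se_out[idx] = se
        conv_out[idx] = ok

    with np.errstate(invalid="ignore", divide="ignore"):
        pvals = 2 * stats.norm.sf(np.abs(beta_out / se_out))
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    return pd.DataFrame(
        {
            "snp": list(snp_ids),
            "beta": beta_out,
            "se": se_out,
            "p": pvals,
            "converged": conv_out,
        }
    )
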