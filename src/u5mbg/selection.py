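"""Best-subset covariate selection for a Gaussian GLM under BIC.

Candidate covariates are regressed against the cluster proportions with an
ordinary Gaussian linear model (identity link) and every subset of the
candidates is scored by BIC = -2 loglik + k ln(n); the subset with the
smallest BIC wins.  Exhaustive enumeration (2^p fits) is exact and tractable
for the covariate menus this pipeline sees (p <= 20); land-cover enters as a
single numeric class-code column rather than dummies, so it carries one
coefficient like any other candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

MAX_CANDIDATES = 20


@dataclass
class SubsetResult:
    subset: tuple[str, ...]
    coefficients: dict[str, float]      # includes "intercept"
    loglik: float
    bic: float
    rank: int = 0


def fit_gaussian_glm(X: pd.DataFrame | np.ndarray, y: np.ndarray
                     ) -> tuple[dict[str, float], float]:
    """OLS fit with implicit intercept; returns coefficients and the Gaussian
    log-likelihood at the MLE variance sigma2_hat = RSS / n."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.atleast_2d(np.asarray(X, dtype=float))
        if Xv.shape[0] == 1 and Xv.shape[1] != 1 and len(np.atleast_1d(y)) != 1:
            Xv = Xv.T
        names = [f"x{i}" for i in range(Xv.shape[1])]
    y = np.asarray(y, dtype=float)
    n = len(y)
    if Xv.size == 0:
        Xv = np.empty((n, 0))
    p = Xv.shape[1]
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 (n={n}, p={p})")
    A = np.column_stack([np.ones(n), Xv])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify offending columns via incremental rank
        bad = []
        kept = A[:, :1]
        for j, nm in enumerate(names):
            cand = np.column_stack([kept, A[:, j + 1]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(nm)
            else:
                kept = cand
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    s2 = float(resid @ resid) / n
    if s2 <= 0:
        s2 = np.finfo(float).tiny
    loglik = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    return dict(zip(["intercept"] + names, coef.tolist())), float(loglik)


def bic(loglik: float, k: int, n: int) -> float:
    """BIC = -2 loglik + k ln(n); k counts intercept, slopes and variance."""
    if n <= 0:
        raise ValueError("n must be positive")
    return -2.0 * loglik + k * np.log(n)


def best_subset_bic(X: pd.DataFrame, y: np.ndarray) -> list[SubsetResult]:
    """Score every covariate subset by BIC; return the full ranking.

    Ties break by fewer covariates, then lexicographic subset names.
    """
    names = list(X.columns)
    if len(names) != len(set(names)):
        raise ValueError("candidate column names must be unique")
    if X.isna().any().any():
        raise ValueError("candidate matrix contains missing values")
    p = len(names)
    if p > MAX_CANDIDATES:
        raise ValueError(
            f"{p} candidates exceed the exhaustive-search limit of {MAX_CANDIDATES}; "
            "pre-screen the candidate list first")
    y = np.asarray(y, dtype=float)
    n = len(y)
    results = []
    for size in range(p + 1):
        for subset in combinations(names, size):
            coefs, ll = fit_gaussian_glm(X[list(subset)], y)
            results.append(SubsetResult(
                subset=subset, coefficients=coefs, loglik=ll,
                bic=bic(ll, k=size + 2, n=n)))
    results.sort(key=lambda r: (r.bic, len(r.subset), r.subset))
    for i, r in enumerate(results):
        r.rank = i + 1
    return results


def ranking_table(results: list[SubsetResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"rank": r.rank, "subset": "+".join(r.subset) or "(intercept)",
         "n_covariates": len(r.subset), "loglik": r.loglik, "bic": r.bic}
        for r in results])
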