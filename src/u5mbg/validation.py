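"""Model validation: holdout metrics, leave-one-out CPO, residual semivariogram.

Two complementary checks on a fitted space-time GP:

* external — refit on ~90% of the clusters, predict the held-out 10% and
  report MPE / MAE / RMSE and Pearson's r between observed and predicted
  proportions;
* internal — the conditional predictive ordinate (CPO), the predictive
  density of each observation given all the others, computed in closed form
  from the fitted covariance; and the semivariogram of standardized
  residuals with Monte-Carlo permutation envelopes, which should be flat
  (inside the envelopes) if the model has soaked up the spatial structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, pearsonr

from .stgp import FitResult, build_cov_matrix, chol_with_jitter


@dataclass
class HoldoutMetrics:
    mpe: float       # mean(predicted - observed): sign convention documented
    mae: float
    rmse: float
    pearson_r: float
    r_defined: bool = True


@dataclass
class Semivariogram:
    bin_dist: np.ndarray      # mean pair distance per bin
    gamma: np.ndarray
    lower: np.ndarray         # permutation envelope, pointwise min
    upper: np.ndarray         # pointwise max
    counts: np.ndarray
    empty_bins: list[int]


def holdout_split(clusters: pd.DataFrame, fraction: float = 0.10, seed: int = 0,
                  stratify_urban: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed-reproducible random train/test split; test size = round(n * fraction)."""
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    n = len(clusters)
    if stratify_urban:
        test_idx = []
        for _, grp in clusters.groupby("urban"):
            k = int(round(len(grp) * fraction))
            test_idx.extend(rng.choice(grp.index.to_numpy(), size=k, replace=False))
        test_idx = np.array(sorted(test_idx))
    else:
        k = int(round(n * fraction))
        test_idx = np.sort(rng.choice(clusters.index.to_numpy(), size=k, replace=False))
    test = clusters.loc[test_idx]
    train = clusters.drop(index=test_idx)
    return train, test


def holdout_metrics(observed: np.ndarray, predicted: np.ndarray) -> HoldoutMetrics:
    """MPE, MAE, RMSE and Pearson correlation between observed and predicted."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    err = predicted - observed
    mpe = float(err.mean())
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err**2).mean()))
    if np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        return HoldoutMetrics(mpe, mae, rmse, np.nan, r_defined=False)
    if np.allclose(observed, predicted):
        return HoldoutMetrics(mpe, mae, rmse, 1.0)
    r = float(pearsonr(observed, predicted).statistic)
    return HoldoutMetrics(mpe, mae, rmse, r)


def loo_cpo(fit: FitResult) -> np.ndarray:
    """Closed-form leave-one-out conditional predictive ordinates.

    With Q = K^-1 and r = Q (y - X beta), the LOO predictive for observation
    i (covariance parameters and beta held at their estimates) is Gaussian
    with mean y_i - r_i / Q_ii and variance 1 / Q_ii; CPO_i is its density
    at y_i.  This equals the naive delete-one conditional density exactly.
    """
    m = fit.model
    beta = np.array([m.beta["intercept"]] + [m.beta[c] for c in m.covariate_names])
    K = build_cov_matrix(fit.lonlat, fit.times, m)
    cf = chol_with_jitter(K)
    n = len(fit.y)
    Q = cho_solve(cf, np.eye(n))
    q = np.diag(Q)
    if np.any(q <= 0):
        raise np.linalg.LinAlgError("singular leave-one-out sub-matrix")
    r = Q @ (fit.y - fit.X @ beta)
    mu = fit.y - r / q
    var = 1.0 / q
    return norm.pdf(fit.y, loc=mu, scale=np.sqrt(var))


def loo_residuals(fit: FitResult, standardize: bool = True) -> np.ndarray:
    """(y_i - mu_loo,i), optionally divided by the LOO predictive sd."""
    m = fit.model
    beta = np.array([m.beta["intercept"]] + [m.beta[c] for c in m.covariate_names])
    K = build_cov_matrix(fit.lonlat, fit.times, m)
    cf = chol_with_jitter(K)
    Q = cho_solve(cf, np.eye(len(fit.y)))
    q = np.diag(Q)
    r = Q @ (fit.y - fit.X @ beta)
    resid = r / q
    return resid * np.sqrt(q) if standardize else resid


def residual_semivariogram(residuals: np.ndarray, lonlat: np.ndarray,
                           n_bins: int = 12, max_dist: float | None = None,
                           n_perm: int = 99, seed: int = 0) -> Semivariogram:
    """Empirical semivariogram with permutation envelopes.

    gamma(b) = mean over pairs in distance bin b of (r_i - r_j)^2 / 2.
    Envelopes are the pointwise min/max of gamma over ``n_perm`` random
    permutations of the residuals across the fixed locations — the spread
    expected by chance with no spatial autocorrelation.
    """
    residuals = np.asarray(residuals, dtype=float)
    lonlat = np.asarray(lonlat, dtype=float)
    n = len(residuals)
    if n < 2:
        raise ValueError("need at least two residuals")
    d = pdist(lonlat)
    if max_dist is None:
        max_dist = 0.5 * d.max()
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    in_range = d <= max_dist
    iu, ju = np.triu_indices(n, k=1)

    def gamma_of(r):
        sq = 0.5 * (r[iu] - r[ju]) ** 2
        g = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = in_range & (which == b)
            if sel.any():
                g[b] = sq[sel].mean()
        return g

    gamma = gamma_of(residuals)
    counts = np.array([(in_range & (which == b)).sum() for b in range(n_bins)])
    bin_dist = np.array([d[in_range & (which == b)].mean() if counts[b] else np.nan
                         for b in range(n_bins)])
    rng = np.random.default_rng(seed)
    perm_gammas = np.empty((n_perm, n_bins))
    for k in range(n_perm):
        perm_gammas[k] = gamma_of(rng.permutation(residuals))
    lower = np.nanmin(perm_gammas, axis=0)
    upper = np.nanmax(perm_gammas, axis=0)
    empty = [int(b) for b in range(n_bins) if counts[b] == 0]
    return Semivariogram(bin_dist=bin_dist, gamma=gamma, lower=lower,
                         upper=upper, counts=counts, empty_bins=empty)


def semivariogram_table(sv: Semivariogram) -> pd.DataFrame:
    return pd.DataFrame({
        "bin": np.arange(len(sv.gamma)), "distance": sv.bin_dist,
        "gamma": sv.gamma, "lo": sv.lower, "hi": sv.upper, "n_pairs": sv.counts,
    })
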