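"""Separable space-time Gaussian process engine.

The model for the cluster-level under-five proportion y(s, t) is

    y(s, t) = x(s)' beta + f(s, t) + e,      e ~ N(0, nugget)

with f a zero-mean Gaussian process whose covariance is separable:
Matern(nu=1) in space times a first-order autoregression across survey
waves,

    Cov(f(s,t), f(s',t')) = sigma2 * (kappa h) K_1(kappa h) * rho^|t - t'|,

h the Euclidean distance in degrees between s and s', K_1 the modified
Bessel function of the second kind.  The nominal spatial range (distance at
which correlation drops to ~0.1) is sqrt(8 nu) / kappa.

Inference is maximum marginal likelihood: the regression coefficients and
the total variance are profiled out in closed form, a bounded quasi-Newton
search runs over the remaining (variance share, log kappa, atanh rho) from
several dispersed starts, and parameter uncertainty comes from the inverse
Hessian of the full log-likelihood at the optimum (Laplace/Gaussian
approximation), summarized in mean / sd / 5% / 50% / 95% columns.
Prediction at new cells is universal kriging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import cdist
from scipy.stats import norm

from .grids import CovariateStack, RasterGrid

logger = logging.getLogger(__name__)

#: Documented km <-> degree constant; latitude dependence is ignored
#: (the target geography is near-equatorial).
KM_PER_DEGREE = 111.32


# ---------------------------------------------------------------------------
# model container and covariance primitives


@dataclass
class STGPModel:
    """Fixed effects + covariance parameters of the space-time GP.

    ``beta`` maps covariate names to coefficients and must contain an
    ``"intercept"`` entry.  ``sigma2`` is the Matern marginal variance
    (proportion^2 units), ``kappa`` the spatial scaling (1/degrees),
    ``nu`` the smoothness (fixed at 1), ``nugget`` the measurement-error
    variance and ``rho`` the AR(1) coefficient across survey waves.
    """

    beta: dict[str, float]
    sigma2: float
    kappa: float
    nugget: float
    rho: float
    nu: float = 1.0

    def __post_init__(self) -> None:
        if "intercept" not in self.beta:
            raise ValueError("beta must include an 'intercept' entry")
        if self.sigma2 < 0 or self.nugget < 0:
            raise ValueError("sigma2 and nugget must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.nu != 1.0:
            raise ValueError("only nu = 1 is supported")

    @property
    def covariate_names(self) -> list[str]:
        return [k for k in self.beta if k != "intercept"]

    @property
    def range_deg(self) -> float:
        return range_from_kappa(self.kappa, self.nu)

    def to_dict(self) -> dict:
        return {
            "beta": dict(self.beta), "sigma2": self.sigma2, "kappa": self.kappa,
            "nugget": self.nugget, "rho": self.rho, "nu": self.nu,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "STGPModel":
        return cls(beta=dict(d["beta"]), sigma2=float(d["sigma2"]),
                   kappa=float(d["kappa"]), nugget=float(d["nugget"]),
                   rho=float(d["rho"]), nu=float(d.get("nu", 1.0)))


def matern_cov(h, sigma2: float, kappa: float, nu: float = 1.0):
    """Matern covariance sigma2 * 2^(1-nu)/Gamma(nu) * (kappa h)^nu K_nu(kappa h).

    Vectorized in ``h``; returns exactly ``sigma2`` at h = 0.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be non-negative")
    u = kappa * h
    with np.errstate(invalid="ignore"):
        if nu == 1.0:
            c = u * special.k1(u)
        else:
            c = (2.0 ** (1.0 - nu) / special.gamma(nu)) * u**nu * special.kv(nu, u)
    c = np.where(u == 0.0, 1.0, c)
    out = sigma2 * c
    return float(out) if out.ndim == 0 else out


def range_from_kappa(kappa: float, nu: float = 1.0) -> float:
    """Nominal range sqrt(8 nu) / kappa, in degrees (correlation ~= 0.1)."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return np.sqrt(8.0 * nu) / kappa


def _ar1_factor(rho: float, tlag) -> np.ndarray:
    """rho^|tlag| for integer wave lags; 0^0 = 1 so rho=0 keeps lag-0 terms.

    Lags are a handful of small integers, so the powers are precomputed and
    gathered by index rather than exponentiated elementwise.
    """
    tl = np.abs(np.rint(np.asarray(tlag, dtype=float))).astype(np.intp)
    if rho == 0.0:
        return np.where(tl == 0, 1.0, 0.0)
    max_lag = int(tl.max()) if tl.size else 0
    table = float(rho) ** np.arange(max_lag + 1)
    return table[tl]


def st_cov(h, tlag, model: STGPModel):
    """Separable space-time covariance: matern_cov(h) * rho^|tlag|."""
    out = matern_cov(h, model.sigma2, model.kappa, model.nu) * _ar1_factor(model.rho, tlag)
    return float(out) if np.ndim(out) == 0 else out


def build_cov_matrix(lonlat: np.ndarray, times: np.ndarray, model: STGPModel,
                     include_nugget: bool = True) -> np.ndarray:
    """Dense covariance matrix over observation (location, wave) pairs.

    K[i, j] = st_cov(d_ij, t_i - t_j) + nugget * 1{i = j}, with Euclidean
    distance on lon/lat degrees.
    """
    lonlat = np.asarray(lonlat, dtype=float)
    times = np.asarray(times)
    d = cdist(lonlat, lonlat)
    tl = times[:, None] - times[None, :]
    K = matern_cov(d, model.sigma2, model.kappa, model.nu) * _ar1_factor(model.rho, tl)
    if include_nugget:
        K = K + model.nugget * np.eye(len(K))
    return K


def chol_with_jitter(K: np.ndarray, scale: float | None = None):
    """Cholesky with escalating diagonal jitter.

    Starts at 1e-10 * scale (scale defaults to the mean diagonal), escalates
    tenfold up to 1e-6 * scale, then raises with condition diagnostics.
    """
    if scale is None:
        scale = max(float(np.mean(np.diag(K))), np.finfo(float).tiny)
    try:
        return cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        pass
    jitter = 1e-10 * scale
    while jitter <= 1e-6 * scale:
        try:
            return cho_factor(K + jitter * np.eye(len(K)), lower=True)
        except np.linalg.LinAlgError:
            jitter *= 10
    eigs = np.linalg.eigvalsh(K)
    raise np.linalg.LinAlgError(
        f"covariance matrix not positive definite after jitter up to {1e-6 * scale:g}; "
        f"eigenvalue range [{eigs.min():.3e}, {eigs.max():.3e}]")


def log_marginal_likelihood(model: STGPModel, X: np.ndarray, y: np.ndarray,
                            lonlat: np.ndarray, times: np.ndarray) -> float:
    """log N(y; X beta, K) via Cholesky (no explicit inverse)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if X.shape[0] != n or len(lonlat) != n or len(times) != n:
        raise ValueError("X, y, lonlat and times must have matching lengths")
    beta = np.array([model.beta["intercept"]]
                    + [model.beta[c] for c in model.covariate_names])
    K = build_cov_matrix(lonlat, times, model)
    cf = chol_with_jitter(K)
    r = y - X @ beta
    alpha = cho_solve(cf, r)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ alpha))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitConfig:
    """Options for maximum-marginal-likelihood fitting and prediction."""

    n_starts: int = 4
    max_iter: int = 200
    seed: int = 0
    interval: float = 0.95            # central credible interval for surfaces
    summary_quantiles: tuple = (0.05, 0.50, 0.95)   # Table-style columns
    include_beta_uncertainty: bool = True
    buffer_radius: float = 0.0        # degrees; covariate extraction buffer
    tile_size: int = 4096             # cells per prediction tile


@dataclass
class FitResult:
    model: STGPModel
    summaries: pd.DataFrame           # rows = parameters; mean/sd/q05/q50/q95
    loglik: float
    dic: float
    p_d: float
    marginal_lik_note: str
    convergence: dict
    # training data retained for prediction / validation
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    lonlat: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)
    covariates: list[str] = field(default_factory=list)
    # importance-weighted covariance-parameter ensemble (weight, model with
    # its own GLS beta); used for hyperparameter-integrated prediction
    hyper: list[tuple[float, STGPModel]] = field(default_factory=list, repr=False)


@dataclass
class PredictionSurface:
    grid: RasterGrid
    time: int
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    interval: float
    n_clipped: int = 0

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def _design(clusters: pd.DataFrame, stack: CovariateStack, covariates: list[str],
            buffer_radius: float = 0.0) -> np.ndarray:
    Z = stack.values_at(clusters["lon"].to_numpy(), clusters["lat"].to_numpy(),
                        covariates, buffer_radius=buffer_radius)
    return np.column_stack([np.ones(len(clusters)), Z])


def _neg_concentrated_ll(theta, D, TL, X, y):
    """-loglik with beta and the total variance profiled out.

    theta = (logit variance-share w, log kappa, atanh rho); the covariance is
    s2 * [w * R_matern(kappa) * rho^|lag| + (1 - w) * I] and s2hat, betahat
    are closed-form GLS quantities.
    """
    w = special.expit(theta[0])
    kappa = np.exp(theta[1])
    rho = np.tanh(theta[2])
    n = len(y)
    R = matern_cov(D, 1.0, kappa) * _ar1_factor(rho, TL)
    C = w * R + (1.0 - w) * np.eye(n)
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        return 1e10
    L = cf[0]
    A = solve_triangular(L, X, lower=True)
    b = solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    r = b - A @ beta
    s2 = float(r @ r) / n
    if s2 <= 0 or not np.isfinite(s2):
        return 1e10
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def _params_from_theta(theta, D, TL, X, y):
    w = special.expit(theta[0])
    kappa = np.exp(theta[1])
    rho = np.tanh(theta[2])
    n = len(y)
    R = matern_cov(D, 1.0, kappa) * _ar1_factor(rho, TL)
    C = w * R + (1.0 - w) * np.eye(n)
    cf = cho_factor(C, lower=True)
    A = solve_triangular(cf[0], X, lower=True)
    b = solve_triangular(cf[0], y, lower=True)
    beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    s2 = float((b - A @ beta) @ (b - A @ beta)) / n
    return beta, s2 * w, kappa, rho, s2 * (1.0 - w)


def fit_arrays(y: np.ndarray, X: np.ndarray, lonlat: np.ndarray, times: np.ndarray,
               covariates: list[str], config: FitConfig | None = None) -> FitResult:
    """Fit the space-time GP to response/design arrays (core entry point).

    ``X`` must carry a leading intercept column; ``covariates`` names the
    remaining columns.
    """
    config = config or FitConfig()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    lonlat = np.asarray(lonlat, dtype=float)
    times = np.asarray(times, dtype=float)
    n = len(y)
    if n < 50:
        raise ValueError("need at least 50 clusters to fit")
    D = cdist(lonlat, lonlat)
    TL = np.abs(times[:, None] - times[None, :])
    extent = max(D.max(), 1e-6)

    # dispersed multi-starts: variance share x spatial range x rho
    rng = np.random.default_rng(config.seed)
    range_guesses = np.array([0.10, 0.30, 0.60, 0.05]) * extent
    w_guesses = [0.5, 0.2, 0.8, 0.5]
    rho_guesses = [0.0, 0.3, -0.3, 0.0]
    starts = []
    for i in range(config.n_starts):
        j = i % 4
        starts.append([
            special.logit(w_guesses[j]),
            np.log(np.sqrt(8.0) / range_guesses[j]),
            np.arctanh(rho_guesses[j]),
        ])
    # identifiability floor: spatial structure below the data spacing is
    # indistinguishable from the nugget, so the nominal range is bounded
    # below by twice the median nearest-neighbour distance
    Dnn = D + np.diag(np.full(n, np.inf))
    nn_median = float(np.median(Dnn.min(axis=1)))
    range_floor = max(2.0 * nn_median, 0.005 * extent)
    lo_k = np.log(np.sqrt(8.0) / (5.0 * extent))     # range up to 5x the extent
    hi_k = np.log(np.sqrt(8.0) / range_floor)
    bounds = [(-16.0, 16.0), (lo_k, hi_k), (-5.0, 5.0)]

    starts = [[s[0], float(np.clip(s[1], lo_k, hi_k)), s[2]] for s in starts]
    best = None
    total_nit = 0
    for x0 in starts:
        res = optimize.minimize(
            _neg_concentrated_ll, x0, args=(D, TL, X, y), method="L-BFGS-B",
            bounds=bounds, options={"maxiter": config.max_iter})
        total_nit += res.nit
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("optimizer failed from every start")
    converged = bool(best.success) or best.fun < 1e9
    if not converged:
        logger.warning("fit did not formally converge: %s", best.message)

    beta, sigma2, kappa, rho, nugget = _params_from_theta(best.x, D, TL, X, y)
    names = ["intercept"] + list(covariates)
    model = STGPModel(beta=dict(zip(names, beta.tolist())),
                      sigma2=max(sigma2, 0.0), kappa=kappa,
                      nugget=max(nugget, 1e-12), rho=rho)
    loglik = -float(best.fun)

    summaries, hyper = _laplace_summaries(model, X, y, lonlat, times, names,
                                          config.summary_quantiles,
                                          seed=config.seed)
    dic, p_d = _dic(model, X, y, lonlat, times, loglik)
    return FitResult(
        model=model, summaries=summaries, loglik=loglik, dic=dic, p_d=p_d, hyper=hyper,
        marginal_lik_note=("log marginal likelihood of the Gaussian process over the "
                           "latent field at the hyperparameter optimum; no "
                           "hyperparameter-level integration"),
        convergence={"status": "converged" if converged else "max-iter",
                     "iterations": int(total_nit), "n_starts": config.n_starts},
        X=X, y=y, lonlat=lonlat, times=times, covariates=list(covariates))


def fit(clusters: pd.DataFrame, stack: CovariateStack, covariates: list[str],
        config: FitConfig | None = None) -> FitResult:
    """Fit using covariates extracted from the stack at cluster locations."""
    config = config or FitConfig()
    missing = [c for c in covariates if c not in stack.layers]
    if missing:
        raise ValueError(f"covariates not in stack: {missing}")
    X = _design(clusters, stack, covariates, config.buffer_radius)
    lonlat = clusters[["lon", "lat"]].to_numpy(dtype=float)
    return fit_arrays(clusters["p_under5"].to_numpy(dtype=float), X, lonlat,
                      clusters["time"].to_numpy(dtype=float), covariates, config)


def _full_negll(phi, X, y, lonlat, times, names):
    """Unconcentrated -loglik over (beta, log sigma2, log kappa, atanh rho, log nugget)."""
    p = X.shape[1]
    beta = dict(zip(names, phi[:p]))
    try:
        model = STGPModel(beta=beta, sigma2=np.exp(phi[p]), kappa=np.exp(phi[p + 1]),
                          rho=np.tanh(phi[p + 2]), nugget=np.exp(phi[p + 3]))
        return -log_marginal_likelihood(model, X, y, lonlat, times)
    except (np.linalg.LinAlgError, ValueError, OverflowError):
        return 1e10


def _laplace_summaries(model, X, y, lonlat, times, names, quantiles,
                       seed: int = 0, n_hyper_draws: int = 60) -> pd.DataFrame:
    """Gaussian (inverse-Hessian) posterior summaries on interpretable scales.

    The Hessian is taken on (beta, log sigma2, log kappa, atanh rho,
    log nugget); quantiles for the transformed parameters are mapped back
    through the monotone transform, so e.g. variance quantiles stay positive.

    Fixed-effect uncertainty additionally integrates over covariance-parameter
    uncertainty: the GLS mean and variance of beta are averaged over
    ``n_hyper_draws`` draws from the Laplace Gaussian on the transformed
    covariance parameters (law of total variance).  Plug-in profiling alone
    understates e.g. the intercept sd when range and variance are weakly
    identified; this mirrors the hyperparameter integration a fully Bayesian
    fit performs.
    """
    p = X.shape[1]
    phi_hat = np.concatenate([
        [model.beta[nm] for nm in names],
        [np.log(max(model.sigma2, 1e-300)), np.log(model.kappa),
         np.arctanh(np.clip(model.rho, -1 + 1e-12, 1 - 1e-12)),
         np.log(model.nugget)],
    ])
    f = lambda phi: _full_negll(phi, X, y, lonlat, times, names)
    H = _numerical_hessian(f, phi_hat)
    try:
        cov = np.linalg.inv(H)
        sd_phi = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        degenerate = not np.all(np.isfinite(sd_phi))
    except np.linalg.LinAlgError:
        sd_phi = np.full(len(phi_hat), np.nan)
        degenerate = True
    if degenerate:
        cov = np.linalg.pinv(H)
        sd_phi = np.sqrt(np.clip(np.diag(cov), 0, np.inf))

    sd_beta, ensemble = _hyper_ensemble(
        model, X, y, lonlat, times, phi_hat[p:], cov[p:, p:], seed,
        n_hyper_draws, names)
    if sd_beta is None:
        sd_beta = sd_phi[:p]
    else:
        sd_beta = np.maximum(sd_beta, sd_phi[:p])

    z = norm.ppf(quantiles)
    rows = {}
    transforms = [None] * p + [np.exp, np.exp, np.tanh, np.exp]
    natural = list(phi_hat[:p]) + [model.sigma2, model.kappa, model.rho, model.nugget]
    labels = names + ["sigma2", "kappa", "rho", "nugget"]
    for i, (label, tf) in enumerate(zip(labels, transforms)):
        sd_i = sd_beta[i] if i < p else sd_phi[i]
        qs_phi = phi_hat[i] + z * sd_i
        if tf is None:
            qs, sd_nat = qs_phi, sd_i
        else:
            qs = tf(qs_phi)
            # delta method for the natural-scale sd
            eps = 1e-6 * max(abs(phi_hat[i]), 1.0)
            deriv = (tf(phi_hat[i] + eps) - tf(phi_hat[i] - eps)) / (2 * eps)
            sd_nat = abs(deriv) * sd_phi[i]
        rows[label] = {"mean": natural[i], "sd": sd_nat,
                       **{f"q{int(q * 100):02d}": v for q, v in zip(quantiles, qs)}}
    df = pd.DataFrame(rows).T
    # derived display row: nominal range in degrees
    krow = df.loc["kappa"]
    qcols = [c for c in df.columns if c.startswith("q")]
    rng_row = {"mean": range_from_kappa(model.kappa),
               "sd": np.sqrt(8.0) / model.kappa**2 * df.loc["kappa", "sd"]}
    for c in qcols:  # range is decreasing in kappa: quantiles flip
        rng_row[c] = np.nan
    flipped = [np.sqrt(8.0) / krow[c] if krow[c] > 0 else np.nan for c in qcols[::-1]]
    for c, v in zip(qcols, flipped):
        rng_row[c] = v
    df.loc["range_deg"] = rng_row
    return df, ensemble


def _hyper_ensemble(model, X, y, lonlat, times, theta_hat, theta_cov, seed,
                    n_draws, names):
    """Importance-weighted covariance-parameter ensemble and beta sd.

    theta = (log sigma2, log kappa, atanh rho, log nugget) sampled from an
    over-dispersed Laplace Gaussian and re-weighted by the restricted
    (beta-integrated) likelihood; per draw the GLS mean and covariance of
    beta are exact, and the total beta sd follows from the law of total
    variance.  Returns (sd_beta, ensemble) where the ensemble pairs weights
    with models carrying their own GLS beta; (None, []) if the theta
    covariance is unusable.
    """
    if not np.all(np.isfinite(theta_cov)):
        return None, []
    try:
        Lt = np.linalg.cholesky(theta_cov + 1e-12 * np.eye(4))
    except np.linalg.LinAlgError:
        return None, []
    rng = np.random.default_rng(seed)
    n, p = X.shape
    means, covs, logw, models = [], [], [], []
    # draws come from an over-dispersed Laplace proposal and are re-weighted by
    # the restricted (beta-integrated) likelihood, so skewed likelihoods - the
    # usual shape for variance parameters - are integrated faithfully
    infl = 1.5
    for _ in range(n_draws):
        z = rng.standard_normal(4)
        th = theta_hat + infl * (Lt @ z)
        try:
            with np.errstate(over="raise"):
                mdl = replace(model, sigma2=float(np.exp(th[0])),
                              kappa=float(np.exp(th[1])),
                              rho=float(np.clip(np.tanh(th[2]), -1 + 1e-9, 1 - 1e-9)),
                              nugget=float(np.exp(th[3])))
            K = build_cov_matrix(lonlat, times, mdl)
            cf = chol_with_jitter(K)
            KinvX = cho_solve(cf, X)
            XtKinvX = X.T @ KinvX
            M = np.linalg.inv(XtKinvX)
            bhat = M @ (KinvX.T @ y)
            r = y - X @ bhat
            quad = float(r @ cho_solve(cf, r))
            logdetK = 2.0 * np.sum(np.log(np.diag(cf[0])))
            sign, logdetX = np.linalg.slogdet(XtKinvX)
            if sign <= 0:
                continue
            ll_restricted = -0.5 * (quad + logdetK + logdetX)
            logq = -0.5 * float(z @ z)   # proposal density up to constants
            means.append(bhat)
            covs.append(M)
            logw.append(ll_restricted - logq)
            models.append(replace(mdl, beta=dict(zip(names, bhat.tolist()))))
        except (np.linalg.LinAlgError, ValueError, OverflowError, FloatingPointError):
            continue
    if len(means) < max(3, n_draws // 2):
        return None, []
    logw = np.array(logw)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    means = np.array(means)
    mbar = w @ means
    between = (w[:, None, None] * np.einsum("si,sj->sij", means - mbar,
                                            means - mbar)).sum(axis=0)
    within = (w[:, None, None] * np.array(covs)).sum(axis=0)
    total = within + between
    sd_beta = np.sqrt(np.clip(np.diag(total), 0, np.inf))
    # keep the highest-weight draws covering 98% of the mass (at most 25)
    order = np.argsort(w)[::-1]
    keep, mass = [], 0.0
    for i in order:
        keep.append(i)
        mass += w[i]
        if mass >= 0.98 or len(keep) == 25:
            break
    wk = w[keep] / w[keep].sum()
    ensemble = [(float(wi), models[i]) for wi, i in zip(wk, keep)]
    return sd_beta, ensemble


def _numerical_hessian(f, x0, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x0)
    h = rel_step * np.maximum(np.abs(x0), 1.0)
    H = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x0.copy(); xp[i] += h[i]
                xm = x0.copy(); xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp = x0.copy(); xpp[[i, j]] += [h[i], h[j]]
                xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x0.copy(); xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


def _dic(model, X, y, lonlat, times, loglik) -> tuple[float, float]:
    """DIC = D(theta_hat) + 2 p_D with trace-based Gaussian p_D.

    p_D = tr(H) where H is the hat matrix sending y to the posterior mean of
    the structured part (fixed effects + latent field) under the plug-in
    covariance parameters.
    """
    n = len(y)
    K = build_cov_matrix(lonlat, times, model)
    cf = chol_with_jitter(K)
    Kinv = cho_solve(cf, np.eye(n))
    Cf = K - model.nugget * np.eye(n)
    XtKinv = X.T @ Kinv
    P = np.linalg.solve(XtKinv @ X, XtKinv)      # beta-hat = P y
    S = Cf @ Kinv
    Hmat = X @ P + S @ (np.eye(n) - X @ P)
    p_d = float(np.trace(Hmat))
    if p_d < 0:
        logger.warning("effective number of parameters p_D = %.3f < 0", p_d)
    dic = -2.0 * loglik + 2.0 * p_d
    return dic, p_d


# ---------------------------------------------------------------------------
# prediction


def _krig(m: STGPModel, X, y, lonlat, times, X_new, lonlat_new, times_new,
          include_nugget, include_beta_uncertainty):
    beta = np.array([m.beta["intercept"]] + [m.beta[c] for c in m.covariate_names])
    K = build_cov_matrix(lonlat, times, m)
    cf = chol_with_jitter(K)
    alpha = cho_solve(cf, y - X @ beta)

    d = cdist(np.asarray(lonlat_new, dtype=float), lonlat)
    tl = np.asarray(times_new, dtype=float)[:, None] - times[None, :]
    Kstar = matern_cov(d, m.sigma2, m.kappa, m.nu) * _ar1_factor(m.rho, tl)

    mu = X_new @ beta + Kstar @ alpha
    V = cho_solve(cf, Kstar.T)                      # K^-1 k*
    var = m.sigma2 - np.einsum("ij,ji->i", Kstar, V)
    if include_beta_uncertainty:
        KinvX = cho_solve(cf, X)
        M = np.linalg.inv(X.T @ KinvX)
        u = X_new - Kstar @ KinvX                   # x* - X' K^-1 k*
        var = var + np.einsum("ij,jk,ik->i", u, M, u)
    if include_nugget:
        var = var + m.nugget
    return mu, np.clip(var, 0.0, np.inf)


def predict_points(fit_result: FitResult, X_new: np.ndarray, lonlat_new: np.ndarray,
                   times_new: np.ndarray, include_nugget: bool = False,
                   include_beta_uncertainty: bool = True,
                   integrate_hyper: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Universal-kriging mean and variance at arbitrary (location, wave) points.

    mu* = x*' beta + k*' K^-1 (y - X beta)
    var* = C(0,0) - k*' K^-1 k*  [+ beta-uncertainty term] [+ nugget]

    ``include_nugget=False`` predicts the noise-free latent proportion;
    ``True`` predicts a new noisy observation.  With ``integrate_hyper`` the
    prediction is a weighted mixture over the fitted covariance-parameter
    ensemble (law of total variance), which widens intervals where the
    covariance parameters are weakly identified.
    """
    if integrate_hyper and fit_result.hyper:
        w = np.array([wi for wi, _ in fit_result.hyper])
        mus, vars_ = [], []
        for _, mdl in fit_result.hyper:
            mu_s, var_s = _krig(mdl, fit_result.X, fit_result.y,
                                fit_result.lonlat, fit_result.times,
                                X_new, lonlat_new, times_new,
                                include_nugget, include_beta_uncertainty)
            mus.append(mu_s)
            vars_.append(var_s)
        mus = np.array(mus)
        vars_ = np.array(vars_)
        mu = w @ mus
        var = w @ (vars_ + mus**2) - mu**2
        return mu, np.clip(var, 0.0, np.inf)
    return _krig(fit_result.model, fit_result.X, fit_result.y, fit_result.lonlat,
                 fit_result.times, X_new, lonlat_new, times_new,
                 include_nugget, include_beta_uncertainty)


def predict_interval(fit_result: FitResult, X_new: np.ndarray,
                     lonlat_new: np.ndarray, times_new: np.ndarray,
                     level: float = 0.95, include_nugget: bool = False
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Central predictive interval integrating hyperparameter uncertainty.

    The hyperparameter-integrated predictive at each point is a weighted
    mixture of Gaussians (one per ensemble member); the interval endpoints
    solve the mixture CDF at (1 -/+ level)/2 by bisection, which is wider in
    the tails than a moment-matched Gaussian when the members disagree.
    Falls back to the plug-in Gaussian interval if no ensemble is available.
    """
    alpha = (1.0 - level) / 2.0
    if not fit_result.hyper:
        mu, var = predict_points(fit_result, X_new, lonlat_new, times_new,
                                 include_nugget=include_nugget)
        z = norm.ppf(1.0 - alpha)
        sd = np.sqrt(var)
        return mu - z * sd, mu + z * sd
    w = np.array([wi for wi, _ in fit_result.hyper])
    mus, sds = [], []
    for _, mdl in fit_result.hyper:
        mu_s, var_s = _krig(mdl, fit_result.X, fit_result.y, fit_result.lonlat,
                            fit_result.times, X_new, lonlat_new, times_new,
                            include_nugget, True)
        mus.append(mu_s)
        sds.append(np.sqrt(var_s))
    mus = np.array(mus)                      # (S, n)
    sds = np.maximum(np.array(sds), 1e-12)

    def mix_cdf(x):
        return w @ norm.cdf((x[None, :] - mus) / sds)

    lo_start = (mus - 8 * sds).min(axis=0)
    hi_start = (mus + 8 * sds).max(axis=0)

    def solve(prob):
        a, b = lo_start.copy(), hi_start.copy()
        for _ in range(80):
            mid = 0.5 * (a + b)
            below = mix_cdf(mid) < prob
            a = np.where(below, mid, a)
            b = np.where(below, b, mid)
        return 0.5 * (a + b)

    return solve(alpha), solve(1.0 - alpha)


def predict(fit_result: FitResult, stack: CovariateStack, wave: int,
            config: FitConfig | None = None, clip: bool = True) -> PredictionSurface:
    """Gridded posterior mean and central credible bounds for one wave.

    Cells are processed in tiles so peak memory stays bounded; cells outside
    the stack mask propagate as NaN (nodata).
    """
    config = config or FitConfig()
    obs_waves = np.unique(fit_result.times)
    if np.min(np.abs(obs_waves - wave)) > 1:
        raise ValueError(f"prediction wave {wave} is more than one step from "
                         f"observed waves {obs_waves.tolist()}")
    grid = stack.grid
    centers = grid.cell_centers()
    flat_mask = stack.mask.ravel()
    idx = np.flatnonzero(flat_mask)
    Z = np.column_stack([stack.layers[c].ravel()[idx] for c in fit_result.covariates]) \
        if fit_result.covariates else np.empty((len(idx), 0))
    X_new = np.column_stack([np.ones(len(idx)), Z])

    mean = np.full(grid.n_cells, np.nan)
    var = np.full(grid.n_cells, np.nan)
    for s in range(0, len(idx), config.tile_size):
        sl = slice(s, s + config.tile_size)
        mu, v = predict_points(
            fit_result, X_new[sl], centers[idx[sl]],
            np.full(len(idx[sl]), wave, dtype=float),
            include_nugget=False,
            include_beta_uncertainty=config.include_beta_uncertainty)
        mean[idx[sl]] = mu
        var[idx[sl]] = v

    z = norm.ppf(0.5 + config.interval / 2.0)
    sd = np.sqrt(var)
    lower, upper = mean - z * sd, mean + z * sd
    n_clipped = 0
    if clip:
        for arr in (mean, lower, upper):
            bad = (arr < 0) | (arr > 1)
            n_clipped += int(np.nansum(bad))
            np.clip(arr, 0.0, 1.0, out=arr)
    if n_clipped:
        logger.info("clipped %d surface values to [0, 1]", n_clipped)
    shape = grid.shape
    return PredictionSurface(grid=grid, time=wave, mean=mean.reshape(shape),
                             lower=lower.reshape(shape), upper=upper.reshape(shape),
                             interval=config.interval, n_clipped=n_clipped)


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fitted models by DIC (log-likelihood breaks ties)."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    y0 = fits[0].y
    for f in fits[1:]:
        if len(f.y) != len(y0) or not np.allclose(f.y, y0):
            raise ValueError("fits were not made on identical response data")
    rows = [{"covariates": "+".join(f.covariates) or "(intercept)",
             "dic": f.dic, "p_d": f.p_d, "loglik": f.loglik} for f in fits]
    df = pd.DataFrame(rows).sort_values(["dic", "loglik"],
                                        ascending=[True, False]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
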