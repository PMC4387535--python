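"""Synthetic survey and raster generator.

Real inputs for this kind of analysis — geolocated household-survey clusters
(DHS-style, with deliberately displaced centroids) and gridded covariate /
population layers — are access-restricted.  This module generates stand-ins
with the exact statistical structure the model assumes: a linear predictor
over environmental covariates, a zero-mean space-time Gaussian field with
Matern(nu=1) spatial covariance and AR(1) wave correlation, Gaussian
measurement noise on the proportion scale, and survey-style anonymisation
displacement of cluster coordinates (up to 2 km urban, 5 km rural, with a
small fraction of rural clusters moved up to 10 km).

Everything is driven by an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from .grids import CovariateStack, RasterGrid
from .stgp import KM_PER_DEGREE, STGPModel, _ar1_factor, build_cov_matrix, matern_cov

#: canonical layer names, mirroring the usual remote-sensing covariate menu
LAYER_NAMES = ("accessibility", "evi", "landcover", "nightlights")


@dataclass
class SimulationTruth:
    """Ground truth retained from a survey simulation, for recovery tests."""

    model: STGPModel
    seed: int
    linear_predictor: np.ndarray        # per cluster, at the TRUE location
    gp: np.ndarray                      # per-cluster latent field draw
    true_lonlat: np.ndarray
    n_clipped: int
    eval_lonlat: np.ndarray | None = None
    eval_times: np.ndarray | None = None
    eval_latent: np.ndarray | None = None   # linear predictor + GP at eval points
    grid_latent: dict[int, np.ndarray] = field(default_factory=dict)


def _smooth_field(shape, rng, sigma_cells: float) -> np.ndarray:
    """Standardized smoothed white noise: a cheap spatially structured layer."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="wrap")
    return (f - f.mean()) / f.std()


def gen_covariate_stack(grid: RasterGrid, seed: int) -> CovariateStack:
    """Four covariate layers emulating long-term environmental means.

    accessibility / evi / nightlights are continuous, spatially smooth and
    standardized to mean 0, sd 1 over the mask; landcover is an integer class
    code in {0..5} derived from thresholding a smooth field.  An urban
    indicator is derivable as nightlights above its 90th percentile.
    """
    if grid.n_cells < 2:
        raise ValueError("degenerate grid: need more than one cell")
    rng = np.random.default_rng(seed)
    shape = grid.shape
    sig = max(min(shape) / 12.0, 1.0)
    mask = np.ones(shape, dtype=bool)

    access = _smooth_field(shape, rng, sig)
    evi = _smooth_field(shape, rng, sig * 1.5)
    lights_raw = _smooth_field(shape, rng, sig / 2.0)
    # sparse bright spots so the upper tail (urban areas) is spatially clumped
    hotspots = np.zeros(shape)
    n_hot = max(grid.n_cells // 400, 3)
    rr = rng.integers(0, shape[0], n_hot)
    cc = rng.integers(0, shape[1], n_hot)
    hotspots[rr, cc] = rng.uniform(5, 15, n_hot)
    lights = lights_raw + gaussian_filter(hotspots, sigma=max(sig / 3.0, 1.0))
    lc_field = _smooth_field(shape, rng, sig)
    landcover = np.digitize(lc_field, np.quantile(lc_field, [1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6]))

    def std(a):
        mu, sd = a[mask].mean(), a[mask].std()
        return (a - mu) / sd

    layers = {
        "accessibility": std(access),
        "evi": std(evi),
        "landcover": landcover.astype(float),
        "nightlights": std(lights),
    }
    return CovariateStack(grid=grid, layers=layers, mask=mask)


def urban_mask(stack: CovariateStack, quantile: float = 0.90) -> np.ndarray:
    """Urban cells: nightlights above the given quantile over the mask."""
    nl = stack.layers["nightlights"]
    thr = np.quantile(nl[stack.mask], quantile)
    return (nl > thr) & stack.mask


def sim_matern_gp(lonlat: np.ndarray, times: np.ndarray, model: STGPModel,
                  seed: int) -> np.ndarray:
    """One draw from the zero-mean space-time field at scattered points.

    Dense Cholesky of the (nugget-free) covariance; intended for n up to a
    few thousand points.
    """
    lonlat = np.asarray(lonlat, dtype=float)
    n = len(lonlat)
    if model.sigma2 == 0.0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    K = build_cov_matrix(lonlat, times, model, include_nugget=False)
    from .stgp import chol_with_jitter
    cf = chol_with_jitter(K, scale=model.sigma2)
    L = np.tril(cf[0])
    return L @ rng.standard_normal(n)


def _sim_gp_all_waves(lonlat: np.ndarray, n_waves: int, model: STGPModel,
                      rng: np.random.Generator) -> np.ndarray:
    """Joint draw of the separable field at every (point, wave) pair.

    Uses the Kronecker structure: F = L_s Z L_t' has covariance
    R_s[i,j] * R_t[u,v], so one n_s Cholesky covers all waves.
    Returns an (n_points, n_waves) array.
    """
    n = len(lonlat)
    if model.sigma2 == 0.0:
        return np.zeros((n, n_waves))
    D = cdist(lonlat, lonlat)
    Rs = matern_cov(D, model.sigma2, model.kappa, model.nu)
    Rs[np.diag_indices(n)] += 1e-10 * model.sigma2
    Ls = cholesky(Rs, lower=True)
    lags = np.arange(n_waves)
    Rt = _ar1_factor(model.rho, lags[:, None] - lags[None, :])
    Lt = cholesky(Rt + 1e-12 * np.eye(n_waves), lower=True)
    Z = rng.standard_normal((n, n_waves))
    return Ls @ Z @ Lt.T


def displace_location(lon, lat, urban, rural_far_fraction: float = 0.01,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      max_km: float | None = None):
    """Survey-anonymisation jitter of cluster coordinates.

    Random uniform bearing; distance uniform on [0, D] km with D = 2 km for
    urban clusters, 5 km for rural ones and 10 km for a ``rural_far_fraction``
    share of rural clusters.  ``max_km`` overrides D (0 disables displacement).
    Conversion uses 1 degree = 111.32 km.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    urban_arr = np.atleast_1d(np.asarray(urban, dtype=bool))
    n = lon.size
    if max_km is not None:
        D = np.full(n, float(max_km))
    else:
        D = np.where(urban_arr, 2.0, 5.0)
        far = (~urban_arr) & (rng.random(n) < rural_far_fraction)
        D = np.where(far, 10.0, D)
    dist_km = rng.uniform(0.0, D)
    bearing = rng.uniform(0.0, 2.0 * np.pi, n)
    dlon = dist_km * np.cos(bearing) / KM_PER_DEGREE
    dlat = dist_km * np.sin(bearing) / KM_PER_DEGREE
    out_lon, out_lat = lon + dlon, lat + dlat
    if out_lon.size == 1 and np.isscalar(urban):
        return float(out_lon[0]), float(out_lat[0])
    return out_lon, out_lat


def gen_population_raster(grid: RasterGrid, seed: int, total: float = 1e6,
                          stack: CovariateStack | None = None) -> np.ndarray:
    """Per-cell person counts: log-normal texture concentrated in bright cells."""
    rng = np.random.default_rng(seed)
    base = np.exp(1.2 * _smooth_field(grid.shape, rng, max(min(grid.shape) / 10, 1.0)))
    if stack is not None:
        base = base * np.exp(1.5 * np.clip(stack.layers["nightlights"], 0, None))
    pop = base / base.sum() * total
    return pop


def gen_zone_raster(grid: RasterGrid, n_zone_rows: int = 3,
                    n_zone_cols: int = 3) -> np.ndarray:
    """Integer admin-zone labels as a block partition of the grid."""
    rows = np.minimum((np.arange(grid.n_rows) * n_zone_rows) // grid.n_rows,
                      n_zone_rows - 1)
    cols = np.minimum((np.arange(grid.n_cols) * n_zone_cols) // grid.n_cols,
                      n_zone_cols - 1)
    return (rows[:, None] * n_zone_cols + cols[None, :]).astype(int)


def simulate_survey(stack: CovariateStack, model: STGPModel, n_clusters: int,
                    n_waves: int, households_range: tuple[int, int] = (20, 50),
                    seed: int = 0, urban_fraction: float = 0.3,
                    rural_far_fraction: float = 0.01,
                    persons_per_household: tuple[float, float] = (4.0, 6.0),
                    zones: np.ndarray | None = None,
                    eval_points: tuple[np.ndarray, np.ndarray] | None = None,
                    displace: bool = True,
                    ) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate a multi-wave cluster survey over the covariate stack.

    Cluster cells are drawn without replacement from the mask, stratified by
    the urban flag (``urban_fraction`` of clusters in urban cells).  The
    response is built at the TRUE location:

        p = beta' x(true cell) + f(true location, wave) + N(0, nugget),

    clipped to [0, 1] (clip events are counted on the returned truth), while
    the *recorded* coordinates are the displaced ones — reproducing the
    covariate-mismatch error that survey anonymisation introduces.  Counts
    are back-filled as ``n_under5 = round(p * n_people)``; ``p_under5``
    remains the continuous response the Gaussian likelihood models.

    ``eval_points`` is an optional (lonlat, times) pair at which the latent
    field is drawn *jointly* with the cluster field, giving held-out truth
    for calibration checks.  ``displace=False`` records the true coordinates
    instead — used when estimator properties are studied in isolation from
    the geomasking error.
    """
    if n_clusters < 10:
        raise ValueError("need at least 10 clusters")
    if n_waves < 1:
        raise ValueError("need at least one survey wave")
    rng = np.random.default_rng(seed)
    grid = stack.grid
    urb = urban_mask(stack)
    flat_urb = urb.ravel()
    flat_mask = stack.mask.ravel()
    if n_clusters > flat_mask.sum():
        raise ValueError("n_clusters exceeds the number of masked-in cells")

    n_urban = min(int(round(n_clusters * urban_fraction)), int(flat_urb.sum()))
    n_rural = n_clusters - n_urban
    urb_cells = np.flatnonzero(flat_urb)
    rur_cells = np.flatnonzero(flat_mask & ~flat_urb)
    cells = np.concatenate([
        rng.choice(urb_cells, size=n_urban, replace=False),
        rng.choice(rur_cells, size=n_rural, replace=False),
    ])
    is_urban = np.concatenate([np.ones(n_urban, bool), np.zeros(n_rural, bool)])
    order = rng.permutation(n_clusters)
    cells, is_urban = cells[order], is_urban[order]

    centers = grid.cell_centers()
    jit = (rng.random((n_clusters, 2)) - 0.5) * grid.cell_size
    true_lonlat = centers[cells] + jit
    times = rng.integers(0, n_waves, n_clusters)

    names = model.covariate_names
    Xc = np.column_stack([stack.layers[c].ravel()[cells] for c in names]) \
        if names else np.empty((n_clusters, 0))
    beta = np.array([model.beta["intercept"]] + [model.beta[c] for c in names])
    linpred = np.column_stack([np.ones(n_clusters), Xc]) @ beta

    # one joint draw across clusters (+ optional eval points) and all waves
    if eval_points is not None:
        ev_lonlat = np.asarray(eval_points[0], dtype=float)
        ev_times = np.asarray(eval_points[1])
        all_lonlat = np.vstack([true_lonlat, ev_lonlat])
    else:
        all_lonlat = true_lonlat
    F = _sim_gp_all_waves(all_lonlat, n_waves, model, rng)
    gp = F[np.arange(n_clusters), times]

    noise = rng.standard_normal(n_clusters) * np.sqrt(model.nugget)
    p_raw = linpred + gp + noise
    p = np.clip(p_raw, 0.0, 1.0)
    n_clipped = int(np.sum(p != p_raw))

    rec_lon, rec_lat = displace_location(
        true_lonlat[:, 0], true_lonlat[:, 1], is_urban,
        rural_far_fraction=rural_far_fraction, rng=rng,
        max_km=None if displace else 0.0)

    n_households = rng.integers(households_range[0], households_range[1] + 1, n_clusters)
    pph = rng.uniform(*persons_per_household, n_clusters)
    n_people = np.maximum(np.round(n_households * pph).astype(int), 1)
    n_under5 = np.round(p * n_people).astype(int)

    if zones is not None:
        row, col = grid.index_of(rec_lon, rec_lat)
        zone_id = np.asarray(zones)[row, col].astype(int)
    else:
        zone_id = np.zeros(n_clusters, dtype=int)

    clusters = pd.DataFrame({
        "cluster_id": np.arange(n_clusters),
        "lon": rec_lon, "lat": rec_lat, "time": times,
        "n_households": n_households, "n_people": n_people,
        "n_under5": n_under5, "p_under5": p,
        "urban": is_urban, "zone_id": zone_id,
    })
    truth = SimulationTruth(
        model=model, seed=seed, linear_predictor=linpred, gp=gp,
        true_lonlat=true_lonlat, n_clipped=n_clipped)
    if eval_points is not None:
        n_ev = len(ev_lonlat)
        Zev = stack.values_at(ev_lonlat[:, 0], ev_lonlat[:, 1], names) \
            if names else np.empty((n_ev, 0))
        ev_lin = np.column_stack([np.ones(n_ev), Zev]) @ beta
        ev_gp = F[n_clusters:][np.arange(n_ev), np.asarray(ev_times, dtype=int)]
        truth.eval_lonlat = ev_lonlat
        truth.eval_times = np.asarray(ev_times)
        truth.eval_latent = ev_lin + ev_gp
    return clusters, truth
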