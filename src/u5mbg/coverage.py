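"""Intervention-coverage application layer.

Turns a proportion surface into an under-five *count* surface by multiplying
with a gridded population layer, aggregates the counts to admin zones, and
contrasts three ways of getting the under-five denominator:

* ``mbg``       — the geostatistical surface (cellwise, with credible bounds);
* ``census``    — one proportion per zone applied uniformly inside the zone;
* ``un_uniform``— a single national proportion (e.g. the UN medium-scenario
  17.5%) applied everywhere.

Unprotected counts are denominator x (1 - coverage).  Zone credible bounds
sum the cellwise bounds, a deliberately conservative envelope since
cell-level posterior correlation is not retained in the surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stgp import PredictionSurface

UNASSIGNED_ZONE = -1


@dataclass
class ZonalEstimate:
    zone_id: int
    method: str                       # "mbg" | "census" | "un_uniform"
    under5: tuple[float, float, float]      # (mean, lower, upper) persons
    coverage_prop: float = np.nan
    unprotected: tuple[float, float, float] | None = None


def under5_surface(prop: PredictionSurface, pop: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cellwise product of the proportion surface bounds with the population."""
    pop = np.asarray(pop, dtype=float)
    if pop.shape != prop.mean.shape:
        raise ValueError("population raster shape does not match the surface grid")
    return prop.mean * pop, prop.lower * pop, prop.upper * pop


def uniform_adjustment(pop: np.ndarray, p: float = 0.175) -> np.ndarray:
    """Single national proportion applied to every cell."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return np.asarray(pop, dtype=float) * p


def census_adjustment(pop: np.ndarray, zone_props: dict[int, float],
                      zones: np.ndarray) -> np.ndarray:
    """Per-zone proportions applied uniformly within each zone."""
    pop = np.asarray(pop, dtype=float)
    zones = np.asarray(zones)
    if pop.shape != zones.shape:
        raise ValueError("population and zone rasters must share a grid")
    out = np.full(pop.shape, np.nan)
    for z in np.unique(zones):
        if z == UNASSIGNED_ZONE:
            continue
        if int(z) not in zone_props:
            raise ValueError(f"no proportion supplied for zone {int(z)}")
        sel = zones == z
        out[sel] = pop[sel] * zone_props[int(z)]
    return out


def zonal_aggregate(count: np.ndarray, zones: np.ndarray) -> dict[int, float]:
    """Sum raster values per zone; NaN-zone or NaN-value cells go to the
    ``UNASSIGNED_ZONE`` bucket so national totals are conserved exactly."""
    count = np.asarray(count, dtype=float)
    zones = np.asarray(zones)
    if count.shape != zones.shape:
        raise ValueError("count raster and zone raster must share a grid")
    out: dict[int, float] = {}
    valid = np.isfinite(count)
    for z in np.unique(zones):
        sel = (zones == z) & valid
        out[int(z)] = float(count[sel].sum())
    return out


def unprotected(zonal_under5: dict[int, tuple[float, float, float]],
                coverage_prop: dict[int, float], method: str) -> list[ZonalEstimate]:
    """Zone-level unprotected counts: under5 * (1 - coverage), elementwise."""
    out = []
    for z, u5 in sorted(zonal_under5.items()):
        cov = coverage_prop.get(z, np.nan)
        if np.isfinite(cov) and not 0.0 <= cov <= 1.0:
            raise ValueError(f"coverage proportion for zone {z} outside [0, 1]")
        unprot = tuple(v * (1.0 - cov) for v in u5) if np.isfinite(cov) else None
        out.append(ZonalEstimate(zone_id=z, method=method, under5=tuple(u5),
                                 coverage_prop=cov, unprotected=unprot))
    return out


def compare_methods(estimates: dict[str, list[ZonalEstimate]],
                    reference: str = "mbg") -> pd.DataFrame:
    """Per-zone absolute and percentage differences of each method vs the
    reference, ranked by the absolute under-five gap."""
    if reference not in estimates:
        raise ValueError(f"reference method {reference!r} missing")
    ref = {e.zone_id: e for e in estimates[reference]}
    rows = []
    for method, ests in estimates.items():
        if method == reference:
            continue
        zones_m = {e.zone_id for e in ests}
        if zones_m != set(ref):
            raise ValueError("methods cover different zone sets")
        for e in ests:
            r = ref[e.zone_id]
            diff = e.under5[0] - r.under5[0]
            pct = 100.0 * diff / r.under5[0] if r.under5[0] != 0 else np.nan
            row = {"zone_id": e.zone_id, "method": e.method,
                   "under5": e.under5[0], f"under5_{reference}": r.under5[0],
                   "abs_diff": diff, "pct_diff": pct}
            if e.unprotected is not None and r.unprotected is not None:
                row["unprotected_diff"] = e.unprotected[0] - r.unprotected[0]
            rows.append(row)
    df = pd.DataFrame(rows)
    df["gap_rank"] = df.assign(mag=df["abs_diff"].abs()).groupby("method")["mag"].rank(
        ascending=False, method="first").astype(int)
    return df.sort_values(["method", "gap_rank"]).reset_index(drop=True)
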