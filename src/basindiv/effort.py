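"""Sampling-effort diagnostics: rarefaction/extrapolation and coverage tables.

The rarefaction side follows the standard sample-size-based estimator for
abundance-type frequency vectors,

    E[S(m)] = S_obs - sum_i C(n - x_i, m) / C(n, m)        (m <= n)

evaluated in log space, and the Chao1-based extrapolation

    S(n + m*) = S_obs + f0 * (1 - (1 - f1 / (n f0 + f1))**m*)

with ``f0 = ((n-1)/n) f1^2 / (2 f2)`` when doubletons exist, else
``((n-1)/n) f1 (f1-1) / 2``.  Confidence bounds come from a seeded
multinomial bootstrap of the reference sample with a normal approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .grid import EARTH_RADIUS_KM, parse_cell_id


def cell_area(lat_south: float, cell_size: float = 1.0,
              radius: float = EARTH_RADIUS_KM) -> float:
    """Area in km^2 of a lon/lat cell via the spherical band formula
    ``R^2 * dlambda * (sin(phi2) - sin(phi1))``."""
    phi1 = np.radians(lat_south)
    phi2 = np.radians(lat_south + cell_size)
    dlam = np.radians(cell_size)
    return float(radius ** 2 * dlam * (np.sin(phi2) - np.sin(phi1)))


def _rarefied_richness(freqs: np.ndarray, m: int) -> float:
    """Expected richness in a subsample of m individuals (hypergeometric)."""
    n = int(freqs.sum())
    if m >= n:
        return float(len(freqs))
    x = freqs.astype(float)
    with np.errstate(invalid="ignore"):
        log_ratio = (gammaln(n - x + 1) + gammaln(n - m + 1)
                     - gammaln(n - x - m + 1) - gammaln(n + 1))
    term = np.where(n - x >= m, np.exp(log_ratio), 0.0)
    return float(len(freqs) - term.sum())


def _extrapolated_richness(freqs: np.ndarray, m_star: int) -> float:
    s_obs = len(freqs)
    n = int(freqs.sum())
    f1 = int((freqs == 1).sum())
    f2 = int((freqs == 2).sum())
    if f1 == 0:
        return float(s_obs)
    if f2 > 0:
        f0 = (n - 1) / n * f1 ** 2 / (2 * f2)
    else:
        f0 = (n - 1) / n * f1 * (f1 - 1) / 2
    if f0 == 0:
        return float(s_obs)
    return float(s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** m_star))


def estimate_richness(freqs, m) -> float:
    """Seamless rarefaction/extrapolation point estimate at sample size m."""
    freqs = np.asarray(freqs)
    freqs = freqs[freqs > 0]
    n = int(freqs.sum())
    if m <= n:
        return _rarefied_richness(freqs, int(m))
    return _extrapolated_richness(freqs, int(m) - n)


@dataclass
class RarefactionCurve:
    region: str
    n: int
    s_obs: int
    f1: int
    f2: int
    m: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    extrapolation_unreliable: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region": self.region, "m": self.m,
                             "richness": self.estimate,
                             "lower": self.lower, "upper": self.upper})


def rarefy_extrapolate(freqs, m_grid=None, n_boot: int = 200,
                       seed: int | None = None, region: str = "") -> RarefactionCurve:
    """Sample-size-based rarefaction/extrapolation curve with bootstrap CI.

    ``freqs`` is the per-species occurrence frequency vector of the region.
    When every species is a singleton the extrapolation is flagged
    unreliable but still returned.
    """
    freqs = np.asarray(freqs, dtype=int)
    if (freqs <= 0).any():
        raise ValueError("frequencies must be positive integers")
    n = int(freqs.sum())
    if n < 2:
        raise ValueError("need a reference sample of at least 2 records")
    s_obs = len(freqs)
    f1 = int((freqs == 1).sum())
    f2 = int((freqs == 2).sum())
    if m_grid is None:
        m_grid = np.unique(np.concatenate([
            np.linspace(1, n, 20).astype(int), np.linspace(n, 2 * n, 10).astype(int)]))
    m_grid = np.asarray(sorted(int(m) for m in m_grid))
    est = np.array([estimate_richness(freqs, m) for m in m_grid])

    rng = np.random.default_rng(seed)
    if n_boot and n_boot > 0:
        p = freqs / n
        sims = np.empty((n_boot, len(m_grid)))
        for b in range(n_boot):
            counts = rng.multinomial(n, p)
            counts = counts[counts > 0]
            sims[b] = [estimate_richness(counts, m) for m in m_grid]
        se = sims.std(axis=0, ddof=1)
    else:
        se = np.zeros(len(m_grid))
    lower = est - 1.96 * se
    upper = est + 1.96 * se
    return RarefactionCurve(region=region, n=n, s_obs=s_obs, f1=f1, f2=f2,
                            m=m_grid, estimate=est, lower=lower, upper=upper,
                            extrapolation_unreliable=(f1 == n))


def _cells_in_geometry(cells, geom, cell_size: float = 1.0) -> np.ndarray:
    from shapely import contains, points
    xy = np.array([parse_cell_id(c) for c in cells], dtype=float)
    pts = points(xy + cell_size / 2.0)
    return contains(geom, pts)


def region_coverage(pam_cells, masks: dict, gridded_records: pd.DataFrame,
                    cell_size: float = 1.0, basin=None,
                    grid_cells=None) -> pd.DataFrame:
    """Per-region coverage statistics (cells, observations, species, areas).

    ``masks`` maps region name to a shapely polygon; cells are assigned by
    their center to the *first* mask that contains them, in mask order.
    ``grid_cells`` is the full cell inventory of the study window (defaults
    to the sampled cells only, in which case per-region totals reflect the
    sampled universe); the basin is the union of the masks unless given.
    """
    from shapely import union_all

    sampled_cells = list(pam_cells)
    grid_cells = list(grid_cells) if grid_cells is not None else sampled_cells
    basin_geom = basin if basin is not None else union_all(list(masks.values()))

    assigned = {}
    for name, geom in masks.items():
        inside = _cells_in_geometry(grid_cells, geom, cell_size)
        for c, isin in zip(grid_cells, inside):
            if isin and c not in assigned:
                assigned[c] = name

    basin_cells = [c for c in grid_cells
                   if _cells_in_geometry([c], basin_geom, cell_size)[0]]
    basin_area = sum(cell_area(parse_cell_id(c)[1], cell_size) for c in basin_cells)

    rec_by_cell = gridded_records.groupby("cell_id")
    n_obs = rec_by_cell.size()
    rows = []
    total = dict.fromkeys(("total_cells", "sampled_cells", "observations",
                           "area_km2", "sampled_area_km2"), 0.0)
    for name in masks:
        cells_r = [c for c, m in assigned.items() if m == name]
        sampled_r = [c for c in cells_r if c in set(sampled_cells) and n_obs.get(c, 0) > 0]
        area_r = sum(cell_area(parse_cell_id(c)[1], cell_size) for c in cells_r)
        s_area = sum(cell_area(parse_cell_id(c)[1], cell_size) for c in sampled_r)
        recs = gridded_records[gridded_records["cell_id"].isin(set(cells_r))]
        rows.append({
            "region": name,
            "area_km2": area_r,
            "total_cells": len(cells_r),
            "sampled_cells": len(sampled_r),
            "observations": int(len(recs)),
            "species_observed": int(recs["scientific_name"].nunique()),
            "sampled_area_km2": s_area,
            "pct_region_sampled": 100.0 * s_area / area_r if area_r > 0 else 0.0,
            "pct_basin_sampled": 100.0 * s_area / basin_area if basin_area > 0 else 0.0,
        })
        total["total_cells"] += len(cells_r)
        total["sampled_cells"] += len(sampled_r)
        total["observations"] += len(recs)
        total["area_km2"] += area_r
        total["sampled_area_km2"] += s_area
    rows.append({
        "region": "Total",
        "area_km2": basin_area,
        "total_cells": int(total["total_cells"]),
        "sampled_cells": int(total["sampled_cells"]),
        "observations": int(total["observations"]),
        "species_observed": int(gridded_records["scientific_name"].nunique()),
        "sampled_area_km2": total["sampled_area_km2"],
        "pct_region_sampled": np.nan,
        "pct_basin_sampled": (100.0 * total["sampled_area_km2"] / basin_area
                              if basin_area > 0 else 0.0),
    })
    return pd.DataFrame(rows)
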