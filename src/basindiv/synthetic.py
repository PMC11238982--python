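"""Synthetic occurrence scenarios with known ground truth.

Everything downstream of the cleaning stage is exercised against data built
here: environmental fields with controlled spatial structure, a species pool
with Gaussian niche responses, heterogeneous sampling effort, and optional
"dirty" records (missing/zero coordinates, genus-level ranks, exact
duplicates) carrying a hidden audit tag so the cleaning rules can be checked
record by record.

All randomness flows from one integer seed; sub-streams are derived from it
by fixed offsets so individual stages stay reproducible in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec, cell_id

ENV_VARIABLES = ("T_mean", "S", "Chla", "O2", "MLD")

# fixed offsets for deriving independent sub-streams from the global seed
_OFFSET_ENV = 101
_OFFSET_POOL = 211
_OFFSET_OCC = 307
_OFFSET_DIRTY = 401

AUDIT_COLUMN = "_audit"
AUDIT_CLEAN = ""
AUDIT_TAGS = ("missing_coords", "zero_coords", "genus_rank", "duplicate")


@dataclass(frozen=True)
class SpeciesPool:
    """Species with Gaussian niche responses to the environmental variables.

    ``table`` has one row per species: ``species_id``, ``name``,
    ``baseline_prevalence`` and, per variable ``v`` in ``env_vars``, columns
    ``center_v`` and ``width_v``.
    """

    table: pd.DataFrame
    env_vars: tuple = ENV_VARIABLES

    def __post_init__(self):
        t = self.table
        if t["name"].duplicated().any():
            raise ValueError("species names must be unique")
        for v in self.env_vars:
            if (t[f"width_{v}"] <= 0).any():
                raise ValueError(f"niche widths for {v} must be positive")
        prev = t["baseline_prevalence"]
        if ((prev <= 0) | (prev > 1)).any():
            raise ValueError("baseline_prevalence must lie in (0, 1]")

    @property
    def n_species(self) -> int:
        return len(self.table)

    @property
    def names(self):
        return list(self.table["name"])


@dataclass(frozen=True)
class EnvStack:
    """Per-slice environmental fields on a grid.

    ``fields[var]`` is an array of shape ``(n_slices, n_lon, n_lat)`` in the
    lon-major cell order of :meth:`GridSpec.cell_corners`.
    """

    grid: GridSpec
    fields: dict
    years: tuple

    @property
    def n_slices(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        """Long format: cell_id, lon, lat, time, variable, value."""
        gx, gy = self.grid.cell_corners()
        cids = [cell_id(x, y) for x, y in zip(gx, gy)]
        frames = []
        for var, arr in self.fields.items():
            for t, year in enumerate(self.years):
                frames.append(pd.DataFrame({
                    "cell_id": cids,
                    "lon": gx,
                    "lat": gy,
                    "time": year,
                    "variable": var,
                    "value": arr[t].ravel(),
                }))
        return pd.concat(frames, ignore_index=True)

    def mean_table(self) -> pd.DataFrame:
        """Per-cell across-slice means, one column per variable."""
        gx, gy = self.grid.cell_corners()
        out = pd.DataFrame({
            "cell_id": [cell_id(x, y) for x, y in zip(gx, gy)],
            "lon": gx,
            "lat": gy,
        })
        for var, arr in self.fields.items():
            out[var] = arr.mean(axis=0).ravel()
        return out


def _random_field(rng, shape, scale):
    """Unit-variance Gaussian random field via smoothed white noise.

    ``scale`` is in cell units; ``inf`` collapses the field to a constant,
    the limiting case of infinite correlation length.
    """
    noise = rng.standard_normal(shape)
    if np.isinf(scale):
        return np.zeros(shape)
    if scale > 0:
        noise = ndimage.gaussian_filter(noise, sigma=scale, mode="wrap")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    return noise


def make_env_fields(grid: GridSpec, n_time_slices: int = 2, spatial_scale: float = 2.0,
                    seed: int = 0, start_year: int = 1993) -> EnvStack:
    """Generate temperature, salinity, chlorophyll, oxygen and MLD slices.

    Each variable is a smooth latitudinal gradient plus Gaussian random field
    noise; oxygen is a strongly decreasing function of temperature so the
    T/O2 Spearman correlation is close to -1 by construction.  With
    ``spatial_scale=inf`` every per-slice field is constant across cells.
    """
    if grid.n_cells < 2:
        raise ValueError("degenerate grid: need at least 2 cells")
    if n_time_slices < 1:
        raise ValueError("need at least one time slice")
    rng = np.random.default_rng(seed + _OFFSET_ENV)
    gx, gy = grid.cell_corners()
    lat = gy.reshape(grid.n_lon, grid.n_lat) + grid.cell_size / 2.0
    shape = (grid.n_lon, grid.n_lat)

    if np.isinf(spatial_scale):
        # infinite correlation length: no spatial structure at all
        def gradient(a, b):
            return np.full(shape, (a + b) / 2.0)
    else:
        def gradient(a, b):
            # linear in latitude between the poleward (a) and equatorward (b) ends
            latspan = max(np.ptp(np.abs(lat)), 1e-12)
            frac = (np.abs(lat) - np.abs(lat).min()) / latspan
            return b + (a - b) * frac

    fields = {}
    years = tuple(start_year + t for t in range(n_time_slices))
    T = np.empty((n_time_slices,) + shape)
    for t in range(n_time_slices):
        T[t] = gradient(5.0, 28.0) + 1.5 * _random_field(rng, shape, spatial_scale) \
            + 0.3 * rng.standard_normal()
    fields["T_mean"] = T
    S = np.empty_like(T)
    for t in range(n_time_slices):
        S[t] = gradient(34.0, 36.0) + 0.4 * _random_field(rng, shape, spatial_scale)
    fields["S"] = S
    chla = np.empty_like(T)
    for t in range(n_time_slices):
        chla[t] = np.exp(gradient(0.5, -1.5) + 0.5 * _random_field(rng, shape, spatial_scale))
    fields["Chla"] = chla
    # oxygen: strong monotone decreasing function of temperature + tiny noise
    o2 = np.empty_like(T)
    for t in range(n_time_slices):
        o2[t] = 320.0 - 5.0 * T[t] + 0.5 * _random_field(rng, shape, spatial_scale)
    fields["O2"] = o2
    mld = np.empty_like(T)
    for t in range(n_time_slices):
        mld[t] = np.exp(gradient(4.5, 3.0) + 0.3 * _random_field(rng, shape, spatial_scale))
    fields["MLD"] = mld
    return EnvStack(grid=grid, fields=fields, years=years)


def make_species_pool(env_table: pd.DataFrame, n_species: int = 40, seed: int = 0,
                      env_vars=ENV_VARIABLES, width_scale: float = 0.35,
                      prevalence_range=(0.2, 1.0)) -> SpeciesPool:
    """Draw a species pool whose niche centers span the observed env ranges."""
    rng = np.random.default_rng(seed + _OFFSET_POOL)
    rows = {"species_id": np.arange(n_species),
            "name": [_binomial_name(i) for i in range(n_species)]}
    lo, hi = prevalence_range
    rows["baseline_prevalence"] = lo + (hi - lo) * rng.random(n_species)
    for v in env_vars:
        x = env_table[v].to_numpy(dtype=float)
        span = max(x.max() - x.min(), 1e-9)
        rows[f"center_{v}"] = x.min() + span * rng.random(n_species)
        rows[f"width_{v}"] = span * width_scale * (0.5 + rng.random(n_species))
    return SpeciesPool(table=pd.DataFrame(rows), env_vars=tuple(env_vars))


_GENERA = ("Acantha", "Brachy", "Cteno", "Dolio", "Eury", "Falco", "Gracili",
           "Helio", "Ischno", "Lepto")
_EPITHETS = ("australis", "borealis", "communis", "dispar", "elegans", "firmus",
             "gracilis", "humilis", "inermis", "longus", "medius", "nitidus",
             "obscurus", "parvus", "rectus", "similis", "tenuis", "validus")


def _binomial_name(i: int) -> str:
    g = _GENERA[i % len(_GENERA)] + "us"
    e = _EPITHETS[(i // len(_GENERA)) % len(_EPITHETS)]
    suffix = i // (len(_GENERA) * len(_EPITHETS))
    return f"{g} {e}" + (f" v{suffix}" if suffix else "")


def occupancy_probability(env_table: pd.DataFrame, pool: SpeciesPool) -> np.ndarray:
    """Per-event detection probability, cells x species.

    Product of per-variable Gaussian kernels scaled by baseline prevalence.
    """
    n_cells = len(env_table)
    p = np.tile(pool.table["baseline_prevalence"].to_numpy(), (n_cells, 1))
    for v in pool.env_vars:
        x = env_table[v].to_numpy(dtype=float)[:, None]
        c = pool.table[f"center_{v}"].to_numpy()[None, :]
        w = pool.table[f"width_{v}"].to_numpy()[None, :]
        p = p * np.exp(-0.5 * ((x - c) / w) ** 2)
    return p


def uniform_effort(env_table: pd.DataFrame, expected_samples: float = 5.0) -> pd.Series:
    """Constant expected sampling events per cell, indexed by cell_id."""
    return pd.Series(expected_samples, index=pd.Index(env_table["cell_id"], name="cell_id"),
                     name="expected_samples")


def simulate_occurrences(env_table: pd.DataFrame, pool: SpeciesPool,
                         effort: pd.Series, dirty_fraction: float = 0.0,
                         seed: int = 0, period=(1993, 2019),
                         cell_size: float = 1.0, fixed_events: bool = False) -> pd.DataFrame:
    """Simulate Darwin Core-style occurrence records.

    Per cell the number of sampling events is Poisson(expected_samples); per
    event each species is recorded independently with its occupancy
    probability.  A ``dirty_fraction`` of the resulting records is corrupted
    (or duplicated); every corrupted row carries its corruption type in the
    hidden ``_audit`` column, which the cleaning stage never reads.
    """
    if not (0.0 <= dirty_fraction <= 1.0):
        raise ValueError("dirty_fraction must be in [0, 1]")
    effort = effort.reindex(env_table["cell_id"])
    if effort.isna().any():
        raise ValueError("env_table must cover all effort cells")
    if not (effort > 0).any():
        warnings.warn("no cell has positive sampling effort", stacklevel=2)

    rng = np.random.default_rng(seed + _OFFSET_OCC)
    p = occupancy_probability(env_table, pool)
    names = np.asarray(pool.names)
    lon0 = env_table["lon"].to_numpy(dtype=float)
    lat0 = env_table["lat"].to_numpy(dtype=float)
    cids = env_table["cell_id"].to_numpy()

    rows = []
    y0, y1 = period
    n_days = (pd.Timestamp(f"{y1}-12-31") - pd.Timestamp(f"{y0}-01-01")).days
    for ci in range(len(env_table)):
        n_events = int(round(effort.iloc[ci])) if fixed_events \
            else rng.poisson(effort.iloc[ci])
        for _ in range(n_events):
            hits = np.nonzero(rng.random(pool.n_species) < p[ci])[0]
            if hits.size == 0:
                continue
            # one shared sampling location/date/depth per event, inside the cell
            lon = lon0[ci] + cell_size * rng.uniform(0.05, 0.95)
            lat = lat0[ci] + cell_size * rng.uniform(0.05, 0.95)
            date = (pd.Timestamp(f"{y0}-01-01") + pd.Timedelta(days=int(rng.integers(n_days + 1)))).date()
            depth = float(np.round(rng.uniform(0.0, 200.0), 3))
            for s in hits:
                rows.append((names[s], "species", lat, lon, str(date), depth, depth, cids[ci]))

    rec = pd.DataFrame(rows, columns=["scientificName", "taxonRank", "decimalLatitude",
                                      "decimalLongitude", "eventDate",
                                      "minimumDepthInMeters", "maximumDepthInMeters",
                                      "true_cell_id"])
    rec["source_id"] = [f"rec{i:07d}" for i in range(len(rec))]
    rec[AUDIT_COLUMN] = AUDIT_CLEAN
    if len(rec) == 0 or dirty_fraction == 0.0:
        return rec
    return _corrupt(rec, dirty_fraction, np.random.default_rng(seed + _OFFSET_DIRTY))


def _corrupt(rec: pd.DataFrame, dirty_fraction: float, rng) -> pd.DataFrame:
    """Corrupt a tagged fraction of records; duplicates are appended copies."""
    n = len(rec)
    n_dirty = int(round(dirty_fraction * n))
    if n_dirty == 0:
        return rec
    kinds = np.array(AUDIT_TAGS)[rng.integers(0, len(AUDIT_TAGS), n_dirty)]
    n_dup = int((kinds == "duplicate").sum())
    # in-place corruptions hit distinct rows; duplicates copy untouched rows
    idx_corrupt = rng.choice(n, size=n_dirty - n_dup, replace=False)
    k_inplace = kinds[kinds != "duplicate"]
    rec = rec.copy()
    for i, kind in zip(idx_corrupt, k_inplace):
        if kind == "missing_coords":
            rec.iloc[i, rec.columns.get_loc("decimalLatitude")] = np.nan
            rec.iloc[i, rec.columns.get_loc("decimalLongitude")] = np.nan
        elif kind == "zero_coords":
            rec.iloc[i, rec.columns.get_loc("decimalLatitude")] = 0.0
            rec.iloc[i, rec.columns.get_loc("decimalLongitude")] = 0.0
        elif kind == "genus_rank":
            name = rec.iloc[i, rec.columns.get_loc("scientificName")]
            rec.iloc[i, rec.columns.get_loc("scientificName")] = str(name).split()[0]
            rec.iloc[i, rec.columns.get_loc("taxonRank")] = "genus"
        rec.iloc[i, rec.columns.get_loc(AUDIT_COLUMN)] = kind
    if n_dup:
        clean_idx = np.setdiff1d(np.arange(n), idx_corrupt)
        src = rng.choice(clean_idx, size=n_dup, replace=False)
        dup = rec.iloc[src].copy()
        dup[AUDIT_COLUMN] = "duplicate"
        rec = pd.concat([rec, dup], ignore_index=True)
    return rec


def ground_truth(env_table: pd.DataFrame, pool: SpeciesPool,
                 effort: pd.Series | None = None, hotspot_quantile: float = 0.9) -> pd.DataFrame:
    """Analytic expected diversity per cell.

    With Poisson(lambda) sampling events and per-event detection probability
    ``p``, the chance a species is ever recorded in a cell is
    ``1 - exp(-lambda * p)``; expected richness is the sum over species.
    Without an effort field a single event per cell is assumed (occupancy
    ``p`` itself).  ``hotspot_flag`` marks the top decile of expected
    richness.
    """
    p = occupancy_probability(env_table, pool)
    if effort is not None:
        lam = effort.reindex(env_table["cell_id"]).to_numpy(dtype=float)[:, None]
        occ = 1.0 - np.exp(-lam * p)
    else:
        occ = p
    richness = occ.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = occ / np.where(richness > 0, richness, np.nan)[:, None]
        h = -np.nansum(np.where(q > 0, q * np.log(q), 0.0), axis=1)
    thr = np.quantile(richness, hotspot_quantile)
    return pd.DataFrame({
        "cell_id": env_table["cell_id"].to_numpy(),
        "lon": env_table["lon"].to_numpy(),
        "lat": env_table["lat"].to_numpy(),
        "true_richness": richness,
        "true_shannon": h,
        "hotspot_flag": richness >= thr,
    })
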