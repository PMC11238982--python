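"""Reading, cleaning, harmonizing and gridding occurrence records.

The cleaning stage applies an ordered rule list — missing coordinates, zero
coordinates, on land, outside basin, non-species rank, outside depth window,
outside period, duplicate — attributing every dropped record to the *first*
rule it violates, so the report counts always reconcile with the totals.

Cells are half-open 1-degree (by default) boxes identified by the SW corner
(see :mod:`basindiv.grid`); duplicate detection rounds coordinates to 4
decimals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, cell_id, parse_cell_id, wrap_lon

#: Darwin Core term -> internal column name
DEFAULT_COLUMN_MAP = {
    "scientificName": "scientific_name",
    "taxonRank": "taxon_rank",
    "decimalLatitude": "latitude",
    "decimalLongitude": "longitude",
    "eventDate": "event_date",
    "minimumDepthInMeters": "depth_min",
    "maximumDepthInMeters": "depth_max",
    "depth": "depth_min",
    "source_id": "source_id",
    "occurrenceID": "source_id",
}

RULE_ORDER = ("missing_coords", "zero_coords", "on_land", "outside_basin",
              "non_species_rank", "outside_depth", "outside_period", "duplicate")


@dataclass
class CleaningReport:
    """Per-rule drop counts; ``input = output + sum(dropped)`` always."""

    n_input: int
    n_output: int
    dropped: dict

    def __post_init__(self):
        assert self.n_input == self.n_output + sum(self.dropped.values())

    def to_json(self, path=None) -> str:
        payload = json.dumps({"input": self.n_input, "output": self.n_output,
                              "dropped": self.dropped}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


@dataclass
class CleaningRules:
    """Configuration of the ordered cleaning rules.

    ``land_mask`` / ``basin_polygon`` are shapely geometries (or None to skip
    the rule).  Depth filtering keeps records whose stated depth values fall
    inside the window; records with no depth information are retained.
    Records with an unparseable/missing date are dropped by the period rule
    when a period is configured.
    """

    depth_window: tuple | None = (0.0, 200.0)
    period: tuple | None = (1993, 2019)
    land_mask: object = None
    basin_polygon: object = None
    require_land_mask: bool = False
    dedup_decimals: int = 4


def read_occurrences(path, column_map=None, sep=",") -> pd.DataFrame:
    """Read a delimited occurrence file into a typed RecordTable.

    Unparseable coordinates, depths and dates become missing values rather
    than errors; a missing scientific-name column is an error.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    rename = {src: dst for src, dst in cmap.items() if src in df.columns}
    df = df.rename(columns=rename)
    if "scientific_name" not in df.columns:
        raise ValueError("no scientific name column found (looked for: "
                         + ", ".join(k for k, v in cmap.items() if v == "scientific_name") + ")")
    for col in ("latitude", "longitude", "depth_min", "depth_max"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = np.nan
    if "event_date" in df.columns:
        df["event_date"] = pd.to_datetime(df["event_date"], errors="coerce")
    else:
        df["event_date"] = pd.NaT
    if "taxon_rank" not in df.columns:
        df["taxon_rank"] = pd.NA
    if "source_id" not in df.columns:
        df["source_id"] = [f"row{i}" for i in range(len(df))]
    return df


def record_table_from_frame(df: pd.DataFrame, column_map=None) -> pd.DataFrame:
    """Like :func:`read_occurrences` but starting from an in-memory frame."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = df.rename(columns={k: v for k, v in cmap.items() if k in df.columns}).copy()
    if "scientific_name" not in out.columns:
        raise ValueError("no scientific name column found")
    for col in ("latitude", "longitude", "depth_min", "depth_max"):
        if col not in out.columns:
            out[col] = np.nan
        out[col] = pd.to_numeric(out[col], errors="coerce")
    if "event_date" not in out.columns:
        out["event_date"] = pd.NaT
    out["event_date"] = pd.to_datetime(out["event_date"], errors="coerce")
    if "taxon_rank" not in out.columns:
        out["taxon_rank"] = pd.NA
    if "source_id" not in out.columns:
        out["source_id"] = [f"row{i}" for i in range(len(out))]
    return out


def _looks_binomial(name) -> bool:
    if not isinstance(name, str):
        return False
    parts = name.strip().split()
    return len(parts) >= 2 and parts[1][:1].islower() and parts[1].isalpha()


def _in_geometry(geom, lon, lat) -> np.ndarray:
    from shapely import points, contains
    pts = points(np.column_stack([lon, lat]))
    return contains(geom, pts)


def clean_records(records: pd.DataFrame, rules: CleaningRules | None = None) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the ordered cleaning rules; return survivors and a report."""
    rules = rules or CleaningRules()
    if rules.require_land_mask and rules.land_mask is None:
        raise ValueError("rule 'on_land' requested but no land mask supplied")
    df = records.reset_index(drop=True)
    n_input = len(df)
    reason = pd.Series("", index=df.index, dtype=object)

    def flag(mask, name):
        mask = mask & (reason == "")
        reason[mask] = name

    lat, lon = df["latitude"], df["longitude"]
    flag(lat.isna() | lon.isna(), "missing_coords")
    flag((lat == 0) & (lon == 0), "zero_coords")
    if rules.land_mask is not None:
        ok = reason == ""
        on_land = np.zeros(len(df), dtype=bool)
        on_land[ok.to_numpy()] = _in_geometry(rules.land_mask, lon[ok].to_numpy(),
                                              lat[ok].to_numpy())
        flag(pd.Series(on_land, index=df.index), "on_land")
    if rules.basin_polygon is not None:
        ok = reason == ""
        inside = np.zeros(len(df), dtype=bool)
        inside[ok.to_numpy()] = _in_geometry(rules.basin_polygon, lon[ok].to_numpy(),
                                             lat[ok].to_numpy())
        flag(pd.Series(~inside, index=df.index) & ok, "outside_basin")

    rank = df["taxon_rank"].astype("string").str.lower()
    has_rank = rank.notna() & (rank != "")
    is_species = pd.Series(False, index=df.index)
    is_species[has_rank] = rank[has_rank] == "species"
    no_rank = ~has_rank
    if no_rank.any():
        heur = df.loc[no_rank, "scientific_name"].map(_looks_binomial)
        is_species[no_rank] = heur
        warnings.warn(f"taxon rank missing for {int(no_rank.sum())} records; "
                      "binomial-name heuristic applied", stacklevel=2)
    flag(~is_species, "non_species_rank")

    if rules.depth_window is not None:
        lo, hi = rules.depth_window
        dmin, dmax = df["depth_min"], df["depth_max"]
        bad = (dmin.notna() & ((dmin < lo) | (dmin > hi))) | \
              (dmax.notna() & ((dmax < lo) | (dmax > hi)))
        flag(bad, "outside_depth")
    if rules.period is not None:
        y0, y1 = rules.period
        yr = df["event_date"].dt.year
        flag(yr.isna() | (yr < y0) | (yr > y1), "outside_period")

    # duplicates are judged among records surviving all previous rules
    d = rules.dedup_decimals
    ok = reason == ""
    sub = df[ok]
    key = pd.MultiIndex.from_arrays([
        sub["scientific_name"],
        sub["latitude"].round(d),
        sub["longitude"].round(d),
        sub["event_date"],
        sub["depth_min"],
        sub["depth_max"],
    ])
    dup = pd.Series(False, index=df.index)
    dup[ok] = key.duplicated(keep="first")
    flag(dup, "duplicate")

    keep = reason == ""
    dropped = {r: int((reason == r).sum()) for r in RULE_ORDER if (reason == r).any()}
    report = CleaningReport(n_input=n_input, n_output=int(keep.sum()), dropped=dropped)
    return df[keep].reset_index(drop=True), report


def load_synonym_table(path) -> dict:
    """Two-column delimited file: name, accepted_name."""
    df = pd.read_csv(path)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def harmonize_taxonomy(records: pd.DataFrame, synonym_table: dict) -> tuple[pd.DataFrame, int]:
    """Replace names by their accepted names, following chains to a fixpoint.

    Returns the harmonized table and the count of names that had no entry in
    the synonym table (passed through unchanged).  Cyclic chains are an
    error.
    """
    resolved = {}

    def resolve(name):
        if name in resolved:
            return resolved[name]
        seen, cur = [name], name
        while cur in synonym_table and synonym_table[cur] != cur:
            cur = synonym_table[cur]
            if cur in seen:
                raise ValueError(f"cyclic synonym chain: {' -> '.join(seen + [cur])}")
            seen.append(cur)
        for s in seen:
            resolved[s] = cur
        return cur

    out = records.copy()
    names = out["scientific_name"]
    out["scientific_name"] = names.map(resolve)
    unmatched = int((~names.isin(synonym_table.keys())).sum())
    return out, unmatched


def assign_cells(records: pd.DataFrame, grid: GridSpec | None = None) -> pd.DataFrame:
    """Attach cell_x/cell_y (SW corners) and cell_id to cleaned records."""
    grid = grid or GridSpec()
    out = records.copy()
    x, y = grid.cell_of(out["longitude"].to_numpy(dtype=float),
                        out["latitude"].to_numpy(dtype=float))
    out["cell_x"] = x
    out["cell_y"] = y
    out["cell_id"] = [cell_id(a, b) for a, b in zip(x, y)]
    return out


@dataclass
class PAM:
    """Presence-absence matrix with occurrence counts, cells x species."""

    cells: list                 # cell_id strings, ordered
    species: list               # species names, ordered
    counts: np.ndarray          # nonnegative ints, len(cells) x len(species)
    cell_size: float = 1.0

    def __post_init__(self):
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell labels")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("negative occurrence counts")

    @property
    def incidence(self) -> np.ndarray:
        return (self.counts > 0).astype(np.int8)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def richness(self) -> np.ndarray:
        return self.incidence.sum(axis=1)

    def cell_coords(self):
        """Cell-center lon/lat arrays derived from the cell ids."""
        xy = np.array([parse_cell_id(c) for c in self.cells], dtype=float)
        return xy[:, 0] + self.cell_size / 2.0, xy[:, 1] + self.cell_size / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.cells, name="cell_id"),
                            columns=self.species)

    def to_wide_csv(self, path):
        self.to_frame().to_csv(path)

    def to_triplets(self, path=None) -> pd.DataFrame:
        r, c = np.nonzero(self.counts)
        trip = pd.DataFrame({"cell_id": [self.cells[i] for i in r],
                             "species": [self.species[j] for j in c],
                             "count": self.counts[r, c]})
        if path is not None:
            trip.to_csv(path, index=False)
        return trip

    def subset_cells(self, keep_mask) -> "PAM":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        counts = self.counts[keep_mask]
        nz = counts.sum(axis=0) > 0
        return PAM(cells=[c for c, k in zip(self.cells, keep_mask) if k],
                   species=[s for s, k in zip(self.species, nz) if k],
                   counts=counts[:, nz], cell_size=self.cell_size)


def build_pam(gridded: pd.DataFrame, cell_size: float = 1.0) -> PAM:
    """Cross-tabulate gridded records into a PAM (all-zero species dropped)."""
    tab = pd.crosstab(gridded["cell_id"], gridded["scientific_name"])
    tab = tab.loc[:, tab.sum(axis=0) > 0]
    return PAM(cells=list(tab.index), species=list(tab.columns),
               counts=tab.to_numpy(), cell_size=cell_size)


def filter_cells(pam: PAM, min_richness: int = 0,
                 excluded_lon_band: tuple | None = None) -> PAM:
    """Keep cells with richness >= min_richness and center lon outside band.

    The band is an inclusive longitude interval given in any order, e.g.
    ``(-110, -170)`` means centers in ``[-170, -110]`` are excluded.
    """
    keep = pam.richness() >= min_richness
    if excluded_lon_band is not None:
        lo, hi = sorted(wrap_lon(np.asarray(excluded_lon_band, dtype=float)))
        lon_c, _ = pam.cell_coords()
        keep &= ~((lon_c >= lo) & (lon_c <= hi))
    if not keep.any():
        warnings.warn("cell filter removed every cell", stacklevel=2)
    return pam.subset_cells(keep)
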