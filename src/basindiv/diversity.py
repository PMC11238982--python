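"""Alpha, Shannon and partitioned beta diversity on a presence-absence matrix.

Pairwise Sorensen dissimilarity is split exactly into a turnover (Simpson)
and a nestedness component:

    beta_sor = (b + c) / (2a + b + c)
    beta_sim = b / (b + a)
    beta_sne = beta_sor - beta_sim

with ``a`` the shared species count and ``b <= c`` the species unique to the
poorer and richer cell.  The identity ``beta_sor = beta_sim + beta_sne``
holds to machine precision by construction; both decomposition terms are
also available in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BetaPair:
    a: int
    b: int
    c: int
    beta_sor: float
    beta_sim: float
    beta_sne: float


def alpha_richness(pam) -> pd.Series:
    """Species count per cell (row sums of the incidence matrix)."""
    return pd.Series(pam.richness(), index=pd.Index(pam.cells, name="cell_id"),
                     name="richness")


def shannon_index(pam) -> pd.Series:
    """Occurrence-based Shannon index H = -sum p_i ln p_i per cell.

    ``p_i`` is the share of the cell's records belonging to species i —
    occurrence counts stand in for abundances.  Cells with no records get a
    missing value, not 0.
    """
    counts = pam.counts.astype(float)
    n = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / n[:, None]
        h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    h = np.where(n > 0, h, np.nan)
    return pd.Series(h, index=pd.Index(pam.cells, name="cell_id"), name="shannon")


def beta_pair(inc_i, inc_j) -> BetaPair:
    """Partitioned dissimilarity between two incidence vectors."""
    xi = np.asarray(inc_i, dtype=bool)
    xj = np.asarray(inc_j, dtype=bool)
    if not xi.any() and not xj.any():
        raise ValueError("beta diversity undefined for two empty cells")
    a = int((xi & xj).sum())
    ui = int((xi & ~xj).sum())
    uj = int((xj & ~xi).sum())
    b, c = min(ui, uj), max(ui, uj)
    sor = (b + c) / (2 * a + b + c)
    sim = b / (b + a) if (b + a) > 0 else 0.0
    return BetaPair(a=a, b=b, c=c, beta_sor=sor, beta_sim=sim, beta_sne=sor - sim)


def beta_matrices(pam) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full pairwise (cells x cells) beta_sor, beta_sim, beta_sne matrices."""
    x = pam.incidence.astype(np.int64)
    a = x @ x.T
    s = x.sum(axis=1)
    u_i = s[:, None] - a
    u_j = s[None, :] - a
    b = np.minimum(u_i, u_j)
    c = np.maximum(u_i, u_j)
    with np.errstate(divide="ignore", invalid="ignore"):
        sor = (b + c) / (2 * a + b + c)
        sim = np.where(b + a > 0, b / (b + a), 0.0)
    np.fill_diagonal(sor, 0.0)
    np.fill_diagonal(sim, 0.0)
    return sor, sim, sor - sim


def beta_per_cell(pam, neighborhood="all-pairs", weights=None):
    """Mean pairwise beta components per focal cell plus grand means.

    ``neighborhood`` is ``"all-pairs"`` (every other cell), ``"queen"``
    (first-order contiguity) or ``("band", d_km)``; for the latter two a
    weights matrix is built from the PAM's cell ids unless ``weights`` (a
    boolean/0-1 adjacency, self excluded) is supplied.  Cells with no
    neighbors come out missing.

    Returns ``(frame, grand_means)`` where the frame has columns
    ``beta_sor/beta_sim/beta_sne`` indexed by cell and ``grand_means`` is a
    dict of across-cell means.
    """
    sor, sim, sne = beta_matrices(pam)
    n = pam.n_cells
    if weights is not None:
        adj = np.asarray(weights, dtype=bool)
    elif neighborhood == "all-pairs":
        adj = ~np.eye(n, dtype=bool)
    else:
        from .spatial import build_weights
        scheme = neighborhood if isinstance(neighborhood, (tuple, list)) else (neighborhood,)
        w = build_weights(pam.cells, scheme=scheme[0],
                          band_km=(scheme[1] if len(scheme) > 1 else None),
                          cell_size=pam.cell_size)
        adj = w.matrix > 0
    np.fill_diagonal(adj, False)

    deg = adj.sum(axis=1)
    out = {}
    for name, mat in (("beta_sor", sor), ("beta_sim", sim), ("beta_sne", sne)):
        with np.errstate(invalid="ignore"):
            mean = np.where(deg > 0, (mat * adj).sum(axis=1) / np.maximum(deg, 1), np.nan)
        out[name] = mean
    frame = pd.DataFrame(out, index=pd.Index(pam.cells, name="cell_id"))
    grand = {k: float(np.nanmean(v)) for k, v in out.items()}
    return frame, grand


def redundancy_index(pam) -> pd.Series:
    """R = 1 - richness/records per cell, clipped to [0, 1]; no records -> missing."""
    s = pam.richness().astype(float)
    n = pam.counts.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.clip(1.0 - s / n, 0.0, 1.0)
    r = np.where(n > 0, r, np.nan)
    return pd.Series(r, index=pd.Index(pam.cells, name="cell_id"), name="redundancy")


def dominant_species(gridded: pd.DataFrame, region_mask=None, k: int = 10) -> pd.DataFrame:
    """Top-k species by occurrence count inside a region (ties alphabetical).

    ``region_mask`` is a shapely geometry tested against record coordinates,
    a collection of cell_id strings, or None for the full table.
    """
    df = gridded
    if region_mask is not None:
        if hasattr(region_mask, "geom_type"):
            from shapely import contains, points
            pts = points(np.column_stack([df["longitude"].to_numpy(dtype=float),
                                          df["latitude"].to_numpy(dtype=float)]))
            df = df[contains(region_mask, pts)]
        else:
            df = df[df["cell_id"].isin(set(region_mask))]
    counts = df.groupby("scientific_name").size().reset_index(name="count")
    counts = counts.sort_values(["count", "scientific_name"],
                                ascending=[False, True], kind="stable")
    counts["rank"] = np.arange(1, len(counts) + 1)
    return counts.head(k).reset_index(drop=True)


def dominant_by_stat_range(pam, stat: pd.Series, n_bins: int = 4) -> list:
    """Species present in every occupied bin of a per-cell statistic.

    Cells are split into ``n_bins`` equal-width intervals of the statistic
    (rightmost edge closed); a species qualifies if it occurs in at least one
    cell of every bin that contains cells.  Deterministic stand-in for
    picking 'species occurring across all ranges' off a matrix plot.
    """
    v = stat.reindex(pam.cells).to_numpy(dtype=float)
    if np.isnan(v).any():
        warnings.warn("cells with missing statistic are ignored in binning", stacklevel=2)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        bins = np.zeros(len(v), dtype=int)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.clip(np.digitize(v, edges[1:-1], right=False), 0, n_bins - 1)
    bins = np.where(np.isnan(v), -1, bins)
    inc = pam.incidence
    selected = None
    for bval in np.unique(bins[bins >= 0]):
        present = set(np.nonzero(inc[bins == bval].sum(axis=0) > 0)[0])
        selected = present if selected is None else (selected & present)
    if not selected:
        return []
    return sorted(pam.species[j] for j in selected)
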