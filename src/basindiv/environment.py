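"""Per-cell environmental predictor construction.

Builds the modelling table from gridded variable stacks: depth/period
averaging, fine-to-coarse block-mean resampling, temperature deviation and
stability, z-standardization and the Spearman association matrix.

Conventions fixed here and relied on elsewhere: sample standard deviation
(``ddof=1``) throughout, including the two-point SD between paired time
slices; all means are missing-aware.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

ENV_COLUMNS = ("T_mean", "S", "Chla", "O2", "MLD", "T_sd", "T_stab")


def aggregate_mean(long_frame: pd.DataFrame, depth_range=None, period=None) -> pd.DataFrame:
    """Average a long-format stack (cell_id, lon, lat, [depth,] time, variable, value)
    over the selected depth range and period, one column per variable.

    Cells with no data for a variable come out missing.
    """
    df = long_frame
    if depth_range is not None and "depth" in df.columns:
        lo, hi = depth_range
        df = df[(df["depth"] >= lo) & (df["depth"] <= hi)]
    if period is not None and "time" in df.columns:
        y0, y1 = period
        df = df[(df["time"] >= y0) & (df["time"] <= y1)]
    keys = [k for k in ("cell_id", "lon", "lat") if k in df.columns]
    out = (df.groupby(keys + ["variable"], sort=False)["value"]
             .mean().unstack("variable").reset_index())
    out.columns.name = None
    return out


def resample_block_mean(fine: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a 2-D field by an integer factor (missing-aware).

    A 0.25-degree field becomes 1-degree with ``factor=4``; each coarse value
    is the mean of the non-missing fine values it covers.
    """
    fine = np.asarray(fine, dtype=float)
    ny, nx = fine.shape
    if ny % factor or nx % factor:
        raise ValueError("field shape must be divisible by the resampling factor")
    blocks = fine.reshape(ny // factor, factor, nx // factor, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        return np.nanmean(blocks, axis=(1, 3))


def temperature_deviation_stability(t_slices: np.ndarray, years,
                                    lag_years: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell temperature deviation and stability from a slice stack.

    Slices (first axis, ordered in time, ``years`` giving their timestamps)
    are grouped into consecutive ``lag_years``-long windows and averaged;
    for each adjacent window pair the per-cell two-point sample SD is divided
    by the elapsed years between window starts.  The deviation field is the
    mean of these ratios over all pairs; stability is the inverse deviation
    rescaled by its maximum so the most stable cell is exactly 1 (cells with
    zero deviation are set to 1 before inversion).
    """
    t_slices = np.asarray(t_slices, dtype=float)
    years = np.asarray(years)
    if t_slices.shape[0] != len(years):
        raise ValueError("one timestamp per slice required")
    if t_slices.shape[0] < 2:
        raise ValueError("need at least two time slices")
    order = np.argsort(years)
    t_slices, years = t_slices[order], years[order]

    # consecutive lag-year windows, averaged
    window_idx = (years - years[0]) // lag_years
    win_means, win_starts = [], []
    for w in np.unique(window_idx):
        sel = window_idx == w
        win_means.append(t_slices[sel].mean(axis=0))
        win_starts.append(years[sel].min())
    if len(win_means) < 2:
        # fall back to slice-by-slice pairs when all slices share one window
        win_means, win_starts = list(t_slices), list(years)
    pair_devs = []
    for a in range(len(win_means) - 1):
        elapsed = max(float(win_starts[a + 1] - win_starts[a]), 1e-12)
        # sample SD of two points = |x1 - x2| / sqrt(2)
        sd = np.abs(win_means[a + 1] - win_means[a]) / np.sqrt(2.0)
        pair_devs.append(sd / elapsed)
    t_sd = np.mean(pair_devs, axis=0)

    t_stab = np.ones_like(t_sd)
    pos = t_sd > 0
    if pos.any():
        inv = np.zeros_like(t_sd)
        inv[pos] = 1.0 / t_sd[pos]
        m = inv[pos].max()
        t_stab[pos] = inv[pos] / m
    return t_sd, t_stab


def standardize(env_table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Z-score each predictor over its non-missing cells (sample SD).

    Idempotent within floating-point noise; a zero-variance column is an
    error naming the variable.  Sets ``attrs['standardized'] = True``.
    """
    out = env_table.copy()
    cols = [c for c in (columns or ENV_COLUMNS) if c in out.columns]
    for c in cols:
        x = out[c].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero-variance predictor: {c}")
        out[c] = (x - x.mean()) / sd
    out.attrs["standardized"] = True
    return out


def spearman_matrix(env_table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pairwise-complete Spearman rank correlations (average ranks for ties)."""
    cols = [c for c in (columns or ENV_COLUMNS) if c in env_table.columns]
    return env_table[cols].corr(method="spearman")


def env_table_from_stack(stack, depth_range=None, period=None,
                         lag_years: int = 2) -> pd.DataFrame:
    """Full predictor table from a synthetic :class:`~basindiv.synthetic.EnvStack`:
    per-cell means of the five base variables plus temperature deviation and
    stability."""
    from .grid import cell_id as _cid

    table = aggregate_mean(stack.to_frame(), depth_range=depth_range, period=period)
    t_sd, t_stab = temperature_deviation_stability(
        stack.fields["T_mean"].reshape(stack.n_slices, -1), stack.years, lag_years=lag_years)
    gx, gy = stack.grid.cell_corners()
    aux = pd.DataFrame({"cell_id": [_cid(x, y) for x, y in zip(gx, gy)],
                        "T_sd": t_sd, "T_stab": t_stab})
    return table.merge(aux, on="cell_id")
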