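"""Spatial weights, Moran's I, Getis-Ord G* and interpolation on the grid.

Weights are queen contiguity on the integer cell lattice (with the
antimeridian treated as adjacent) or a great-circle distance band between
cell centers.  G* uses binary contiguity *including self*; Moran's I and the
residual autocovariate exclude self.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import great_circle_km, parse_cell_id, wrap_lon

GSTAR_CLASSES = (
    (2.58, "hot99"), (1.96, "hot95"), (1.65, "hot90"),
)


@dataclass
class WeightsMatrix:
    cells: list
    matrix: np.ndarray          # dense, n x n
    scheme: str
    include_self: bool = False
    row_standardized: bool = False

    @property
    def n(self) -> int:
        return len(self.cells)

    def neighbors(self, i: int) -> np.ndarray:
        m = self.matrix[i].copy()
        if self.include_self:
            m[i] = 0
        return np.nonzero(m)[0]

    def row_standardize(self) -> "WeightsMatrix":
        w = self.matrix.astype(float).copy()
        rs = w.sum(axis=1)
        nz = rs > 0
        w[nz] = w[nz] / rs[nz, None]
        return WeightsMatrix(cells=self.cells, matrix=w, scheme=self.scheme,
                             include_self=self.include_self, row_standardized=True)


def build_weights(cells, scheme: str = "queen", include_self: bool = False,
                  row_standardize: bool = False, band_km: float | None = None,
                  cell_size: float = 1.0) -> WeightsMatrix:
    """Binary spatial weights between grid cells.

    ``scheme`` is ``"queen"`` (8-neighbour contiguity, dateline-wrapped) or
    ``"band"`` with ``band_km`` a great-circle radius between cell centers.
    Isolated cells are flagged with a warning.
    """
    cells = list(cells)
    xy = np.array([parse_cell_id(c) for c in cells], dtype=float)
    n = len(cells)
    if scheme == "queen":
        dx = np.abs(wrap_lon(xy[:, 0][:, None] - xy[:, 0][None, :]))
        dy = np.abs(xy[:, 1][:, None] - xy[:, 1][None, :])
        tol = 1e-9
        adj = (dx <= cell_size + tol) & (dy <= cell_size + tol)
        np.fill_diagonal(adj, False)
        w = adj.astype(float)
    elif scheme == "band":
        if band_km is None:
            raise ValueError("band scheme needs band_km")
        cx = xy[:, 0] + cell_size / 2.0
        cy = xy[:, 1] + cell_size / 2.0
        d = great_circle_km(cx[:, None], cy[:, None], cx[None, :], cy[None, :])
        w = ((d <= band_km) & ~np.eye(n, dtype=bool)).astype(float)
    else:
        raise ValueError(f"unknown weights scheme: {scheme}")

    isolated = int((w.sum(axis=1) == 0).sum())
    if isolated:
        warnings.warn(f"{isolated} cells have no neighbors", stacklevel=2)
    if include_self:
        w = w + np.eye(n)
    wm = WeightsMatrix(cells=cells, matrix=w, scheme=scheme, include_self=include_self)
    if row_standardize:
        wm = wm.row_standardize()
    return wm


@dataclass
class MoranResult:
    i: float
    expected: float
    z: float
    p_analytic: float
    p_perm: float | None
    n_perm: int


def morans_i(values, weights: WeightsMatrix, n_perm: int = 999,
             seed: int | None = None) -> MoranResult:
    """Global Moran's I with analytic (normality) and permutation inference.

    The permutation p-value is one-sided in the direction of the observed
    departure from E[I] = -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    w = weights.matrix.astype(float).copy()
    np.fill_diagonal(w, 0.0)
    ok = ~np.isnan(x)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing cells")
    x = x[ok]
    w = w[np.ix_(ok, ok)]
    z = x - x.mean()
    s2 = (z ** 2).sum()
    if s2 == 0:
        raise ValueError("zero variance")
    n = len(x)
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("empty weights")

    def stat(zv):
        return (n / s0) * (zv @ w @ zv) / (zv ** 2).sum()

    i_obs = stat(z)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2s = ((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum()
    var = (n * n * s1 - n * s2s + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i ** 2
    from scipy import stats
    zscore = (i_obs - e_i) / np.sqrt(var) if var > 0 else np.nan
    p_analytic = float(2 * stats.norm.sf(abs(zscore))) if np.isfinite(zscore) else np.nan

    p_perm = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        sims = np.empty(n_perm)
        for k in range(n_perm):
            sims[k] = stat(rng.permutation(z))
        if i_obs >= e_i:
            p_perm = float((1 + (sims >= i_obs).sum()) / (n_perm + 1))
        else:
            p_perm = float((1 + (sims <= i_obs).sum()) / (n_perm + 1))
    return MoranResult(i=float(i_obs), expected=e_i, z=float(zscore),
                       p_analytic=p_analytic, p_perm=p_perm, n_perm=n_perm or 0)


def getis_ord_gstar(values, weights: WeightsMatrix) -> pd.DataFrame:
    """Getis-Ord G* z-scores and hot/cold classes per cell.

    ``weights`` must include self (standard G*).  Classes follow the usual
    1.65 / 1.96 / 2.58 |z| thresholds.
    """
    if not weights.include_self:
        raise ValueError("G* requires weights that include self")
    x = np.asarray(values, dtype=float)
    w = weights.matrix.astype(float)
    n = len(x)
    xbar = x.mean()
    s = np.sqrt((x ** 2).mean() - xbar ** 2)
    if s == 0:
        # a uniform field carries no clustering signal at all
        warnings.warn("zero variance: all G* z-scores are 0", stacklevel=2)
        return pd.DataFrame({"cell_id": list(weights.cells),
                             "z": np.zeros(n),
                             "class": ["not significant"] * n})
    wsum = w.sum(axis=1)
    w2sum = (w ** 2).sum(axis=1)
    num = w @ x - xbar * wsum
    den = s * np.sqrt((n * w2sum - wsum ** 2) / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(den > 0, num / den, 0.0)

    cls = np.full(n, "not significant", dtype=object)
    for thr, label in GSTAR_CLASSES:
        cls[(z >= thr) & (cls == "not significant")] = label
    for thr, label in GSTAR_CLASSES:
        cold = label.replace("hot", "cold")
        cls[(z <= -thr) & (cls == "not significant")] = cold
    return pd.DataFrame({"cell_id": list(weights.cells), "z": z, "class": cls})


def idw(sample_lon, sample_lat, sample_values, target_lon, target_lat,
        power: float = 2.0, max_dist_km: float | None = None) -> np.ndarray:
    """Inverse-distance-weighted interpolation on the sphere.

    Exact at sample locations; predictions are clamped to the range of the
    input values.  Targets with no sample within ``max_dist_km`` are missing.
    """
    sv = np.asarray(sample_values, dtype=float)
    d = great_circle_km(np.asarray(target_lon, dtype=float)[:, None],
                        np.asarray(target_lat, dtype=float)[:, None],
                        np.asarray(sample_lon, dtype=float)[None, :],
                        np.asarray(sample_lat, dtype=float)[None, :])
    out = np.empty(d.shape[0])
    for t in range(d.shape[0]):
        dt = d[t]
        if max_dist_km is not None:
            use = dt <= max_dist_km
        else:
            use = np.ones_like(dt, dtype=bool)
        if not use.any():
            out[t] = np.nan
            continue
        exact = use & (dt <= 1e-9)
        if exact.any():
            out[t] = sv[exact][0]
            continue
        wgt = dt[use] ** (-power)
        out[t] = (wgt * sv[use]).sum() / wgt.sum()
    return np.clip(out, np.nanmin(sv), np.nanmax(sv))


def _variogram_model(name):
    if name == "spherical":
        def g(h, nugget, sill, rng_):
            h = np.asarray(h, dtype=float)
            inside = nugget + (sill - nugget) * (1.5 * h / rng_ - 0.5 * (h / rng_) ** 3)
            return np.where(h <= 0, 0.0, np.where(h < rng_, inside, sill))
    elif name == "exponential":
        def g(h, nugget, sill, rng_):
            h = np.asarray(h, dtype=float)
            return np.where(h <= 0, 0.0, nugget + (sill - nugget) * (1 - np.exp(-3.0 * h / rng_)))
    else:
        raise ValueError(f"unknown variogram model: {name}")
    return g


def fit_variogram(sample_lon, sample_lat, values, model: str = "spherical",
                  n_bins: int = 12):
    """Least-squares fit of a variogram model to the empirical semivariogram."""
    from scipy.optimize import curve_fit

    lon = np.asarray(sample_lon, dtype=float)
    lat = np.asarray(sample_lat, dtype=float)
    v = np.asarray(values, dtype=float)
    d = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    iu = np.triu_indices(len(v), k=1)
    h = d[iu]
    gamma = 0.5 * (v[iu[0]] - v[iu[1]]) ** 2
    edges = np.linspace(0, h.max(), n_bins + 1)
    hb, gb = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (h > a) & (h <= b)
        if sel.any():
            hb.append(h[sel].mean())
            gb.append(gamma[sel].mean())
    hb, gb = np.asarray(hb), np.asarray(gb)
    g = _variogram_model(model)
    sill0 = max(v.var(), 1e-12)
    try:
        popt, _ = curve_fit(g, hb, gb, p0=[0.0, sill0, h.max() / 2],
                            bounds=([0, 1e-12, 1e-6], [sill0 * 10 + 1, sill0 * 100 + 1, h.max() * 10]),
                            maxfev=5000)
    except RuntimeError:
        popt = (0.0, sill0, h.max() / 2)
    return model, tuple(float(p) for p in popt)


def ordinary_kriging(sample_lon, sample_lat, sample_values, target_lon, target_lat,
                     model: str = "spherical", params: tuple | None = None,
                     clamp: bool = False):
    """Ordinary kriging with a fitted or supplied variogram.

    Solves the standard system with a Lagrange multiplier per target; with a
    zero nugget it interpolates sample points exactly with zero variance.
    Duplicate sample locations make the system singular and raise.

    Returns ``(predictions, variances, (model, params))``.
    """
    lon = np.asarray(sample_lon, dtype=float)
    lat = np.asarray(sample_lat, dtype=float)
    v = np.asarray(sample_values, dtype=float)
    m = len(v)
    if m < 5:
        raise ValueError("need at least 5 samples")
    d = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    off_diag = d[~np.eye(m, dtype=bool)]
    if (off_diag <= 1e-9).any():
        raise ValueError("duplicate sample locations make the kriging system singular")
    if params is None:
        model, params = fit_variogram(lon, lat, v, model=model)
    g = _variogram_model(model)
    gamma = g(d, *params)
    np.fill_diagonal(gamma, 0.0)
    A = np.empty((m + 1, m + 1))
    A[:m, :m] = gamma
    A[m, :m] = 1.0
    A[:m, m] = 1.0
    A[m, m] = 0.0
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular kriging system") from exc

    tlon = np.asarray(target_lon, dtype=float)
    tlat = np.asarray(target_lat, dtype=float)
    d0 = great_circle_km(tlon[:, None], tlat[:, None], lon[None, :], lat[None, :])
    preds = np.empty(len(tlon))
    variances = np.empty(len(tlon))
    for t in range(len(tlon)):
        b = np.empty(m + 1)
        b[:m] = g(d0[t], *params)
        b[m] = 1.0
        sol = A_inv @ b
        lam, mu = sol[:m], sol[m]
        preds[t] = lam @ v
        variances[t] = max(float(lam @ b[:m] + mu), 0.0)
        exact = d0[t] <= 1e-9
        if exact.any() and params[0] == 0:
            preds[t] = v[exact][0]
            variances[t] = 0.0
    if clamp:
        preds = np.clip(preds, v.min(), v.max())
    return preds, variances, (model, params)
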