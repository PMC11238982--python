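"""Generalized dissimilarity modelling.

Site-pair compositional dissimilarity ``d`` in [0, 1] is regressed on
environmental contrasts through monotone I-spline transforms with a
saturating negative-exponential link:

    eta = intercept + sum_p |f_p(x_p_i) - f_p(x_p_j)|
    d_hat = 1 - exp(-eta)

Each ``f_p`` is a nonnegative combination of order-2 I-spline basis
functions with knots at the predictor's min/median/max, so every fitted
transform is nondecreasing and ``d_hat`` is nondecreasing in each
environmental contrast.  Coefficients are estimated by iteratively
reweighted nonnegative least squares against a binomial-type deviance.

The per-predictor importance is the total rise of its transform (the sum of
its spline coefficients); composition maps come from a PCA of the
transformed predictor table with the first three axes rescaled to RGB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .diversity import beta_matrices

_EPS = 1e-9


def ispline_basis(x, knots) -> np.ndarray:
    """Order-2 I-spline basis values, one column per basis function.

    With knots ``(q1, q2, q3)`` the three basis functions rise monotonically
    from 0 at ``q1`` to 1 at ``q3``; values outside the knot range are held
    at 0/1.
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    triples = [(knots[0], knots[0], knots[1]),
               (knots[0], knots[1], knots[2]),
               (knots[1], knots[2], knots[2])]
    cols = [_ispline_one(x, a, b, c) for a, b, c in triples]
    return np.column_stack(cols)


def _ispline_one(x, a, b, c) -> np.ndarray:
    """One quadratic I-spline piece on knot triple ``a <= b <= c``."""
    out = np.zeros_like(x, dtype=float)
    if c <= a:  # degenerate predictor with zero range
        return np.where(x >= c, 1.0, 0.0)
    out[x >= c] = 1.0
    if b > a:
        seg = (x > a) & (x <= b)
        out[seg] = (x[seg] - a) ** 2 / ((c - a) * (b - a))
    if c > b:
        seg = (x > b) & (x < c)
        out[seg] = 1.0 - (c - x[seg]) ** 2 / ((c - a) * (c - b))
    return out


def default_knots(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.array([np.min(x), np.median(x), np.max(x)])


@dataclass
class GdmFit:
    predictors: list
    knots: dict                   # predictor -> 3 knot locations
    coefs: dict                   # predictor -> 3 nonnegative spline coefficients
    intercept: float
    deviance_explained: float     # percent
    fitted: np.ndarray
    observed: np.ndarray
    n_iter: int

    def transform(self, name: str, x) -> np.ndarray:
        """Fitted monotone transform f_p evaluated at x."""
        return ispline_basis(x, self.knots[name]) @ self.coefs[name]

    def importance(self) -> pd.Series:
        """Total rise of each fitted transform (max spline height)."""
        return pd.Series({p: float(np.sum(self.coefs[p])) for p in self.predictors},
                         name="height")

    def to_json_dict(self) -> dict:
        return {"intercept": self.intercept,
                "deviance_explained": self.deviance_explained,
                "predictors": {p: {"knots": list(self.knots[p]),
                                   "coefficients": list(self.coefs[p])}
                               for p in self.predictors}}


def build_site_pairs(pam, env_table: pd.DataFrame, predictors,
                     response: str = "sor", max_pairs: int = 50000,
                     seed: int | None = None) -> pd.DataFrame:
    """Site-pair table: dissimilarity plus predictor values at both sites.

    All unordered cell pairs, or a seeded random subsample of ``max_pairs``.
    ``response`` is ``"sor"`` (Sorensen) or ``"sim"`` (Simpson turnover).
    """
    env = env_table.set_index("cell_id").loc[list(pam.cells)]
    sor, sim, _ = beta_matrices(pam)
    mat = {"sor": sor, "sim": sim}[response]
    iu = np.triu_indices(pam.n_cells, k=1)
    rows = pd.DataFrame({"cell_i": [pam.cells[i] for i in iu[0]],
                         "cell_j": [pam.cells[j] for j in iu[1]],
                         "dissimilarity": mat[iu]})
    for p in predictors:
        v = env[p].to_numpy(dtype=float)
        rows[f"{p}_i"] = v[iu[0]]
        rows[f"{p}_j"] = v[iu[1]]
    if len(rows) > max_pairs:
        rng = np.random.default_rng(seed)
        rows = rows.iloc[np.sort(rng.choice(len(rows), max_pairs, replace=False))]
        rows = rows.reset_index(drop=True)
    return rows


def _binomial_deviance(d, mu) -> float:
    d = np.clip(d, 0.0, 1.0)
    mu = np.clip(mu, _EPS, 1.0 - _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(d > 0, d * np.log(d / mu), 0.0)
        t2 = np.where(d < 1, (1.0 - d) * np.log((1.0 - d) / (1.0 - mu)), 0.0)
    return float(2.0 * (t1 + t2).sum())


def fit_gdm(pairs: pd.DataFrame, predictors, max_iter: int = 100,
            tol: float = 1e-6) -> GdmFit:
    """Fit the monotone dissimilarity model by IRLS over nonnegative least
    squares.

    Raises on non-convergence with the coefficient-change trace attached.
    """
    if len(pairs) < 30:
        raise ValueError("need at least 30 site pairs")
    predictors = list(predictors)
    if not predictors:
        raise ValueError("need at least one predictor")
    d = pairs["dissimilarity"].to_numpy(dtype=float)

    knots, columns = {}, []
    for p in predictors:
        both = np.concatenate([pairs[f"{p}_i"], pairs[f"{p}_j"]])
        knots[p] = default_knots(both)
        bi = ispline_basis(pairs[f"{p}_i"].to_numpy(dtype=float), knots[p])
        bj = ispline_basis(pairs[f"{p}_j"].to_numpy(dtype=float), knots[p])
        columns.append(np.abs(bi - bj))
    design = np.column_stack([np.ones(len(d))] + columns)

    if np.allclose(d, 0.0):
        coef = np.zeros(design.shape[1])
        return _make_fit(predictors, knots, coef, d, np.zeros_like(d), 0)

    # IRLS with binomial variance under the negative-exponential link
    coef = np.zeros(design.shape[1])
    coef[0] = -np.log1p(-np.clip(d.mean(), _EPS, 1 - _EPS))
    trace = []
    for it in range(1, max_iter + 1):
        eta = design @ coef
        mu = 1.0 - np.exp(-eta)
        mu = np.clip(mu, _EPS, 1.0 - _EPS)
        dmu_deta = 1.0 - mu                      # d(1 - e^-eta)/deta = e^-eta
        var = mu * (1.0 - mu)
        w = dmu_deta ** 2 / np.maximum(var, _EPS)
        z = eta + (d - mu) / np.maximum(dmu_deta, _EPS)
        sw = np.sqrt(w)
        new_coef, _ = nnls(design * sw[:, None], z * sw)
        delta = float(np.max(np.abs(new_coef - coef)))
        trace.append(delta)
        coef = new_coef
        if delta < tol:
            return _make_fit(predictors, knots, coef, d,
                             1.0 - np.exp(-(design @ coef)), it)
    raise RuntimeError(f"GDM did not converge in {max_iter} iterations; "
                       f"coefficient-change trace: {trace[-5:]}")


def _make_fit(predictors, knots, coef, d, fitted, n_iter) -> GdmFit:
    coefs = {}
    for k, p in enumerate(predictors):
        coefs[p] = coef[1 + 3 * k: 4 + 3 * k]
    dev = _binomial_deviance(d, fitted)
    null = _binomial_deviance(d, np.full_like(d, np.clip(d.mean(), _EPS, 1 - _EPS)))
    expl = 100.0 * (1.0 - dev / null) if null > 0 else 100.0
    return GdmFit(predictors=list(predictors), knots=knots, coefs=coefs,
                  intercept=float(coef[0]),
                  deviance_explained=float(np.clip(expl, 0.0, 100.0)),
                  fitted=fitted, observed=d, n_iter=n_iter)


def predictor_importance(fit: GdmFit) -> pd.Series:
    """Max spline height per predictor; zero-height predictors should be
    dropped from mapping."""
    return fit.importance()


def transform_and_map(fit: GdmFit, env_table: pd.DataFrame) -> pd.DataFrame:
    """PCA/RGB composition map from the fitted transforms.

    Height-0 predictors are dropped; the first three principal component
    scores of the transformed cell x predictor matrix are min-max scaled to
    0..255.  Axes are sign-fixed by making the loading of the first retained
    predictor positive.  Fewer than 3 retained predictors pad the missing
    channels with zeros.
    """
    heights = fit.importance()
    retained = [p for p in fit.predictors if heights[p] > 0]
    if not retained:
        raise ValueError("no predictor has positive spline height")
    if len(retained) < 3:
        warnings.warn("fewer than 3 predictors retained; padding RGB channels "
                      "with zeros", stacklevel=2)
    T = np.column_stack([fit.transform(p, env_table[p].to_numpy(dtype=float))
                         for p in retained])
    Tc = T - T.mean(axis=0)
    u, s, vt = np.linalg.svd(Tc, full_matrices=False)
    # sign convention: loading of the first retained predictor positive
    for k in range(vt.shape[0]):
        if vt[k, 0] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u * s
    rgb = np.zeros((len(env_table), 3))
    for ch in range(min(3, scores.shape[1])):
        col = scores[:, ch]
        span = col.max() - col.min()
        rgb[:, ch] = 0.0 if span == 0 else (col - col.min()) / span * 255.0
    out = env_table[["cell_id"]].copy()
    for c in ("lon", "lat"):
        if c in env_table.columns:
            out[c] = env_table[c]
    out[["R", "G", "B"]] = np.round(rgb).astype(int)
    return out


def pca_scores(matrix: np.ndarray) -> np.ndarray:
    """Centered PCA scores via SVD (used as an independent check target)."""
    x = np.asarray(matrix, dtype=float)
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    return u * s
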