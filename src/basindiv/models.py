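"""Predictive modelling: variable selection, GAMs, residual autocovariates,
and BIC-based model comparison.

The GAM backend is statsmodels' penalized B-spline ``GLMGam``; BIC is
computed from the log-likelihood with the *effective* degrees of freedom of
the penalized smooths, ``BIC = -2 llf + edf * log(n)``.  The default
smoothing penalty is fixed (predictors are standardized); data-driven
penalty selection is available via ``select_penalty=True`` but is markedly
slower.

The residual autocovariate (RAC) is the row-standardized neighborhood mean
of the residuals of a base fit, added back as a linear predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .spatial import WeightsMatrix, MoranResult, morans_i

EVIDENCE_BINS = ((2.0, "not worth more than a mention"), (6.0, "positive"),
                 (10.0, "strong"), (np.inf, "very strong"))


# ---------------------------------------------------------------------------
# random-forest two-stage variable selection


@dataclass
class SelectionResult:
    ranking: pd.DataFrame          # variable, importance_mean, importance_sd
    threshold: float
    survivors: list
    selected: list
    oob_errors: list               # (k, mean_error, se) per nested model

    def __post_init__(self):
        ranked = list(self.ranking["variable"])
        assert set(self.selected) <= set(self.survivors) <= set(ranked)


def rf_select(X: pd.DataFrame, y, n_trees: int = 100, n_runs: int = 3,
              seed: int = 0, n_permute: int = 5) -> SelectionResult:
    """Two-stage random-forest variable selection.

    Stage 1 ranks variables by permutation importance averaged over
    ``n_runs`` forests and discards those whose mean importance falls below
    the mean importance-SD of the lower half of the ranking.  Stage 2 fits
    nested forests over the survivors in rank order and keeps the smallest
    set whose out-of-bag MSE is within one standard error of the minimum.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.inspection import permutation_importance

    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate predictors")
    y = np.asarray(y, dtype=float)
    cols = list(X.columns)
    Xa = X.to_numpy()
    n = len(y)
    imps = np.zeros((n_runs, len(cols)))
    split_rng = np.random.default_rng(seed)
    for r in range(n_runs):
        # held-out importance so pure-noise predictors score ~0, not inflated
        perm = split_rng.permutation(n)
        cut = min(max(int(0.7 * n), 1), n - 1)
        tr, va = perm[:cut], perm[cut:]
        rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed + r,
                                   n_jobs=1)
        rf.fit(Xa[tr], y[tr])
        pi = permutation_importance(rf, Xa[va], y[va], n_repeats=n_permute,
                                    random_state=seed + 1000 + r, n_jobs=1)
        imps[r] = pi.importances_mean
    mean_imp = imps.mean(axis=0)
    sd_imp = imps.std(axis=0, ddof=1) if n_runs > 1 else np.zeros(len(cols))
    order = np.argsort(mean_imp)[::-1]
    ranking = pd.DataFrame({"variable": [cols[i] for i in order],
                            "importance_mean": mean_imp[order],
                            "importance_sd": sd_imp[order]})
    lower_half = max(1, len(cols) // 2)
    threshold = float(ranking["importance_sd"].tail(lower_half).mean())
    survivors = list(ranking.loc[ranking["importance_mean"] > threshold, "variable"])

    oob_errors = []
    selected = []
    if survivors:
        errs = []
        for k in range(1, len(survivors) + 1):
            sub = X[survivors[:k]].to_numpy()
            run_err = []
            for r in range(n_runs):
                rf = RandomForestRegressor(n_estimators=n_trees, oob_score=True,
                                           random_state=seed + 2000 + r, n_jobs=1,
                                           bootstrap=True)
                rf.fit(sub, y)
                run_err.append(float(np.mean((y - rf.oob_prediction_) ** 2)))
            mean_err = float(np.mean(run_err))
            se = float(np.std(run_err, ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else 0.0
            errs.append(mean_err)
            oob_errors.append((k, mean_err, se))
        best_k = int(np.argmin(errs))
        cutoff = errs[best_k] + oob_errors[best_k][2]
        k_sel = next(k for k, e, _ in oob_errors if e <= cutoff)
        selected = survivors[:k_sel]
    return SelectionResult(ranking=ranking, threshold=threshold,
                           survivors=survivors, selected=selected,
                           oob_errors=oob_errors)


# ---------------------------------------------------------------------------
# GAM fitting


@dataclass
class GamFit:
    response_name: str
    predictors: list
    linear_terms: list
    family: str
    fitted: np.ndarray
    residuals: np.ndarray
    edf: float
    bic: float
    adj_r2: float
    has_rac: bool
    n: int
    result: object = field(repr=False, default=None)


def _check_rank(X: pd.DataFrame):
    cols = list(X.columns)
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(arr)), arr])) <= arr.shape[1]:
        corr = np.corrcoef(arr, rowvar=False)
        worst = "unknown pair"
        if corr.ndim == 2:
            iu = np.triu_indices(len(cols), k=1)
            j = np.argmax(np.abs(corr[iu]))
            worst = f"{cols[iu[0][j]]} ~ {cols[iu[1][j]]}"
        raise ValueError(f"rank-deficient design; collinear predictors: {worst}")


def _family(name: str):
    return {"gaussian": sm.families.Gaussian(),
            "poisson": sm.families.Poisson()}[name]


def fit_gam(y, X: pd.DataFrame, family: str = "gaussian", basis_size: int = 6,
            alpha: float = 1.0, linear_terms=(), select_penalty: bool = False,
            response_name: str = "y", has_rac: bool = False) -> GamFit:
    """Additive penalized-spline model via statsmodels ``GLMGam``.

    Columns listed in ``linear_terms`` enter linearly; everything else gets a
    cubic B-spline smooth with ``basis_size`` basis functions and penalty
    ``alpha`` (or a GCV-selected penalty with ``select_penalty=True``).
    With no smooth columns a plain GLM is fitted.
    """
    from statsmodels.gam.api import BSplines, GLMGam

    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 30:
        raise ValueError("need at least 30 observations")
    _check_rank(X)
    smooth_cols = [c for c in X.columns if c not in linear_terms]
    lin_cols = [c for c in X.columns if c in linear_terms]
    exog = sm.add_constant(X[lin_cols].to_numpy(dtype=float)) if lin_cols \
        else np.ones((n, 1))

    fam = _family(family)
    if np.ptp(y) == 0:
        # constant response: degenerate exact fit (unit-scale BIC convention)
        fitted = np.full(n, y.mean())
        llf = -0.5 * n * np.log(2 * np.pi)
        return GamFit(response_name=response_name, predictors=list(X.columns),
                      linear_terms=list(lin_cols), family=family, fitted=fitted,
                      residuals=y - fitted, edf=1.0,
                      bic=float(-2 * llf + np.log(n)), adj_r2=0.0,
                      has_rac=has_rac, n=n, result=None)
    if smooth_cols:
        bs = BSplines(X[smooth_cols].to_numpy(dtype=float),
                      df=[basis_size] * len(smooth_cols),
                      degree=[3] * len(smooth_cols))
        mod = GLMGam(y, exog=exog, smoother=bs,
                     alpha=[alpha] * len(smooth_cols), family=fam)
        if select_penalty:
            try:
                alphas = mod.select_penweight()[0]
                mod = GLMGam(y, exog=exog, smoother=bs, alpha=alphas, family=fam)
            except Exception:  # penalty search can fail on degenerate fits
                warnings.warn("penalty selection failed; using fixed alpha",
                              stacklevel=2)
        res = mod.fit()
        edf = float(np.sum(res.edf))
    else:
        res = sm.GLM(y, exog, family=fam).fit()
        edf = float(exog.shape[1])
    fitted = np.asarray(res.fittedvalues, dtype=float)
    resid = y - fitted
    bic = float(-2.0 * res.llf + edf * np.log(n))

    if family == "gaussian":
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else 0.0
        denom = max(n - edf - 1.0, 1.0)
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1.0) / denom
    else:
        null = sm.GLM(y, np.ones((n, 1)), family=fam).fit()
        d_ratio = res.deviance / null.deviance if null.deviance > 0 else 0.0
        adj_r2 = 1.0 - d_ratio * (n - 1.0) / max(n - edf, 1.0)
    return GamFit(response_name=response_name, predictors=list(X.columns),
                  linear_terms=list(lin_cols), family=family, fitted=fitted,
                  residuals=resid, edf=edf, bic=bic, adj_r2=float(adj_r2),
                  has_rac=has_rac, n=n, result=res)


# ---------------------------------------------------------------------------
# residual autocovariate


def residual_autocovariate(residuals, weights: WeightsMatrix) -> np.ndarray:
    """Row-standardized neighborhood mean of residuals (self excluded)."""
    r = np.asarray(residuals, dtype=float)
    w = weights.matrix.astype(float).copy()
    np.fill_diagonal(w, 0.0)
    rs = w.sum(axis=1)
    none = rs == 0
    if none.any():
        warnings.warn(f"{int(none.sum())} cells have no neighbors; RAC set to 0",
                      stacklevel=2)
    w[~none] = w[~none] / rs[~none, None]
    return w @ r


def fit_gam_rac(y, X: pd.DataFrame, weights: WeightsMatrix,
                family: str = "gaussian", n_perm: int = 199, seed: int = 0,
                **gam_kwargs) -> tuple[GamFit, MoranResult, MoranResult]:
    """Base GAM -> Moran's I of residuals -> RAC -> refit -> Moran's I again.

    Returns the RAC-augmented fit plus the before/after Moran results.
    """
    base = fit_gam(y, X, family=family, **gam_kwargs)
    moran_before = morans_i(base.residuals, weights, n_perm=n_perm, seed=seed)
    rac = residual_autocovariate(base.residuals, weights)
    X2 = X.copy()
    X2["RAC"] = rac
    lin = tuple(gam_kwargs.pop("linear_terms", ())) + ("RAC",)
    fit2 = fit_gam(y, X2, family=family, linear_terms=lin, has_rac=True,
                   **gam_kwargs)
    moran_after = morans_i(fit2.residuals, weights, n_perm=n_perm, seed=seed + 1)
    return fit2, moran_before, moran_after


# ---------------------------------------------------------------------------
# model comparison


def evidence_category(delta: float) -> str:
    for bound, label in EVIDENCE_BINS:
        if delta < bound:
            return label
    return EVIDENCE_BINS[-1][1]


def model_table(bics: dict) -> pd.DataFrame:
    """BIC comparison table from model name -> BIC value."""
    df = pd.DataFrame({"model": list(bics.keys()),
                       "bic": [float(b) for b in bics.values()]})
    best = df["bic"].min()
    df["delta_bic"] = df["bic"] - best
    df["evidence"] = df["delta_bic"].map(evidence_category)
    df["best"] = df["bic"] == best
    if df["best"].sum() > 1:  # deterministic single best on exact ties
        first = df.index[df["best"]][0]
        df["best"] = False
        df.loc[first, "best"] = True
    return df.sort_values("bic", kind="stable").reset_index(drop=True)


def bic_select(candidates: dict, fit_fn) -> tuple[pd.DataFrame, dict]:
    """Fit every candidate predictor set and rank by BIC.

    ``candidates`` maps model name -> predictor list; ``fit_fn(predictors)``
    must return a :class:`GamFit` (or anything with a ``bic`` attribute).
    Returns the comparison table and the fitted models.
    """
    fits = {name: fit_fn(preds) for name, preds in candidates.items()}
    table = model_table({name: fit.bic for name, fit in fits.items()})
    return table, fits


def predicted_vs_observed(fit: GamFit) -> dict:
    """Pearson r between fitted and observed plus residual-sign counts.

    Negative residuals (observed below prediction) flag potential knowledge
    shortfalls; positive residuals flag underestimation by the model.
    """
    obs = fit.fitted + fit.residuals
    if np.std(fit.fitted) == 0 or np.std(obs) == 0:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(obs, fit.fitted)
    return {"pearson_r": float(r), "p_value": float(p),
            "n_negative_residuals": int((fit.residuals < 0).sum()),
            "n_positive_residuals": int((fit.residuals > 0).sum())}
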