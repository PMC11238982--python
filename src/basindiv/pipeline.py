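"""End-to-end orchestration from a declarative configuration.

A run executes the stages in dependency order — simulate/load, clean, grid,
PAM, diversity, effort, hotspots, environment, models, GDM — writing every
artifact under the output directory and recording it in a manifest with its
SHA-256 checksum, the stage name, the seed and the package version.  A stage
failure halts the run with the stage name and leaves the partial manifest on
disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grid import GridSpec

log = logging.getLogger("basindiv")

DEFAULTS = {
    "mode": "synthetic",
    "seed": 0,
    "grid": {"cell_size": 1.0, "lon_min": -80.0, "lon_max": -70.0,
             "lat_min": -40.0, "lat_max": -30.0},
    "period": [1993, 2019],
    "depth_window": [0.0, 200.0],
    "exclude_lon_band": [-110.0, -170.0],
    "min_richness": 10,
    "weights": "queen",
    "families": {"richness": "poisson", "composition": "gaussian"},
    "synthetic": {"n_species": 40, "n_time_slices": 4, "spatial_scale": 2.0,
                  "effort": 8.0, "dirty_fraction": 0.1},
    "gdm_response": "sor",
    "max_pairs": 50000,
}

REQUIRED = ("outdir",)
REQUIRED_FILES_MODE = ("occurrences", "env")


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration: " + "; ".join(self.errors))


class PipelineError(RuntimeError):
    def __init__(self, stage, cause, manifest):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"pipeline failed at stage '{stage}': {cause}")


def validate_config(config: dict) -> dict:
    """Normalize a run configuration, filling documented defaults.

    Every problem is reported with the offending key; normalization is
    idempotent.
    """
    errors = []
    cfg = dict(config or {})
    for key in REQUIRED:
        if key not in cfg:
            errors.append(f"missing required key: {key}")
    for key, val in DEFAULTS.items():
        if key not in cfg or cfg[key] is None:
            cfg[key] = json.loads(json.dumps(val))  # deep copy
        elif isinstance(val, dict):
            merged = dict(val)
            merged.update(cfg[key])
            cfg[key] = merged
    if cfg["mode"] not in ("synthetic", "files"):
        errors.append("mode: must be 'synthetic' or 'files'")
    if cfg["mode"] == "files":
        for key in REQUIRED_FILES_MODE:
            if key not in cfg:
                errors.append(f"missing required key for files mode: {key}")
            elif not Path(cfg[key]).exists():
                errors.append(f"{key}: path does not exist: {cfg[key]}")
    if not isinstance(cfg["seed"], int):
        errors.append("seed: must be an integer")
    if errors:
        raise ConfigError(errors)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, seed: int):
        self.outdir = outdir
        self.seed = seed
        self.entries = []

    def add(self, stage: str, path: Path):
        self.entries.append({"stage": stage, "path": str(path.relative_to(self.outdir)),
                             "sha256": _sha256(path), "seed": self.seed,
                             "version": __version__})

    def write(self):
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps({"version": __version__, "seed": self.seed,
                                    "artifacts": self.entries}, indent=2))
        return path


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages; return the manifest dictionary."""
    from . import diversity, effort, environment, gdm, models, occurrences, spatial, synthetic

    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest = _Manifest(outdir, seed)
    grid = GridSpec(**cfg["grid"])
    stage = "setup"
    t0 = time.time()
    try:
        # ------------------------------------------------ occurrence records
        stage = "simulate" if cfg["mode"] == "synthetic" else "load"
        if cfg["mode"] == "synthetic":
            s = cfg["synthetic"]
            stack = synthetic.make_env_fields(grid, n_time_slices=s["n_time_slices"],
                                              spatial_scale=s["spatial_scale"], seed=seed,
                                              start_year=cfg["period"][0])
            env_table = environment.env_table_from_stack(stack)
            pool = synthetic.make_species_pool(env_table, n_species=s["n_species"],
                                               seed=seed)
            eff = synthetic.uniform_effort(env_table, s["effort"])
            raw = synthetic.simulate_occurrences(env_table, pool, eff,
                                                 dirty_fraction=s["dirty_fraction"],
                                                 seed=seed, period=tuple(cfg["period"]),
                                                 cell_size=grid.cell_size)
            p = outdir / "occurrences_raw.csv"
            raw.to_csv(p, index=False)
            manifest.add(stage, p)
            truth = synthetic.ground_truth(env_table, pool, eff)
            p = outdir / "ground_truth.csv"
            truth.to_csv(p, index=False)
            manifest.add(stage, p)
            records = occurrences.record_table_from_frame(raw)
        else:
            records = occurrences.read_occurrences(cfg["occurrences"])
            env_table = None  # read lazily at the environment stage

        # ------------------------------------------------------------- clean
        stage = "clean"
        rules = occurrences.CleaningRules(depth_window=tuple(cfg["depth_window"]),
                                          period=tuple(cfg["period"]))
        cleaned, report = occurrences.clean_records(records, rules)
        if "synonyms" in cfg and cfg["synonyms"]:
            syn = occurrences.load_synonym_table(cfg["synonyms"])
            cleaned, n_unmatched = occurrences.harmonize_taxonomy(cleaned, syn)
            log.info("taxonomy: %d names without synonym entry", n_unmatched)
        p = outdir / "cleaning_report.json"
        report.to_json(p)
        manifest.add(stage, p)
        p = outdir / "occurrences_clean.csv"
        cleaned.to_csv(p, index=False)
        manifest.add(stage, p)

        # -------------------------------------------------------------- grid
        stage = "grid"
        gridded = occurrences.assign_cells(cleaned, grid)
        stage = "pam"
        pam = occurrences.build_pam(gridded, cell_size=grid.cell_size)
        band = cfg.get("exclude_lon_band")
        pam_f = occurrences.filter_cells(pam, min_richness=cfg["min_richness"],
                                         excluded_lon_band=tuple(band) if band else None)
        if pam_f.n_cells == 0:
            raise RuntimeError("no cells left after filtering")
        p = outdir / "pam_wide.csv"
        pam_f.to_wide_csv(p)
        manifest.add(stage, p)
        p = outdir / "pam_triplets.csv"
        pam_f.to_triplets(p)
        manifest.add(stage, p)

        # --------------------------------------------------------- diversity
        stage = "diversity"
        rich = diversity.alpha_richness(pam_f)
        shan = diversity.shannon_index(pam_f)
        beta_cells, beta_grand = diversity.beta_per_cell(pam_f)
        redun = diversity.redundancy_index(pam_f)
        div = pd.concat([rich, shan, beta_cells, redun], axis=1)
        p = outdir / "diversity.csv"
        div.to_csv(p)
        manifest.add(stage, p)
        p = outdir / "beta_grand_means.json"
        p.write_text(json.dumps(beta_grand, indent=2))
        manifest.add(stage, p)

        # ------------------------------------------------------------ effort
        stage = "effort"
        freqs = pd.Series(pam_f.counts.sum(axis=0), index=pam_f.species)
        curve = effort.rarefy_extrapolate(freqs.to_numpy(), n_boot=100, seed=seed,
                                          region="all")
        p = outdir / "rarefaction.csv"
        curve.to_frame().to_csv(p, index=False)
        manifest.add(stage, p)

        # ---------------------------------------------------------- hotspots
        stage = "hotspots"
        scheme = cfg["weights"]
        band_km = None
        if isinstance(scheme, str) and scheme.startswith("band:"):
            band_km = float(scheme.split(":", 1)[1])
            scheme = "band"
        w_self = spatial.build_weights(pam_f.cells, scheme=scheme, include_self=True,
                                       band_km=band_km, cell_size=grid.cell_size)
        hot = spatial.getis_ord_gstar(rich.to_numpy(dtype=float), w_self)
        p = outdir / "hotspots.csv"
        hot.to_csv(p, index=False)
        manifest.add(stage, p)
        w = spatial.build_weights(pam_f.cells, scheme=scheme, include_self=False,
                                  band_km=band_km, cell_size=grid.cell_size)
        moran_rich = spatial.morans_i(rich.to_numpy(dtype=float), w, n_perm=199,
                                      seed=seed)
        p = outdir / "moran_richness.json"
        p.write_text(json.dumps({"I": moran_rich.i, "expected": moran_rich.expected,
                                 "p_analytic": moran_rich.p_analytic,
                                 "p_perm": moran_rich.p_perm}, indent=2))
        manifest.add(stage, p)

        # ------------------------------------------------------- environment
        stage = "environment"
        if env_table is None:
            env_long = pd.read_csv(cfg["env"])
            env_table = environment.aggregate_mean(env_long,
                                                   depth_range=tuple(cfg["depth_window"]),
                                                   period=tuple(cfg["period"]))
        env_cells = env_table[env_table["cell_id"].isin(set(pam_f.cells))].copy()
        missing = env_cells[list(environment.ENV_COLUMNS)].isna().any(axis=1) \
            if set(environment.ENV_COLUMNS) <= set(env_cells.columns) else \
            env_cells.isna().any(axis=1)
        if missing.any():
            log.info("dropping %d cells with missing predictors", int(missing.sum()))
            env_cells = env_cells[~missing]
        env_std = environment.standardize(env_cells)
        corr = environment.spearman_matrix(env_std)
        p = outdir / "env_table.csv"
        env_std.to_csv(p, index=False)
        manifest.add(stage, p)
        p = outdir / "env_spearman.csv"
        corr.to_csv(p)
        manifest.add(stage, p)

        # ------------------------------------------------------------ models
        stage = "models"
        env_idx = env_std.set_index("cell_id").loc[[c for c in pam_f.cells
                                                    if c in set(env_std["cell_id"])]]
        common = list(env_idx.index)
        keep_mask = np.array([c in set(common) for c in pam_f.cells])
        pam_m = pam_f.subset_cells(keep_mask)
        env_idx = env_idx.loc[list(pam_m.cells)]
        wm = spatial.build_weights(pam_m.cells, scheme=scheme, include_self=False,
                                   band_km=band_km, cell_size=grid.cell_size)
        predictors = [c for c in environment.ENV_COLUMNS if c in env_idx.columns]
        y_rich = diversity.alpha_richness(pam_m).to_numpy(dtype=float)
        Xfull = env_idx[predictors]
        sel = models.rf_select(Xfull, y_rich, seed=seed)
        chosen = sel.selected or sel.ranking["variable"].head(3).tolist()
        fit, mb, ma = models.fit_gam_rac(y_rich, env_idx[chosen], wm,
                                         family=cfg["families"]["richness"],
                                         seed=seed)
        beta_m, _ = diversity.beta_per_cell(pam_m)
        y_comp = beta_m["beta_sor"].to_numpy(dtype=float)
        fit_c, mb_c, ma_c = models.fit_gam_rac(y_comp, env_idx[chosen], wm,
                                               family=cfg["families"]["composition"],
                                               seed=seed + 1)
        summary = {
            "richness": {"predictors": chosen, "bic": fit.bic, "adj_r2": fit.adj_r2,
                         "moran_before": mb.i, "moran_after": ma.i,
                         **models.predicted_vs_observed(fit)},
            "composition": {"predictors": chosen, "bic": fit_c.bic,
                            "adj_r2": fit_c.adj_r2, "moran_before": mb_c.i,
                            "moran_after": ma_c.i,
                            **models.predicted_vs_observed(fit_c)},
            "rf_selection": {"ranked": sel.ranking["variable"].tolist(),
                             "selected": sel.selected},
        }
        p = outdir / "model_summary.json"
        p.write_text(json.dumps(summary, indent=2))
        manifest.add(stage, p)

        # --------------------------------------------------------------- gdm
        stage = "gdm"
        pairs = gdm.build_site_pairs(pam_m, env_std, predictors,
                                     response=cfg["gdm_response"],
                                     max_pairs=cfg["max_pairs"], seed=seed)
        gfit = gdm.fit_gdm(pairs, predictors)
        p = outdir / "gdm_fit.json"
        p.write_text(json.dumps(gfit.to_json_dict(), indent=2))
        manifest.add(stage, p)
        rgb = gdm.transform_and_map(gfit, env_std[env_std["cell_id"].isin(set(pam_m.cells))])
        p = outdir / "composition_rgb.csv"
        rgb.to_csv(p, index=False)
        manifest.add(stage, p)

        stage = "manifest"
        mpath = manifest.write()
        log.info("pipeline finished in %.1fs, %d artifacts", time.time() - t0,
                 len(manifest.entries))
        return json.loads(mpath.read_text())
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        manifest.write()
        raise PipelineError(stage, exc, manifest.entries) from exc
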