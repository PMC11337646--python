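"""Study orchestration: run the full simulate -> extract -> classify ->
select -> train -> compare -> repeatability pipeline over the experiment
grid, reproducibly from one config and one seed.

The default study mirrors the shape of a multi-environment wheat trial
programme: 8 experiments (seven 21-plot and one 27-plot biomass-calibration
trial), 5 biomass cuts per plot spread over the season, and the full
comparison grid of 4 broad-stage subsets x 3 variable sets (12 cells),
evaluated for both ROI types.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import TrialDesign, biocal_2021_spec, biocal_2022_spec, generate_design
from .fieldobs import classify_stage, compute_dw_agb
from .growth import (
    BiomassCut,
    GrowthParams,
    default_genotype_asymptotes,
    simulate_growth,
    synthetic_weather,
)
from .phenology import PhenologyModel, simulate_zadoks_observations
from .scene import PlotState, heterogeneity_profile, render_scene
from .selection import correlation_filter, rfe
from .traits import GEOMETRIC_TRAITS, extract_traits, trait_columns
from .training import ModelConfig, split_train_test, train_model
from .spatial import repeatability_trajectory

__all__ = ["StudyConfig", "StudyResults", "run_study", "roi_comparison", "variable_set_columns"]

STAGE_LEVELS = ("vegetative", "flowering", "grain_fill", "all")


def _stable_hash(*parts) -> int:
    """Process-independent 31-bit hash for seed derivation."""
    key = "|".join(str(p) for p in parts)
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "little") % (2**31)
VARIABLE_SETS = ("spectral", "geometric", "combined")


@dataclass
class StudyConfig:
    """Everything needed to re-create a study bit-identically (with a seed)."""

    n_experiments: int = 8
    n_cuts: int = 5
    gsd: float = 1.0 / 64.0
    plot_length: float = 8.0
    plot_width: float = 2.0
    roi_size: float = 1.0
    stages: tuple[str, ...] = STAGE_LEVELS
    variable_sets: tuple[str, ...] = VARIABLE_SETS
    learners: tuple[str, ...] = ("plsr", "rf", "svm_poly", "xgboost")
    roi_types: tuple[str, ...] = ("permanent", "precise")
    # growth / scene
    residual_cv: float = 0.10
    spatial_trend_amplitude: float = 150.0
    heterogeneity: float = 0.0
    genotype_cv: float = 0.10
    quad_area: float = 0.5
    quad_noise_cv: float = 0.05
    # cut timing (degC day targets, vegetative through grain fill)
    cut_tt_targets: tuple[float, ...] = (500.0, 850.0, 1200.0, 1550.0, 1900.0)
    # selection / training effort
    rfe_resamples: int = 30
    cv_folds: int = 10
    cv_repeats: int = 10
    rf_trees: int = 200
    repeatability_learner: str = "rf"

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGE_LEVELS:
                raise ValueError(f"unknown stage {s!r}")
        for v in self.variable_sets:
            if v not in VARIABLE_SETS:
                raise ValueError(f"unknown variable set {v!r}")
        if len(self.cut_tt_targets) < self.n_cuts:
            raise ValueError("need a TT target per cut")

    @property
    def grid_cells(self) -> list[tuple[str, str]]:
        """The stage x variable-set comparison grid (12 cells by default)."""
        return [(s, v) for s in self.stages for v in self.variable_sets]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("stages", "variable_sets", "learners", "roi_types", "cut_tt_targets"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


def variable_set_columns(variable_set: str) -> list[str]:
    """Trait columns belonging to one variable set."""
    spectral = [c for c in trait_columns() if c.endswith("_median")]
    geometric = list(GEOMETRIC_TRAITS)
    if variable_set == "spectral":
        return spectral
    if variable_set == "geometric":
        return geometric
    if variable_set == "combined":
        return geometric + spectral
    raise ValueError(f"unknown variable set {variable_set!r}")


def _experiment_specs(config: StudyConfig):
    """Experiment id -> design spec; the last experiment uses the 27-plot
    template, the rest the 21-plot one."""
    specs = []
    for i in range(config.n_experiments):
        eid = f"E{i + 1}"
        spec = biocal_2022_spec() if i == config.n_experiments - 1 else biocal_2021_spec()
        specs.append((eid, spec))
    return specs


def _dates_for_tt_targets(tt_series: pd.DataFrame, targets) -> list[date]:
    dates = []
    for t in targets:
        idx = int((tt_series["tt"] - t).abs().idxmin())
        dates.append(tt_series["date"].iloc[idx])
    return dates


def simulate_experiment(experiment_id: str, spec, config: StudyConfig, seed: int):
    """Design, weather, growth and per-cut ground truth for one experiment.

    Returns (design, growth frame, cuts list, zadoks observations).  The
    growth frame gains per-cut columns for the local biomass at each ROI
    position (the within-plot heterogeneity profile evaluated at the ROI
    centroid), which is what the destructive quadrat actually measures.
    """
    from .fieldobs import cumulative_thermal_time
    from .scene import _default_rois

    ss = np.random.SeedSequence([seed, _stable_hash(experiment_id)])
    s_design, s_weather, s_geno, s_growth, s_cuts, s_zadoks, s_phase = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(7)
    ]
    design = generate_design(spec, seed=s_design, experiment_id=experiment_id)
    sowing = date(2021, 5, 15)
    weather = synthetic_weather(sowing, 200, seed=s_weather)
    params = GrowthParams(
        biomass_asymptote=default_genotype_asymptotes(design.genotypes, s_geno,
                                                      cv=config.genotype_cv),
        spatial_trend_amplitude=config.spatial_trend_amplitude,
        residual_cv=config.residual_cv,
        within_plot_heterogeneity=config.heterogeneity,
    )
    tt_series = cumulative_thermal_time(weather, sowing)
    cut_dates = _dates_for_tt_targets(tt_series, config.cut_tt_targets[: config.n_cuts])
    growth = simulate_growth(design, weather, params, seed=s_growth,
                             sowing_date=sowing, dates=cut_dates)
    growth["cut_number"] = growth.groupby("plot_id")["date"].rank(method="dense").astype(int)

    # within-plot heterogeneity: local biomass at each ROI centroid
    rng_phase = np.random.default_rng(s_phase)
    phases = {p.plot_id: float(rng_phase.uniform(0, 2 * np.pi)) for p in design.plots}
    roi_perm, roi_prec = _default_rois(config.plot_length, config.plot_width,
                                       config.n_cuts, config.roi_size)
    x_perm = roi_perm.centroid.x
    x_prec = {k: poly.centroid.x for k, poly in roi_prec.items()}

    growth["phase"] = growth["plot_id"].map(phases)
    growth["mult_permanent"] = heterogeneity_profile(
        np.full(len(growth), x_perm), config.plot_length, config.heterogeneity,
        growth["phase"].to_numpy())
    growth["mult_precise"] = heterogeneity_profile(
        growth["cut_number"].map(x_prec).to_numpy(), config.plot_length,
        config.heterogeneity, growth["phase"].to_numpy())
    growth["dw_agb_cut"] = growth["dw_agb"] * growth["mult_precise"]

    rng_cuts = np.random.default_rng(s_cuts)
    cuts: list[BiomassCut] = []
    for r in growth.itertuples():
        cuts.append(
            BiomassCut(
                plot_id=r.plot_id, date=r.date, cut_number=int(r.cut_number),
                **_cut_fields(r.dw_agb_cut, config, rng_cuts),
            )
        )

    tt_obs, z_obs = simulate_zadoks_observations(1189.0, 1523.0, n=30, sigma=2.0,
                                                 seed=s_zadoks)
    return design, growth, cuts, (tt_obs, z_obs)


def _cut_fields(true_dw: float, config: StudyConfig, rng) -> dict:
    from .growth import sample_biomass

    sub_seed = int(rng.integers(0, 2**31))
    c = sample_biomass(true_dw, config.quad_area, config.quad_noise_cv, sub_seed)
    return {"fw_quad": c.fw_quad, "fw_sub": c.fw_sub, "dw_sub": c.dw_sub,
            "quad_area": c.quad_area}


def build_trait_table(config: StudyConfig, seed: int,
                      scene_dir: Path | None = None) -> pd.DataFrame:
    """Simulate all experiments, render every plot x cut scene, extract
    traits for both ROI types and attach the measured DW_AGB response and
    broad growth stage.  One row per plot x cut x roi_type."""
    records = []
    zadoks_all = []
    for experiment_id, spec in _experiment_specs(config):
        design, growth, cuts, (tt_obs, z_obs) = simulate_experiment(
            experiment_id, spec, config, seed)
        zadoks_all.append((tt_obs, z_obs))
        cut_lookup = {(c.plot_id, c.cut_number): c for c in cuts}
        meta = {p.plot_id: p for p in design.plots}
        ss = np.random.SeedSequence([seed, _stable_hash(experiment_id), 77])
        scene_seeds = iter(int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(growth)))
        for r in growth.itertuples():
            state = PlotState(
                plot_id=r.plot_id, date=r.date, mean_height=r.mean_height,
                green_fraction=r.green_fraction, senescence=r.senescence)
            scene = render_scene(
                state, config.gsd, seed=next(scene_seeds),
                plot_length=config.plot_length, plot_width=config.plot_width,
                n_cuts=config.n_cuts, roi_size=config.roi_size,
                heterogeneity=config.heterogeneity, heterogeneity_phase=r.phase)
            if scene_dir is not None:
                from .io import write_scene

                write_scene(scene, Path(scene_dir) / experiment_id /
                            f"{r.plot_id}_cut{r.cut_number}")
            cut = cut_lookup[(r.plot_id, int(r.cut_number))]
            dw_obs = compute_dw_agb(cut)
            plot = meta[r.plot_id]
            for roi_type in config.roi_types:
                rec = extract_traits(scene, roi_type,
                                     cut_number=int(r.cut_number) if roi_type == "precise" else None)
                row = rec.to_dict()
                row.update(
                    experiment=experiment_id, genotype=plot.genotype,
                    density=plot.density, row=plot.row, column=plot.column,
                    cut_number=int(r.cut_number), tt=r.tt, dw_agb=dw_obs,
                    dw_agb_true=r.dw_agb_cut if roi_type == "precise" else r.dw_agb,
                )
                records.append(row)
    table = pd.DataFrame(records)

    tt_cat = np.concatenate([t for t, _ in zadoks_all])
    z_cat = np.concatenate([z for _, z in zadoks_all])
    pheno = PhenologyModel(tt_cat, z_cat).fit()
    boundaries = pheno.solve_stage_boundaries()
    table["stage"] = classify_stage(table["tt"].to_numpy(), boundaries)
    table.attrs["stage_boundaries"] = (boundaries.tt_veg_flower,
                                       boundaries.tt_flower_grainfill)
    return table


def _cell_data(table: pd.DataFrame, stage: str, variable_set: str) -> tuple[pd.DataFrame, list[str]]:
    sub = table if stage == "all" else table[table["stage"] == stage]
    cols = variable_set_columns(variable_set)
    sub = sub.dropna(subset=["dw_agb"])
    keep = [c for c in cols if sub[c].notna().all() and sub[c].nunique() > 1]
    return sub.copy(), keep


@dataclass
class StudyResults:
    config: StudyConfig
    seed: int
    traits: pd.DataFrame
    selection: dict  # (roi, stage, varset) -> selection report dict
    results: pd.DataFrame  # learner x stage x varset x roi metrics
    comparisons: dict[str, pd.DataFrame]  # axis -> general/specific table
    repeatability: pd.DataFrame
    timings: dict[str, float] = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "config_digest": self.config.digest(),
            "seed": self.seed,
            "version": __version__,
            "timings_s": {k: round(v, 2) for k, v in self.timings.items()},
        }


def run_study(config: StudyConfig, seed: int, out_dir: str | Path | None = None) -> StudyResults:
    """Execute the full study; optionally write all tables under ``out_dir``."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    traits = build_trait_table(config, seed)
    timings["simulate_extract"] = time.perf_counter() - t0

    selection: dict = {}
    result_rows = []
    cv_pred_frames = []
    t0 = time.perf_counter()
    for roi_type in config.roi_types:
        roi_table = traits[traits["roi_type"] == roi_type]
        for stage, varset in config.grid_cells:
            sub, cols = _cell_data(roi_table, stage, varset)
            if len(sub) < 20 or len(cols) < 2:
                warnings.warn(f"skipping cell {roi_type}/{stage}/{varset}: too little data")
                continue
            retained = correlation_filter(sub[cols], cutoff=0.95)
            cell_seed = int(np.random.SeedSequence(
                [seed, _stable_hash(roi_type, stage, varset)]).generate_state(1)[0] % (2**31))
            profile = rfe(sub[retained], sub["dw_agb"],
                          n_resamples=config.rfe_resamples, seed=cell_seed,
                          strata=sub["experiment"].to_numpy())
            chosen = profile.chosen_features
            selection[(roi_type, stage, varset)] = profile.to_dict()

            train, test = split_train_test(sub, 0.8, strata="experiment", seed=cell_seed)
            for learner in config.learners:
                mc = ModelConfig(learner=learner, cv_folds=config.cv_folds,
                                 cv_repeats=config.cv_repeats, seed=cell_seed,
                                 rf_trees=config.rf_trees)
                fit = train_model(train[chosen], train["dw_agb"], mc,
                                  X_test=test[chosen], y_test=test["dw_agb"])
                result_rows.append({
                    "roi_type": roi_type, "stage": stage, "variable_set": varset,
                    "learner": learner, "n_train": len(train), "n_test": len(test),
                    "n_features": len(chosen),
                    "cv_r2": fit.cv_metrics["r2"], "cv_rmse": fit.cv_metrics["rmse"],
                    "cv_rrmse": fit.cv_metrics["rrmse"],
                    "test_r2": fit.test_metrics["r2"], "test_rmse": fit.test_metrics["rmse"],
                    "test_rrmse": fit.test_metrics["rrmse"],
                })
                if (roi_type == "permanent" and stage == "all" and varset == "combined"
                        and learner == config.repeatability_learner):
                    preds = fit.cv_predictions.join(
                        train[["experiment", "cut_number", "row", "column", "genotype"]])
                    cv_pred_frames.append(preds)
    results = pd.DataFrame(result_rows)
    timings["select_train"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    comparisons = {}
    perm_all = traits[traits["roi_type"] == "permanent"]
    sub, cols = _cell_data(perm_all, "all", "combined")
    if (("permanent", "all", "combined") in selection) and len(sub) >= 40:
        chosen = selection[("permanent", "all", "combined")]["chosen_features"]
        from .training import compare_general_specific

        mc = ModelConfig(learner=config.repeatability_learner,
                         cv_folds=config.cv_folds, cv_repeats=min(config.cv_repeats, 3),
                         seed=seed, rf_trees=config.rf_trees)
        for axis in ("stage", "experiment"):
            comparisons[axis] = compare_general_specific(
                sub, chosen, "dw_agb", axis, mc, seed=seed)
    timings["compare"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if cv_pred_frames:
        preds = pd.concat(cv_pred_frames)
        repeat = repeatability_trajectory(preds, value_col="pred")
    else:
        repeat = pd.DataFrame()
    timings["repeatability"] = time.perf_counter() - t0

    out = StudyResults(config=config, seed=seed, traits=traits, selection=selection,
                       results=results, comparisons=comparisons,
                       repeatability=repeat, timings=timings)
    if out_dir is not None:
        _write_results(out, Path(out_dir))
    return out


def _write_results(res: StudyResults, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    res.traits.to_csv(out_dir / "traits.csv", index=False)
    res.results.to_csv(out_dir / "results.csv", index=False)
    res.repeatability.to_csv(out_dir / "repeatability.csv", index=False)
    for axis, df in res.comparisons.items():
        df.to_csv(out_dir / f"comparison_{axis}.csv", index=False)
    sel = {"/".join(k): v for k, v in res.selection.items()}
    (out_dir / "selection.json").write_text(json.dumps(sel, indent=1))
    (out_dir / "manifest.json").write_text(json.dumps(res.manifest(), indent=1))


def roi_comparison(results: pd.DataFrame) -> pd.DataFrame:
    """Paired per-cell metrics for ROI_permanent vs ROI_precise.

    One row per (stage, variable_set, learner) cell with both ROI runs
    present; raises if a cell is missing one side.
    """
    needed = {"permanent", "precise"}
    if not needed.issubset(set(results["roi_type"])):
        raise ValueError("need results for both ROI types")
    keys = ["stage", "variable_set", "learner"]
    perm = results[results["roi_type"] == "permanent"].set_index(keys)
    prec = results[results["roi_type"] == "precise"].set_index(keys)
    missing = set(perm.index.tolist()) ^ set(prec.index.tolist())
    if missing:
        raise ValueError(f"cells missing one ROI run: {sorted(missing)}")
    rows = []
    for key in perm.index:
        a, b = perm.loc[key], prec.loc[key]
        rows.append({
            **dict(zip(keys, key)),
            "test_rmse_permanent": float(a["test_rmse"]),
            "test_rmse_precise": float(b["test_rmse"]),
            "test_rmse_diff": float(b["test_rmse"] - a["test_rmse"]),
            "cv_rmse_permanent": float(a["cv_rmse"]),
            "cv_rmse_precise": float(b["cv_rmse"]),
        })
    return pd.DataFrame(rows)
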