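"""End-to-end pipeline orchestration.

Stages — world, fit, rake, aggregate, burden, inequality, validate — form a
linear DAG and communicate only through serialized artifacts in the output
directory (CSV tables, plain-text rasters, draw-cube arrays with JSON
sidecars), so any stage can be rerun independently, including in a separate
process.  A master seed plus stable per-stage tags make reruns bitwise
reproducible; a manifest records the config hash, seed, and versions.  On a
stage failure an INCOMPLETE marker is left next to the partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from washmap import __version__
from washmap._rng import child_rng, child_seed
from washmap.admin import AdminHierarchy
from washmap.aggregate import transitions_table, unit_estimates_table
from washmap.burden import (
    RiskRatioTable,
    attributable_deaths,
    averted_deaths,
    build_water_exposure,
    paf,
    synthetic_risk_ratio_frame,
)
from washmap.calibration import (
    fit_national_model,
    national_series_frame,
    rake_continuation_ratio,
)
from washmap.grids import RasterGrid
from washmap.inequality import disparity, inequality_table
from washmap.ingest import resample_areal_to_points
from washmap.ordinal import recombine, to_conditional_observations
from washmap.records import read_survey_csv, write_survey_csv
from washmap.spatial import DrawCube, GeostatConfig, fit_parent
from washmap.stacking import (
    build_features,
    default_specs,
    fit_children,
    logit,
    predict_child_rasters,
)
from washmap.synthetic import (
    World,
    WorldConfig,
    generate_world,
    simulate_areal_survey,
    simulate_national_series,
    simulate_point_survey,
)
from washmap.validation import cv_metrics, make_folds

log = logging.getLogger("washmap.pipeline")

STAGES = ("world", "fit", "rake", "aggregate", "burden", "inequality", "validate")

CSV_FLOAT_FORMAT = "%.10g"

CATEGORY_NAMES = ("cat1", "cat2", "cat3", "cat4")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class SurveyConfig:
    clusters_per_country_year: int = 20
    households_per_cluster: int = 25
    areal_years: tuple[int, ...] = (2000, 2006, 2012)
    areal_households_per_unit: int = 400
    national_households: int = 4000


@dataclass
class PipelineConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    survey: SurveyConfig = field(default_factory=SurveyConfig)
    model: GeostatConfig = field(default_factory=GeostatConfig)
    stacking_folds: int = 5
    raking_tolerance: float = 1e-8
    validation_folds: int = 5
    validation_countries: tuple[str, ...] = ("C0",)
    stages: tuple[str, ...] = STAGES
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order) or order != list(range(len(order))):
            raise ValueError("stages must form a prefix of the pipeline DAG")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["world"]["years"] = list(d["world"]["years"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "world" in d:
            w = dict(d["world"])
            if "years" in w:
                w["years"] = tuple(w["years"])
            d["world"] = WorldConfig(**w)
        if "survey" in d:
            s = dict(d["survey"])
            if "areal_years" in s:
                s["areal_years"] = tuple(s["areal_years"])
            d["survey"] = SurveyConfig(**s)
        if "model" in d:
            m = dict(d["model"])
            if "prior_scales" in m:
                m["prior_scales"] = tuple(m["prior_scales"])
            d["model"] = GeostatConfig(**m)
        for key in ("validation_countries", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


# --------------------------------------------------------------------------
# stage implementations


def stage_world(cfg: PipelineConfig, out: Path) -> None:
    wcfg = WorldConfig(**{**asdict(cfg.world), "years": cfg.world.years, "seed": cfg.seed})
    world = generate_world(wcfg)
    world.population.write_ascii(out / "population.asc")
    world.covariates.write_ascii(out / "covariates.asc")
    _write_csv(world.admin.to_frame(), out / "admin.csv")
    records = []
    for country in world.admin.units("country"):
        for year in world.years:
            records += simulate_point_survey(
                world,
                country,
                year,
                cfg.survey.clusters_per_country_year,
                cfg.survey.households_per_cluster,
                seed=child_seed(cfg.seed, f"survey.{country}.{year}"),
            )
        for year in cfg.survey.areal_years:
            if year in world.years:
                records += simulate_areal_survey(
                    world,
                    country,
                    year,
                    "admin1",
                    cfg.survey.areal_households_per_unit,
                    seed=child_seed(cfg.seed, f"areal.{country}.{year}"),
                )
    write_survey_csv(records, out / "surveys.csv", n_cols=wcfg.n_cols)
    national = []
    for country in world.admin.units("country"):
        national += simulate_national_series(
            world,
            country,
            seed=child_seed(cfg.seed, f"national.{country}"),
            n_households=cfg.survey.national_households,
        )
    write_survey_csv(national, out / "national.csv", n_cols=wcfg.n_cols)
    (out / "world_config.json").write_text(json.dumps(asdict(wcfg)))


def _load_world_artifacts(cfg: PipelineConfig, out: Path):
    population = RasterGrid.read_ascii(out / "population.asc")
    covariates = RasterGrid.read_ascii(out / "covariates.asc")
    admin = AdminHierarchy.from_frame(pd.read_csv(out / "admin.csv"))
    return population, covariates, admin


def _conditional_observations_frame(records, admin, n_cols: int) -> pd.DataFrame:
    """Point/pseudo-point records -> long (level, cell, year, s, n) table."""
    rows = []
    for r in records:
        for level, s, n in to_conditional_observations(r):
            rows.append(
                {
                    "record_id": r.record_id,
                    "country": r.country,
                    "admin1": r.admin1,
                    "level": level,
                    "cell": r.cell,
                    "year": r.year,
                    "successes": s,
                    "trials": n,
                }
            )
    return pd.DataFrame(rows)


def stage_fit(cfg: PipelineConfig, out: Path) -> None:
    population, covariates, admin = _load_world_artifacts(cfg, out)
    n_cols = population.n_cols
    records = read_survey_csv(out / "surveys.csv", n_cols=n_cols)
    points = [r for r in records if r.source_type == "point"]
    for r in records:
        if r.source_type == "areal":
            points += resample_areal_to_points(r, population, admin)
    obs = _conditional_observations_frame(points, admin, n_cols)
    years = tuple(cfg.world.years)
    covflat = covariates.flat()
    coords = population.cell_centers()
    cube_dir = out / "cubes"
    cube_dir.mkdir(exist_ok=True)
    for country in admin.units("country"):
        ccells = admin.cells_of(country)
        local = {int(c): i for i, c in enumerate(ccells)}
        for level in (1, 2, 3):
            sub = obs[(obs["country"] == country) & (obs["level"] == level)]
            seed = child_seed(cfg.seed, f"fit.{country}.L{level}")
            t0 = time.perf_counter()
            X = build_features(
                covflat, coords, sub["cell"].to_numpy(int), sub["year"].to_numpy()
            )
            stacked = fit_children(
                X,
                sub["successes"].to_numpy(int),
                sub["trials"].to_numpy(int),
                groups=sub["record_id"].to_numpy(),
                specs=default_specs(seed=seed, n_folds=cfg.stacking_folds),
                seed=seed,
            )
            rasters = predict_child_rasters(
                stacked, covflat, coords, list(years), cells=ccells
            )
            feats = np.concatenate(
                [np.ones((1, len(ccells), len(years))), logit(rasters)]
            )  # (1+3, cells, years)
            X_parent = np.column_stack(
                [np.ones(len(sub)), stacked.oos_logits]
            )
            posterior = fit_parent(
                coords[ccells],
                years,
                X_parent,
                sub["successes"].to_numpy(int),
                sub["trials"].to_numpy(int),
                np.array([local[c] for c in sub["cell"]]),
                sub["year"].to_numpy(int),
                GeostatConfig(**{**asdict(cfg.model), "seed": seed}),
            )
            cube = posterior.sample_surface(
                X_pred=np.moveaxis(feats, 0, -1), cells=ccells
            )
            cube.indicator = "conditional"
            cube.conditional_level = level
            cube.save(cube_dir / f"{country}_L{level}")
            log.info(
                "fit %s level %d: m=%d sites, wall=%.1fs",
                country,
                level,
                posterior.m,
                time.perf_counter() - t0,
            )


def _load_cubes(cube_dir: Path, country: str) -> list[DrawCube]:
    return [DrawCube.load(cube_dir / f"{country}_L{level}") for level in (1, 2, 3)]


def stage_rake(cfg: PipelineConfig, out: Path) -> None:
    population, covariates, admin = _load_world_artifacts(cfg, out)
    national = read_survey_csv(out / "national.csv", n_cols=population.n_cols)
    years = tuple(cfg.world.years)
    raked_dir = out / "cubes_raked"
    raked_dir.mkdir(exist_ok=True)
    series_rows = []
    delta_rows = []
    for country in admin.units("country"):
        cubes = _load_cubes(out / "cubes", country)
        series = [
            fit_national_model(national, country, level, years) for level in (1, 2, 3)
        ]
        series_rows.append(national_series_frame(series))
        nat_cond = np.stack([s.targets for s in series])
        nat_cat = recombine(nat_cond)
        pop = admin.population[cubes[0].cells]
        raked, deltas = rake_continuation_ratio(
            cubes, nat_cat, pop, tolerance=cfg.raking_tolerance
        )
        for cube, level in zip(raked, (1, 2, 3)):
            cube.save(raked_dir / f"{country}_L{level}")
        for level, d in zip((1, 2, 3), deltas):
            for t, year in enumerate(years):
                delta_rows.append(
                    {
                        "country": country,
                        "conditional_level": level,
                        "year": year,
                        "delta_mean": float(d[t].mean()),
                    }
                )
    _write_csv(pd.concat(series_rows, ignore_index=True), out / "national_series.csv")
    _write_csv(pd.DataFrame(delta_rows), out / "raking_deltas.csv")


def _category_cubes(cond: list[DrawCube]) -> list[DrawCube]:
    cat = recombine(np.stack([c.values for c in cond]))
    return [
        DrawCube(
            np.ascontiguousarray(cat[k]),
            cells=cond[0].cells,
            years=cond[0].years,
            indicator=CATEGORY_NAMES[k],
            seed=cond[0].seed,
        )
        for k in range(4)
    ]


def stage_aggregate(cfg: PipelineConfig, out: Path) -> None:
    population, covariates, admin = _load_world_artifacts(cfg, out)
    unit_frames = []
    trans_frames = []
    for country in admin.units("country"):
        cats = _category_cubes(_load_cubes(out / "cubes_raked", country))
        for level in ("country", "admin1", "admin2"):
            unit_frames.append(
                unit_estimates_table(cats, admin, level, CATEGORY_NAMES)
            )
        trans_frames.append(transitions_table(cats, admin, "admin2"))
    _write_csv(pd.concat(unit_frames, ignore_index=True), out / "units.csv")
    _write_csv(pd.concat(trans_frames, ignore_index=True), out / "transitions.csv")


def stage_burden(cfg: PipelineConfig, out: Path) -> None:
    population, covariates, admin = _load_world_artifacts(cfg, out)
    rr_frame = synthetic_risk_ratio_frame()
    _write_csv(rr_frame, out / "risk_ratios.csv")
    rr = RiskRatioTable.from_frame(rr_frame, "water")
    years = tuple(cfg.world.years)
    first_i, last_i = 0, len(years) - 1
    mort_rows = []
    burden_rows = []
    for country in admin.units("country"):
        cats = _category_cubes(_load_cubes(out / "cubes_raked", country))
        cell_pos = {int(c): i for i, c in enumerate(cats[0].cells)}
        for unit in admin.units("admin2"):
            cells = [c for c in admin.cells_of(unit) if int(c) in cell_pos]
            if not cells:
                continue
            idx = np.array([cell_pos[int(c)] for c in cells])
            pop = admin.population[np.array(cells)]
            rng = child_rng(cfg.seed, f"burden.{unit}")
            # synthetic external inputs: under-5 diarrhoeal deaths and
            # household water-treatment prevalence per unit
            treatment = float(rng.uniform(0.2, 0.6))
            death_rate = float(rng.uniform(0.002, 0.006))
            deaths = float(pop.sum()) * 0.15 * death_rate
            mort_rows.append({"unit_id": unit, "year": years[last_i], "deaths": deaths})
            per_cat = [
                np.tensordot(pop, c.values[idx], axes=(0, 0)) / pop.sum() for c in cats
            ]  # each (years, draws)
            p_first = np.stack([c[first_i] for c in per_cat])  # (4, draws)
            p_last = np.stack([c[last_i] for c in per_cat])
            e_first = build_water_exposure(p_first, treatment)
            e_last = build_water_exposure(p_last, treatment)
            paf_d = paf(e_last, rr)
            attr_d = attributable_deaths(deaths, paf_d)
            avert_d = averted_deaths(deaths, e_first, e_last, rr)
            q = lambda a, p: float(np.percentile(a, p))
            burden_rows.append(
                {
                    "unit_id": unit,
                    "year": years[last_i],
                    "deaths": deaths,
                    "paf_mean": float(paf_d.mean()),
                    "paf_lower": q(paf_d, 2.5),
                    "paf_upper": q(paf_d, 97.5),
                    "attributable_mean": float(attr_d.mean()),
                    "attributable_lower": q(attr_d, 2.5),
                    "attributable_upper": q(attr_d, 97.5),
                    "averted_mean": float(avert_d.mean()),
                    "averted_lower": q(avert_d, 2.5),
                    "averted_upper": q(avert_d, 97.5),
                }
            )
    _write_csv(pd.DataFrame(mort_rows), out / "mortality.csv")
    _write_csv(pd.DataFrame(burden_rows), out / "burden.csv")


def stage_inequality(cfg: PipelineConfig, out: Path) -> None:
    units = pd.read_csv(out / "units.csv")
    adm2 = units[units["level"] == "admin2"].copy()
    adm2["country"] = adm2["unit_id"].str.extract(r"^(C\d+)")[0]
    results = []
    for (country, year), grp in adm2.groupby(["country", "year"]):
        wide = grp.pivot_table(index="unit_id", columns="indicator", values="mean")
        pops = grp.groupby("unit_id")["population"].first().reindex(wide.index)
        improved = (wide["cat1"] + wide["cat2"]).to_numpy()
        if len(improved) < 2:
            continue
        results.append(
            disparity(country, "improved", int(year), improved, pops.to_numpy())
        )
    _write_csv(inequality_table(results), out / "inequality.csv")


def stage_validate(cfg: PipelineConfig, out: Path) -> None:
    population, covariates, admin = _load_world_artifacts(cfg, out)
    n_cols = population.n_cols
    records = [
        r
        for r in read_survey_csv(out / "surveys.csv", n_cols=n_cols)
        if r.source_type == "point"
    ]
    years = tuple(cfg.world.years)
    covflat = covariates.flat()
    coords = population.cell_centers()
    report_rows = []
    for country in cfg.validation_countries:
        recs = [r for r in records if r.country == country]
        obs = _conditional_observations_frame(recs, admin, n_cols)
        sub = obs[obs["level"] == 1].reset_index(drop=True)
        folds = make_folds(
            sub["record_id"].to_numpy(),
            k=cfg.validation_folds,
            seed=child_seed(cfg.seed, f"cv.{country}"),
            strata=sub["country"].to_numpy(),
        )
        ccells = admin.cells_of(country)
        local = {int(c): i for i, c in enumerate(ccells)}
        observed = np.empty(len(sub))
        trials_arr = sub["trials"].to_numpy(int)
        pred_draws = np.empty((len(sub), cfg.model.n_draws))
        for f in range(cfg.validation_folds):
            tr = folds != f
            te = ~tr
            seed = child_seed(cfg.seed, f"cv.{country}.fold{f}")
            Xtr = build_features(
                covflat, coords, sub["cell"][tr].to_numpy(int), sub["year"][tr].to_numpy()
            )
            stacked = fit_children(
                Xtr,
                sub["successes"][tr].to_numpy(int),
                sub["trials"][tr].to_numpy(int),
                groups=sub["record_id"][tr].to_numpy(),
                specs=default_specs(seed=seed, n_folds=cfg.stacking_folds),
                seed=seed,
            )
            rasters = predict_child_rasters(
                stacked, covflat, coords, list(years), cells=ccells
            )
            feats = np.concatenate(
                [np.ones((1, len(ccells), len(years))), logit(rasters)]
            )
            posterior = fit_parent(
                coords[ccells],
                years,
                np.column_stack([np.ones(tr.sum()), stacked.oos_logits]),
                sub["successes"][tr].to_numpy(int),
                sub["trials"][tr].to_numpy(int),
                np.array([local[c] for c in sub["cell"][tr]]),
                sub["year"][tr].to_numpy(int),
                GeostatConfig(**{**asdict(cfg.model), "seed": seed}),
            )
            cube = posterior.sample_surface(X_pred=np.moveaxis(feats, 0, -1))
            yr_index = {y: i for i, y in enumerate(years)}
            for i in np.flatnonzero(te):
                ci = local[int(sub["cell"][i])]
                ti = yr_index[int(sub["year"][i])]
                pred_draws[i] = cube.values[ci, ti]
                observed[i] = sub["successes"][i] / sub["trials"][i]
        report = cv_metrics(
            observed,
            trials_arr,
            pred_draws,
            seed=child_seed(cfg.seed, f"cv.pred.{country}"),
            fold_labels=folds,
        )
        report_rows.append(
            {
                "country": country,
                "conditional_level": 1,
                "rmse": report.rmse,
                "bias": report.bias,
                "coverage95": report.coverage95,
                "n_heldout": report.n_heldout,
            }
        )
    _write_csv(pd.DataFrame(report_rows), out / "cv_report.csv")


_STAGE_FUNCS = {
    "world": stage_world,
    "fit": stage_fit,
    "rake": stage_rake,
    "aggregate": stage_aggregate,
    "burden": stage_burden,
    "inequality": stage_inequality,
    "validate": stage_validate,
}


def run(cfg: PipelineConfig, out_dir: str | Path, stages: tuple[str, ...] | None = None) -> dict:
    """Run the configured stages; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages) if stages is not None else cfg.stages
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages {bad}")
    incomplete = out / "INCOMPLETE"
    incomplete.write_text("run in progress\n")
    manifest = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": [],
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        log.info("stage=%s start seed=%d", stage, cfg.seed)
        try:
            _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:
            incomplete.write_text(f"failed in stage {stage}: {exc}\n")
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        wall = time.perf_counter() - t0
        log.info("stage=%s done wall=%.1fs", stage, wall)
        manifest["stages"].append({"stage": stage, "wall_s": round(wall, 2)})
    incomplete.unlink()
    # the manifest hash covers config, seed, version and stage list — not
    # wall times — so a deterministic rerun yields the identical hash
    ident = json.dumps(
        [manifest["config_hash"], manifest["seed"], manifest["version"], list(stages)]
    )
    manifest["manifest_hash"] = hashlib.sha256(ident.encode()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
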