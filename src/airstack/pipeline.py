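"""End-to-end pipeline orchestration.

Sequences the stages — simulate → qc → stage1 (PM2.5 augmentation) →
stage2 (satellite gap-filling) → features → train → evaluate → predict —
with a single YAML configuration, per-stage artifacts on disk, and a run
manifest (config hash, per-stage seeds, artifact checksums) so that two
runs with the same config and master seed produce identical outputs.
Stages are resumable: a stage whose outputs already exist is skipped
unless forced, and a missing upstream artifact raises an error naming
the stage to rerun.

The master seed is split deterministically into per-stage seeds through
``numpy.random.SeedSequence`` so partial reruns stay reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import ensemble as ens
from . import evaluation as ev
from . import features as feat
from . import qc as qcmod
from . import reconstruct as rec
from . import synth
from .grids import CellDayIndex, GridDomain, RasterField
from .qc import Monitor

log = logging.getLogger("airstack")

__all__ = ["DEFAULT_CONFIG", "PipelineRun", "run_pipeline", "load_config"]

_STAGE_ORDER = ("simulate", "qc", "stage1", "stage2", "features",
                "train", "evaluate", "predict")

DEFAULT_CONFIG: dict = {
    "world": {},            # overrides for synth.WorldParams
    "observations": {},     # overrides for synth.ObsParams
    "qc": {"min_hours": 18, "min_per_month": 9, "min_days_per_year": 270,
           "outlier_lower": 0.0, "outlier_upper": 1000.0},
    "stage1": {"budget": 10, "n_folds": 10, "tune_folds": 3},
    "stage2": {"targets": {"PM25": "aod", "NO2": "no2"},
               "satellite": {}, "rf_params": {"n_estimators": 100},
               "n_folds": 10, "max_train_rows": 20000},
    "train": {"pollutants": ["NO2", "PM10", "PM25"],
              "learners": ["RF", "XGB", "LGBM", "ridge", "lasso"],
              "budget": 10, "n_folds": 10, "tune_folds": 3,
              "rf_params": {}},
    "predict": {"n_days": None},    # None = all days
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config merged over the defaults; validate keys."""
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_CONFIG) - {"seed", "out_dir"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return _deep_merge(DEFAULT_CONFIG, user)


def _config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(master), _STAGE_ORDER.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _fields_to_dataset(fields: Mapping[str, RasterField]) -> xr.Dataset:
    return xr.Dataset({name: f.to_dataarray() for name, f in fields.items()})


def _dataset_to_fields(ds: xr.Dataset, grid: GridDomain) -> dict[str, RasterField]:
    return {name: RasterField.from_dataarray(ds[name], grid=grid) for name in ds.data_vars}


class PipelineRun:
    """One pipeline execution rooted at ``out_dir``."""

    def __init__(self, config: dict, out_dir: str | Path, seed: int = 0):
        self.config = _deep_merge(DEFAULT_CONFIG, config or {})
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(seed)
        self.world_params = replace(synth.WorldParams(), **self.config["world"])
        self.obs_params = replace(synth.ObsParams(), **self.config["observations"])
        self._world: synth.SyntheticWorld | None = None
        self.manifest: dict = {
            "config_hash": _config_hash(self.config),
            "master_seed": self.seed,
            "stage_seeds": {s: _stage_seed(self.seed, s) for s in _STAGE_ORDER},
            "stages": {},
        }

    # ---------------------------------------------------------- helpers
    def _path(self, name: str) -> Path:
        return self.out / name

    def _require(self, name: str, producer: str) -> Path:
        p = self._path(name)
        if not p.exists():
            raise FileNotFoundError(
                f"missing artifact {name!r}; rerun the {producer!r} stage first")
        return p

    def _record(self, stage: str, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        with open(self._path("manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2)

    def _done(self, *names: str) -> bool:
        return all(self._path(n).exists() for n in names)

    @property
    def world(self) -> synth.SyntheticWorld:
        """The synthetic world, regenerated deterministically on demand."""
        if self._world is None:
            self._world = synth.generate_world(self.world_params,
                                               seed=_stage_seed(self.seed, "simulate"))
        return self._world

    # ----------------------------------------------------------- stages
    def simulate(self, force: bool = False) -> list[Path]:
        outs = ["world.nc", "monitors.csv", "roads.geojson", "observations.csv"]
        if not force and self._done(*outs):
            log.info("simulate: outputs exist, skipping")
            return [self._path(n) for n in outs]
        world = self.world
        ds = _fields_to_dataset({**world.true_fields, **world.covariate_fields})
        ds.attrs.update({"crs": world.grid.crs, "cell_size_m": world.grid.cell,
                         "x0": world.grid.x0, "y0": world.grid.y0})
        ds.to_netcdf(self._path("world.nc"), engine="scipy")
        pd.DataFrame([asdict(m) for m in world.monitors]).to_csv(
            self._path("monitors.csv"), index=False)
        geo = {"type": "FeatureCollection", "features": [
            {"type": "Feature", "properties": {"class": cls},
             "geometry": {"type": "LineString", "coordinates": [list(c) for c in coords]}}
            for coords, cls in world.roads]}
        with open(self._path("roads.geojson"), "w") as fh:
            json.dump(geo, fh)
        obs = synth.sample_monitor_observations(world, self.obs_params)
        obs.to_csv(self._path("observations.csv"), index=False)
        paths = [self._path(n) for n in outs]
        self._record("simulate", paths)
        return paths

    def qc(self, force: bool = False) -> Path:
        out = self._path("daily_qc.csv")
        if not force and out.exists():
            log.info("qc: outputs exist, skipping")
            return out
        cfg = self.config["qc"]
        obs = pd.read_csv(self._require("observations.csv", "simulate"),
                          parse_dates=["date"] if not self.obs_params.hourly else ["time"])
        rules = qcmod.OutlierRules(lower=cfg["outlier_lower"], upper=cfg["outlier_upper"])
        if self.obs_params.hourly:
            kept, rejected = qcmod.remove_outliers(obs, rules)
            daily = pd.concat([
                qcmod.aggregate_hourly_to_daily(kept[kept["pollutant"] == p],
                                                min_hours=cfg["min_hours"])
                for p in kept["pollutant"].unique()
            ], ignore_index=True)
        else:
            renamed = obs.rename(columns={"date": "time"})
            kept, rejected = qcmod.remove_outliers(renamed, rules)
            daily = kept.rename(columns={"time": "date"})
            daily["n_hours"] = 24
        daily, cov_log = qcmod.filter_monitor_coverage(
            daily, min_per_month=cfg["min_per_month"],
            min_days_per_year=cfg["min_days_per_year"])
        monitors = _read_monitors(self._require("monitors.csv", "simulate"))
        daily, dropped = qcmod.deduplicate_monitors(daily, monitors)
        daily.to_csv(out, index=False)
        rejected.to_csv(self._path("qc_rejected.csv"), index=False)
        cov_log.to_csv(self._path("qc_coverage_log.csv"), index=False)
        self._record("qc", [out])
        return out

    def stage1(self, force: bool = False) -> Path:
        out = self._path("augmented.csv")
        if not force and out.exists():
            log.info("stage1: outputs exist, skipping")
            return out
        cfg = self.config["stage1"]
        seed = _stage_seed(self.seed, "stage1")
        daily = pd.read_csv(self._require("daily_qc.csv", "qc"), parse_dates=["date"])
        monitors = _read_monitors(self._require("monitors.csv", "simulate"))
        table = _stage1_table(daily, monitors)
        train = table.dropna(subset=["PM25", "PM10"])
        year = int(pd.DatetimeIndex(train["date"]).year[0])
        model = rec.fit_stage1(train, year=year, budget=cfg["budget"], seed=seed,
                               n_folds=cfg["n_folds"], tune_folds=cfg["tune_folds"])
        augmented = rec.augment_pm25(table, model)
        augmented.to_csv(out, index=False)
        with open(self._path("stage1_cv.json"), "w") as fh:
            json.dump({k: v.as_dict() for k, v in model.cv.items()}, fh, indent=2)
        self._record("stage1", [out, self._path("stage1_cv.json")])
        return out

    def stage2(self, force: bool = False) -> list[Path]:
        cfg = self.config["stage2"]
        outs = [f"gapfilled_{pol}.nc" for pol in cfg["targets"]]
        if not force and self._done(*outs, "stage2_cv.json"):
            log.info("stage2: outputs exist, skipping")
            return [self._path(n) for n in outs]
        seed = _stage_seed(self.seed, "stage2")
        world = self.world
        cv_all = {}
        paths = []
        for pol, kind in cfg["targets"].items():
            sat = synth.degrade_to_satellite(
                world, replace(synth.SatParams(pollutant=pol), **cfg["satellite"]))
            predictors = _stage2_predictors(world, kind)
            model = rec.fit_stage2_gapfill(
                sat.fine, predictors, kind=kind, year=int(world.dates.year[0]),
                seed=seed, rf_params=cfg["rf_params"], n_folds=cfg["n_folds"],
                max_train_rows=cfg["max_train_rows"])
            filled, source = rec.apply_gapfill(sat.fine, model, predictors)
            ds = xr.Dataset({filled.name or f"SAT_{pol}": filled.to_dataarray(),
                             "source_filled": (("time", "y", "x"), source == "filled")})
            p = self._path(f"gapfilled_{pol}.nc")
            ds.to_netcdf(p, engine="scipy")
            paths.append(p)
            cv_all[pol] = {k: v.as_dict() for k, v in model.cv.items()}
        with open(self._path("stage2_cv.json"), "w") as fh:
            json.dump(cv_all, fh, indent=2)
        self._record("stage2", paths + [self._path("stage2_cv.json")])
        return paths

    def features(self, force: bool = False) -> list[Path]:
        pollutants = self.config["train"]["pollutants"]
        outs = [f"features_{pol}.csv" for pol in pollutants]
        if not force and self._done(*outs):
            log.info("features: outputs exist, skipping")
            return [self._path(n) for n in outs]
        world = self.world
        monitors = _read_monitors(self._require("monitors.csv", "simulate"))
        augmented = pd.read_csv(self._require("augmented.csv", "stage1"),
                                parse_dates=["date"])
        paths = []
        for pol in pollutants:
            table = build_training_table(world, monitors, augmented, pol)
            p = self._path(f"features_{pol}.csv")
            table.to_csv(p, index=False)
            paths.append(p)
        self._record("features", paths)
        return paths

    def train(self, force: bool = False) -> list[Path]:
        cfg = self.config["train"]
        outs = []
        for pol in cfg["pollutants"]:
            outs += [f"model_{pol}.pkl", f"cv_{pol}.csv"]
        if not force and self._done(*outs):
            log.info("train: outputs exist, skipping")
            return [self._path(n) for n in outs]
        seed = _stage_seed(self.seed, "train")
        paths = []
        for pol in cfg["pollutants"]:
            table = pd.read_csv(self._require(f"features_{pol}.csv", "features"),
                                parse_dates=["date"])
            X, y, groups, feature_cols = _training_matrices(table)
            specs = _learner_specs(cfg, seed)
            tuned = []
            for s in specs:
                t, _ = ens.tune_learner(s, X, y, groups, budget=cfg["budget"],
                                        n_folds=cfg["tune_folds"], seed=seed)
                tuned.append(t)
            folds = ev.make_folds(list(pd.unique(groups)), n_folds=cfg["n_folds"],
                                  seed=seed, kind="monitor")
            cvres = ens.crossvalidate_superlearner(tuned, X, y, groups, folds)
            sl = ens.fit_final(tuned, X, y, groups, folds, oof=cvres["oof"])
            sl.save(self._path(f"model_{pol}.pkl"))
            cv_table = cvres["oof"].copy()
            cv_table["ensemble"] = cvres["ensemble"]
            cv_table["observed"] = y
            cv_table["monitor_id"] = groups
            cv_table["date"] = table["date"].to_numpy()
            cv_table.to_csv(self._path(f"cv_{pol}.csv"), index=False)
            with open(self._path(f"manifest_{pol}.json"), "w") as fh:
                json.dump(sl.manifest, fh, indent=2)
            paths += [self._path(f"model_{pol}.pkl"), self._path(f"cv_{pol}.csv")]
        self._record("train", paths)
        return paths

    def evaluate(self, force: bool = False) -> Path:
        out = self._path("reports.csv")
        if not force and out.exists():
            log.info("evaluate: outputs exist, skipping")
            return out
        rows = []
        for pol in self.config["train"]["pollutants"]:
            cv = pd.read_csv(self._require(f"cv_{pol}.csv", "train"), parse_dates=["date"])
            learner_cols = [c for c in cv.columns
                            if c not in ("fold", "observed", "monitor_id", "date")]
            for col in learner_cols:
                reports = ev.decompose_performance(cv["observed"], cv[col],
                                                   cv["monitor_id"])
                for scope, rep in reports.items():
                    rows.append({"pollutant": pol, "learner": col, **rep.as_dict()})
        pd.DataFrame(rows).to_csv(out, index=False)
        self._record("evaluate", [out])
        return out

    def predict(self, force: bool = False) -> list[Path]:
        cfg = self.config["predict"]
        pollutants = self.config["train"]["pollutants"]
        outs = [f"predictions_{pol}.nc" for pol in pollutants]
        if not force and self._done(*outs):
            log.info("predict: outputs exist, skipping")
            return [self._path(n) for n in outs]
        world = self.world
        monitors = _read_monitors(self._require("monitors.csv", "simulate"))
        augmented = pd.read_csv(self._require("augmented.csv", "stage1"),
                                parse_dates=["date"])
        dates = world.dates if cfg["n_days"] is None else world.dates[: cfg["n_days"]]
        paths = []
        for pol in pollutants:
            sl = ens.SuperLearner.load(self._require(f"model_{pol}.pkl", "train"))
            table = build_prediction_table(world, monitors, augmented, pol, dates)
            fld = ens.predict_grid(sl, table, world.grid, dates)
            fld.to_dataarray().to_dataset(name=pol).to_netcdf(
                self._path(f"predictions_{pol}.nc"), engine="scipy")
            paths.append(self._path(f"predictions_{pol}.nc"))
        self._record("predict", paths)
        return paths

    def run_all(self, force: bool = False) -> dict:
        t0 = time.time()
        self.simulate(force)
        self.qc(force)
        self.stage1(force)
        self.stage2(force)
        self.features(force)
        self.train(force)
        self.evaluate(force)
        self.predict(force)
        self.manifest["wall_seconds"] = round(time.time() - t0, 2)
        with open(self._path("manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2)
        return self.manifest


def run_pipeline(config_path: str | Path | None, out_dir: str | Path,
                 seed: int = 0, force: bool = False) -> dict:
    """Execute the full pipeline from a YAML config; returns the manifest."""
    config = load_config(config_path)
    run = PipelineRun(config, out_dir, seed=seed)
    return run.run_all(force=force)


# ------------------------------------------------------------------ plumbing

def _read_monitors(path: Path) -> list[Monitor]:
    df = pd.read_csv(path)
    return [Monitor(id=r["id"], network=r["network"], x=float(r["x"]), y=float(r["y"]),
                    type=r["type"]) for _, r in df.iterrows()]


def _stage1_table(daily: pd.DataFrame, monitors: list[Monitor]) -> pd.DataFrame:
    """Wide monitor-day table with PM10/PM25 columns and the Stage-1 predictors."""
    wide = daily.pivot_table(index=["monitor_id", "date"], columns="pollutant",
                             values="value", aggfunc="first").reset_index()
    wide.columns.name = None
    for pol in ("PM10", "PM25"):
        if pol not in wide.columns:
            wide[pol] = np.nan
    minfo = pd.DataFrame([{"monitor_id": m.id, "x": m.x, "y": m.y, "type": m.type}
                          for m in monitors])
    wide = wide.merge(minfo, on="monitor_id", how="left")
    cal = feat.temporal_features(wide["date"])
    for c in cal.columns:
        wide[c] = cal[c].to_numpy()
    return wide


def _stage2_predictors(world: synth.SyntheticWorld, kind: str) -> dict[str, RasterField]:
    names = (rec.AOD_PREDICTORS if kind == "aod" else rec.NO2_PREDICTORS)
    return {n: world.covariate_fields[n] for n in names if n not in ("yday", "x", "y")}


def _feature_layers(world: synth.SyntheticWorld, pollutant: str
                    ) -> tuple[dict[str, RasterField], dict[str, RasterField]]:
    """Static and daily gridded layers entering the Stage-3 predictor set."""
    cov = world.covariate_fields
    grid = world.grid
    rh, wspd, wdir = feat.derive_meteorology(cov["T2M"].values, cov["DEW"].values,
                                             cov["U10"].values, cov["V10"].values)
    daily = {
        "T2M": cov["T2M"], "BLH": cov["BLH"], "BLH12": cov["BLH12"],
        "MSLP": cov["MSLP"],
        "RH": RasterField(grid, rh, dates=world.dates, name="RH", units="%"),
        "WSPD": RasterField(grid, wspd, dates=world.dates, name="WSPD", units="m/s"),
        "WDIR": RasterField(grid, wdir, dates=world.dates, name="WDIR", units="deg"),
        f"CTM_{pollutant}": cov[f"CTM_{pollutant}"],
    }
    if pollutant == "NO2":
        daily["CAMS_NO2"] = cov["CAMS_NO2"]
    else:
        daily["CAMS_AOD_055"] = cov["CAMS_AOD_055"]
    static = {n: cov[n] for n in ("ELEV", "ELEV_SD", "URBAN", "VEGET", "ROADS")}
    return static, daily


def _monitor_spatial_features(targets_xy: np.ndarray, monitors: list[Monitor],
                              annual_means: dict[str, float],
                              exclude_ids: list | None) -> pd.DataFrame:
    """The six monitor-based predictors: 4 LOO-IDW surfaces + 2 distances."""
    out = {}
    for tf, tag in (("hotspot", "H"), ("background", "B")):
        for power in (1, 2):
            out[f"IDW_{tag}{power}"] = feat.loo_idw_surface(
                targets_xy, monitors, annual_means, tf, power, exclude_ids=exclude_ids)
        out[f"DIST_{tag}"] = feat.nearest_monitor_distance(
            targets_xy, monitors, tf, exclude_ids=exclude_ids)
    return pd.DataFrame(out)


def _target_column(pollutant: str) -> str:
    return {"NO2": "NO2", "PM10": "PM10", "PM25": "PM25"}[pollutant]


def build_training_table(world: synth.SyntheticWorld, monitors: list[Monitor],
                         augmented: pd.DataFrame, pollutant: str) -> pd.DataFrame:
    """Monitor-day feature table with the observed target in ``value``."""
    col = _target_column(pollutant)
    units = augmented.dropna(subset=[col]).copy()
    units = units.rename(columns={col: "value"})
    keep = ["monitor_id", "date", "value", "x", "y", "type"]
    if pollutant == "PM25" and "pm25_source" in units.columns:
        keep.append("pm25_source")
    units = units[keep]
    static, daily = _feature_layers(world, pollutant)
    table = feat.assemble_feature_table(units, static, daily)
    annual = units.groupby("monitor_id")["value"].mean().to_dict()
    msf = _monitor_spatial_features(table[["x", "y"]].to_numpy(float), monitors,
                                   annual, exclude_ids=table["monitor_id"].tolist())
    table = pd.concat([table, msf], axis=1)
    table["type_code"] = table["type"].map({"background": 0, "hotspot": 1})
    return table


def build_prediction_table(world: synth.SyntheticWorld, monitors: list[Monitor],
                           augmented: pd.DataFrame, pollutant: str,
                           dates: pd.DatetimeIndex) -> pd.DataFrame:
    """Cell-day feature table with the same schema as the training table."""
    grid = world.grid
    index = CellDayIndex.for_grid(grid, dates)
    cells = np.tile(index.cell_ids, len(dates))
    date_col = np.repeat(np.asarray(dates), len(index.cell_ids))
    x, y = grid.cell_centers(cells)
    units = pd.DataFrame({"cell": cells, "date": date_col, "x": x, "y": y})
    static, daily = _feature_layers(world, pollutant)
    table = feat.assemble_feature_table(units, static, daily)
    col = _target_column(pollutant)
    annual = augmented.dropna(subset=[col]).groupby("monitor_id")[col].mean().to_dict()
    msf = _monitor_spatial_features(table[["x", "y"]].to_numpy(float), monitors,
                                    annual, exclude_ids=None)
    table = pd.concat([table, msf], axis=1)
    table["type_code"] = 0  # grid cells are treated as background locations
    return table


def _training_matrices(table: pd.DataFrame):
    drop = {"monitor_id", "cell", "date", "value", "type", "pm25_source"}
    feature_cols = [c for c in table.columns if c not in drop]
    X = table[feature_cols].astype(float)
    y = table["value"].to_numpy(dtype=float)
    groups = table["monitor_id"].to_numpy()
    return X, y, groups, feature_cols


def _learner_specs(cfg: Mapping, seed: int) -> list[ens.BaseLearnerSpec]:
    specs = []
    for i, algo in enumerate(cfg["learners"]):
        hp = cfg.get("rf_params", {}) if algo == "RF" else {}
        specs.append(ens.BaseLearnerSpec(algo, hyperparameters=hp, seed=seed + i))
    return specs
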