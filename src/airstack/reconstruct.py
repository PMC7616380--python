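"""Stage 1 and Stage 2 data reconstruction.

Stage 1 augments the sparse PM2.5 monitor record: for monitor-days with
a co-located PM10 value but no PM2.5 observation, a yearly gradient-
boosted model (LGBM) predicts PM2.5 from

    PM2.5(m,t) = f(PM10(m,t), type_m, yday_t, dow_t, month_t,
                   weekend_t, x_m, y_m)

tuned by random hyperparameter search and validated with 10-fold
monitor-blocked cross-validation.  Observed values are never modified;
every record carries a provenance flag (observed / reconstructed).

Stage 2 gap-fills cloud-masked satellite products from gap-free coarse
proxies with a yearly random forest, validated by 10-fold cell-blocked
cross-validation (all days of a cell share a fold).  The AOD target uses
exactly the five coarse AOD wavelengths plus yday and the cell
coordinates; the columnar-NO2 target uses boundary-layer height, mean
sea-level pressure, temperature, road density, elevation, urban and
vegetation fractions plus yday and coordinates.  For years where the
satellite NO2 product is absent entirely, the coarse proxy can be
substituted directly via :func:`substitute_with_proxy`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .ensemble import BaseLearnerSpec, _fit, tune_learner
from .evaluation import (PerformanceReport, decompose_performance, make_folds,
                         performance_from_pairs)
from .grids import RasterField

__all__ = [
    "STAGE1_PREDICTORS",
    "AOD_PREDICTORS",
    "NO2_PREDICTORS",
    "Stage1Model",
    "GapFillModel",
    "fit_stage1",
    "augment_pm25",
    "fit_stage2_gapfill",
    "apply_gapfill",
    "substitute_with_proxy",
]

STAGE1_PREDICTORS = ("PM10", "type", "yday", "dow", "month", "weekend", "x", "y")

AOD_PREDICTORS = ("CAMS_AOD_047", "CAMS_AOD_055", "CAMS_AOD_067",
                  "CAMS_AOD_0865", "CAMS_AOD_124", "yday", "x", "y")
NO2_PREDICTORS = ("BLH", "MSLP", "T2M", "ROADS", "ELEV", "URBAN", "VEGET",
                  "yday", "x", "y")

_TYPE_CODE = {"background": 0, "hotspot": 1}


@dataclass
class Stage1Model:
    """Yearly PM10→PM2.5 reconstruction model with its blocked-CV report."""

    model: object
    spec: BaseLearnerSpec
    year: int
    cv: dict[str, PerformanceReport]
    tuning_log: pd.DataFrame

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = _stage1_matrix(table)
        return self.model.predict(X.to_numpy(dtype=float))


def _stage1_matrix(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STAGE1_PREDICTORS if c not in table.columns]
    if missing:
        raise ValueError(f"stage-1 table lacks predictors {missing}; "
                         f"required exactly {list(STAGE1_PREDICTORS)}")
    X = table[list(STAGE1_PREDICTORS)].copy()
    if X["type"].dtype == object:
        X["type"] = X["type"].map(_TYPE_CODE)
        if X["type"].isna().any():
            raise ValueError("monitor type must be 'hotspot' or 'background'")
    return X


def fit_stage1(
    train: pd.DataFrame,
    year: int,
    budget: int = 100,
    seed: int = 0,
    n_folds: int = 10,
    tune_folds: int = 3,
    space: Mapping | None = None,
) -> Stage1Model:
    """Fit the yearly Stage-1 model on monitor-days with both pollutants.

    ``train`` needs columns ``monitor_id, PM25, PM10, type, yday, dow,
    month, weekend, x, y``.  Rows with missing PM10 or PM25 are rejected
    (the caller selects co-located pairs).  The CV report is computed
    from 10-fold monitor-blocked out-of-fold predictions of the selected
    configuration.
    """
    if train["PM10"].isna().any():
        raise ValueError("training rows with missing PM10 are not allowed")
    if train["PM25"].isna().any():
        raise ValueError("training rows with missing PM25 are not allowed")
    monitors = pd.unique(train["monitor_id"])
    if len(monitors) < n_folds:
        raise ValueError(
            f"need >= {n_folds} monitors with co-located PM10/PM2.5 pairs, got {len(monitors)}")
    X = _stage1_matrix(train)
    y = train["PM25"].to_numpy(dtype=float)
    groups = train["monitor_id"].to_numpy()

    spec = BaseLearnerSpec("LGBM", seed=seed)
    tuned, log = tune_learner(spec, X, y, groups, budget=budget,
                              space=space, n_folds=tune_folds, seed=seed)

    folds = make_folds(list(monitors), n_folds=n_folds, seed=seed, kind="monitor")
    fold_of_row = folds.fold_of(groups)
    oof = np.empty(len(X))
    for f in range(1, folds.n_folds + 1):
        test = fold_of_row == f
        model = _fit(tuned, X[~test], y[~test], groups[~test])
        oof[test] = model.predict(X[test].to_numpy(dtype=float))
    cv = decompose_performance(y, oof, groups)

    final = _fit(tuned, X, y, groups)
    return Stage1Model(model=final, spec=tuned, year=year, cv=cv, tuning_log=log)


def augment_pm25(records: pd.DataFrame, model: Stage1Model) -> pd.DataFrame:
    """Fill PM2.5 gaps at monitors with co-located PM10.

    Monitor-days with observed PM2.5 keep their observation (flag
    ``observed``); days with PM10 but no PM2.5 get a model prediction
    (flag ``reconstructed``); days with neither stay absent (flag
    ``absent``).  Input rows are passed through unmodified otherwise.
    """
    out = records.copy()
    has_obs = out["PM25"].notna()
    fillable = ~has_obs & out["PM10"].notna()
    out["pm25_source"] = np.where(has_obs, "observed",
                                  np.where(fillable, "reconstructed", "absent"))
    if fillable.any():
        out.loc[fillable, "PM25"] = model.predict(out.loc[fillable])
    return out


@dataclass
class GapFillModel:
    """Yearly satellite gap-filling model (random forest)."""

    target: str
    kind: str                       # "aod" | "no2"
    predictors: tuple[str, ...]
    model: object
    spec: BaseLearnerSpec
    year: int
    cv: dict[str, PerformanceReport]

    def required_predictors(self) -> tuple[str, ...]:
        return AOD_PREDICTORS if self.kind == "aod" else NO2_PREDICTORS


def _required(kind: str) -> tuple[str, ...]:
    if kind == "aod":
        return AOD_PREDICTORS
    if kind == "no2":
        return NO2_PREDICTORS
    raise ValueError(f"kind must be 'aod' or 'no2', got {kind!r}")


def _stage2_matrix(field: RasterField, predictors: Mapping[str, RasterField],
                   kind: str, sel: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix at the selected (day, y, x) boolean positions.

    Returns (X, flat cell ids) with columns in the target's fixed order.
    """
    required = _required(kind)
    layer_names = [p for p in required if p not in ("yday", "x", "y")]
    missing = [p for p in layer_names if p not in predictors]
    extra = [p for p in predictors if p not in layer_names]
    if missing or extra:
        raise ValueError(
            f"{kind} gap-filling requires exactly predictors {list(required)}; "
            f"missing {missing}, unexpected {extra}")
    nt, ny, nx = field.values.shape
    ti, iy, ix = np.nonzero(sel)
    grid = field.grid
    cols = {}
    for name in layer_names:
        layer = predictors[name]
        cols[name] = layer.values[ti, iy, ix] if layer.is_temporal else layer.values[iy, ix]
    yday = field.dates.dayofyear.to_numpy()
    cols["yday"] = yday[ti].astype(float)
    cols["x"] = grid.x0 + (ix + 0.5) * grid.cell
    cols["y"] = grid.y0 + (iy + 0.5) * grid.cell
    X = pd.DataFrame(cols)[list(required)]
    return X, grid.flat_index(iy, ix)


def fit_stage2_gapfill(
    target: RasterField,
    predictors: Mapping[str, RasterField],
    kind: str,
    year: int,
    seed: int = 0,
    rf_params: Mapping | None = None,
    n_folds: int = 10,
    max_train_rows: int | None = None,
    compute_cv: bool = True,
) -> GapFillModel:
    """Fit the yearly gap-filling random forest on unmasked cell-days.

    The CV report comes from ``n_folds``-fold cell-blocked out-of-fold
    predictions (all days of a cell share a fold); ``compute_cv=False``
    skips it when only the fitted model is needed.  ``max_train_rows``
    optionally subsamples the training rows (seeded) to bound cost.
    """
    if target.mask is None:
        observed = np.ones_like(target.values, dtype=bool)
    else:
        observed = ~target.mask
    if not observed.any():
        raise ValueError("all cell-days are masked; nothing to train on")
    X, cells = _stage2_matrix(target, predictors, kind, observed)
    y = target.values[observed]
    if max_train_rows is not None and len(X) > max_train_rows:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(X), size=max_train_rows, replace=False))
        X, y, cells = X.iloc[keep].reset_index(drop=True), y[keep], cells[keep]

    spec = BaseLearnerSpec("RF", hyperparameters=dict(rf_params or {}), seed=seed)
    cv: dict[str, PerformanceReport] = {}
    if compute_cv:
        unique_cells = pd.unique(cells)
        folds = make_folds(list(unique_cells), n_folds=min(n_folds, len(unique_cells)),
                           seed=seed, kind="cell")
        fold_of_row = folds.fold_of(cells)
        oof = np.empty(len(X))
        for f in range(1, folds.n_folds + 1):
            test = fold_of_row == f
            model = _fit(spec, X[~test], y[~test], cells[~test])
            oof[test] = model.predict(X[test].to_numpy(dtype=float))
        cv["overall"] = performance_from_pairs(y, oof)

    final = _fit(spec, X, y, cells)
    return GapFillModel(target=target.name, kind=kind,
                        predictors=_required(kind), model=final, spec=spec,
                        year=year, cv=cv)


def apply_gapfill(
    field: RasterField,
    model: GapFillModel,
    predictors: Mapping[str, RasterField],
) -> tuple[RasterField, np.ndarray]:
    """Replace masked cell-days with model predictions.

    Unmasked values are retained verbatim (bitwise).  Returns the
    complete field and a per-cell-day source flag array with values
    ``"observed"`` / ``"filled"``.
    """
    source = np.full(field.values.shape, "observed", dtype="<U8")
    if field.mask is None or not field.mask.any():
        return RasterField(field.grid, field.values.copy(), dates=field.dates,
                           name=field.name, units=field.units), source
    X, _ = _stage2_matrix(field, predictors, model.kind, field.mask)
    pred = model.model.predict(X.to_numpy(dtype=float))
    values = field.values.copy()
    values[field.mask] = pred
    source[field.mask] = "filled"
    return RasterField(field.grid, values, dates=field.dates,
                       name=field.name, units=field.units), source


def substitute_with_proxy(field: RasterField, proxy: RasterField) -> tuple[RasterField, np.ndarray]:
    """Fill masked cell-days directly with a gap-free proxy field.

    Used for years where the satellite product is entirely absent and a
    coarse reanalysis column is carried in its place.  The proxy must
    already be on the field's grid and dates.
    """
    if proxy.values.shape != field.values.shape:
        raise ValueError("proxy must be on the same grid and dates as the field")
    source = np.full(field.values.shape, "observed", dtype="<U8")
    values = field.values.copy()
    if field.mask is not None and field.mask.any():
        values[field.mask] = proxy.values[field.mask]
        source[field.mask] = "proxy"
    return RasterField(field.grid, values, dates=field.dates,
                       name=field.name, units=field.units), source
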