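"""Predictor engineering for the exposure models.

Covers the spatial predictors (leave-one-out inverse-distance-weighted
surfaces of monitor annual means, distance to the nearest hotspot /
background monitor, road density, raster harmonisation to the 1-km grid),
derived meteorology (relative humidity via the Magnus formula, wind speed
and direction from the u/v components), calendar features, and the
assembly of the unit-by-feature table shared by training (monitor-day)
and prediction (cell-day).

All distances are planar Euclidean metres in the projected CRS of the
grid.  Missing feature entries are always explicit ``NaN``, never silent
zeros.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box

from .grids import GridDomain, RasterField
from .qc import Monitor

__all__ = [
    "loo_idw_surface",
    "nearest_monitor_distance",
    "derive_meteorology",
    "temporal_features",
    "harmonize_to_grid",
    "road_density",
    "assemble_feature_table",
    "check_schema_match",
]

# August–Roche–Magnus saturation vapour-pressure coefficients (over water)
_MAGNUS_A = 17.625
_MAGNUS_B = 243.04  # °C


def _select(monitors: Sequence[Monitor], type_filter: str) -> list[Monitor]:
    sel = [m for m in monitors if m.type == type_filter]
    return sel


def loo_idw_surface(
    targets: np.ndarray,
    monitors: Sequence[Monitor],
    annual_means: Mapping[str, float],
    type_filter: str,
    power: int,
    exclude_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Inverse-distance-weighted surface of monitor annual means.

    value(p) = Σₘ d(p,m)⁻ᵏ Aₘ / Σₘ d(p,m)⁻ᵏ over monitors of the requested
    type, where Aₘ is monitor m's annual mean and k the power (1 or 2).
    When the query point *is* a monitor (``exclude_ids[i]`` gives its id),
    that monitor is left out of its own surface (leave-one-out).  A query
    with no remaining monitor is flagged missing (NaN).  A query exactly
    on a remaining monitor takes that monitor's value (the IDW limit).

    Parameters
    ----------
    targets : (n, 2) array of projected (x, y) metres.
    annual_means : mapping monitor id -> annual mean (μg/m³); monitors
        without a mean are ignored.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if power not in (1, 2):
        raise ValueError(f"power must be 1 or 2, got {power}")
    sel = [m for m in _select(monitors, type_filter) if m.id in annual_means]
    if not sel:
        raise ValueError(f"no {type_filter} monitor with an annual mean available")
    mx = np.array([m.x for m in sel])
    my = np.array([m.y for m in sel])
    mv = np.array([float(annual_means[m.id]) for m in sel])
    mids = np.array([m.id for m in sel])

    d = np.hypot(targets[:, [0]] - mx[None, :], targets[:, [1]] - my[None, :])
    include = np.ones_like(d, dtype=bool)
    if exclude_ids is not None:
        exclude_ids = np.asarray(exclude_ids, dtype=object)
        include &= exclude_ids[:, None] != mids[None, :]

    out = np.full(len(targets), np.nan)
    with np.errstate(divide="ignore"):
        w = np.where(include, d ** (-float(power)), 0.0)
    for i in range(len(targets)):
        wi = w[i]
        if not include[i].any():
            continue  # flagged missing: excluded the only available monitor(s)
        exact = include[i] & (d[i] == 0.0)
        if exact.any():
            out[i] = mv[exact].mean()
        else:
            out[i] = np.dot(wi, mv) / wi.sum()
    return out


def nearest_monitor_distance(
    targets: np.ndarray,
    monitors: Sequence[Monitor],
    type_filter: str,
    exclude_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Distance (m) to the nearest monitor of the given type.

    A monitor querying its own feature (``exclude_ids``) is excluded, so
    the distance is to the *next* nearest monitor of the type.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    sel = _select(monitors, type_filter)
    if not sel:
        raise ValueError(f"no {type_filter} monitors available")
    mx = np.array([m.x for m in sel])
    my = np.array([m.y for m in sel])
    mids = np.array([m.id for m in sel])
    d = np.hypot(targets[:, [0]] - mx[None, :], targets[:, [1]] - my[None, :])
    if exclude_ids is not None:
        excl = np.asarray(exclude_ids, dtype=object)[:, None] == mids[None, :]
        d = np.where(excl, np.inf, d)
    out = d.min(axis=1)
    if np.isinf(out).any():
        raise ValueError("a query point excluded every monitor of the requested type")
    return out


def _saturation_vp(temp_c: np.ndarray) -> np.ndarray:
    """Magnus saturation vapour pressure (hPa) at temperature °C."""
    return 6.1094 * np.exp(_MAGNUS_A * temp_c / (_MAGNUS_B + temp_c))


def derive_meteorology(
    t2m: np.ndarray,
    dewpoint: np.ndarray,
    u_wind: np.ndarray,
    v_wind: np.ndarray,
    tolerance: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Derive (RH %, wind speed m/s, wind direction °) from reanalysis fields.

    RH is the Magnus saturation-vapour-pressure ratio es(Td)/es(T), clipped
    to (0, 100].  Wind direction follows the meteorological convention:
    the direction the wind blows FROM, 0° = north, clockwise (so u=-1, v=0
    — air moving west — is an easterly, 90°).  Temperatures in kelvin.
    """
    t2m = np.asarray(t2m, dtype=float)
    dewpoint = np.asarray(dewpoint, dtype=float)
    if np.any(dewpoint > t2m + tolerance):
        raise ValueError("dewpoint exceeds temperature beyond tolerance")
    t_c = t2m - 273.15
    td_c = np.minimum(dewpoint, t2m) - 273.15
    rh = 100.0 * _saturation_vp(td_c) / _saturation_vp(t_c)
    rh = np.clip(rh, None, 100.0)
    u = np.asarray(u_wind, dtype=float)
    v = np.asarray(v_wind, dtype=float)
    speed = np.hypot(u, v)
    direction = (180.0 + np.degrees(np.arctan2(u, v))) % 360.0
    return rh, speed, direction


def temporal_features(dates: Iterable) -> pd.DataFrame:
    """Calendar features: day of year, day of week (1=Mon..7=Sun), month,
    weekend indicator (Saturday/Sunday)."""
    idx = pd.DatetimeIndex(pd.to_datetime(list(dates)))
    dow = idx.dayofweek + 1
    return pd.DataFrame({
        "yday": idx.dayofyear.astype(int),
        "dow": dow.astype(int),
        "month": idx.month.astype(int),
        "weekend": (dow >= 6).astype(int),
    })


def _fine_to_grid_index(src: RasterField, grid: GridDomain) -> tuple[np.ndarray, np.ndarray]:
    """Map each source cell centre to a flat target-cell id; returns
    (flat ids, flattened source values mask of in-extent cells)."""
    sx, sy = src.grid.meshgrid()
    inside = grid.contains(sx.ravel(), sy.ravel())
    if not inside.any():
        raise ValueError("source raster extent is disjoint from the target grid")
    iy, ix = grid.cell_of(sx.ravel()[inside], sy.ravel()[inside])
    return grid.flat_index(iy, ix), inside


def harmonize_to_grid(
    src: RasterField,
    grid: GridDomain,
    method: str,
    classes: Sequence | None = None,
):
    """Resample a native-resolution raster onto the modelling grid.

    Finer-than-grid sources are aggregated per target cell with the
    requested statistic: ``mean`` (continuous), ``sum`` (lengths/counts),
    ``sd`` (e.g. elevation roughness), or ``fraction`` (per-class cover
    fractions of a categorical raster; returns a dict class -> field).
    Coarser-than-grid sources are assigned by nearest-cell sampling at
    the target cell centres (``method="nearest"``, or automatically when
    the source cell is larger than the target cell).
    """
    if src.is_temporal:
        slices = [
            harmonize_to_grid(
                RasterField(src.grid, src.values[t], name=src.name), grid, method, classes
            )
            for t in range(src.n_times)
        ]
        if isinstance(slices[0], dict):
            raise ValueError("fraction harmonisation of temporal rasters is not supported")
        return RasterField(grid, np.stack([s.values for s in slices]), dates=src.dates,
                           name=src.name, units=src.units)

    coarser = src.grid.cell > grid.cell
    if method == "nearest" or (coarser and method != "fraction"):
        gx, gy = grid.meshgrid()
        sxmin, symin, sxmax, symax = src.grid.extent
        if gx.max() < sxmin or gx.min() > sxmax or gy.max() < symin or gy.min() > symax:
            raise ValueError("source raster extent is disjoint from the target grid")
        ix = np.clip(np.floor((gx - src.grid.x0) / src.grid.cell).astype(int), 0, src.grid.nx - 1)
        iy = np.clip(np.floor((gy - src.grid.y0) / src.grid.cell).astype(int), 0, src.grid.ny - 1)
        return RasterField(grid, src.values[iy, ix], name=src.name, units=src.units)

    flat, inside = _fine_to_grid_index(src, grid)
    vals = src.values.ravel()[inside]
    n = grid.n_cells
    count = np.bincount(flat, minlength=n).astype(float)
    with np.errstate(invalid="ignore"):
        if method == "mean":
            s = np.bincount(flat, weights=vals, minlength=n)
            out = np.where(count > 0, s / np.maximum(count, 1), np.nan)
        elif method == "sum":
            out = np.bincount(flat, weights=vals, minlength=n)
            out = np.where(count > 0, out, np.nan)
        elif method == "sd":
            s = np.bincount(flat, weights=vals, minlength=n)
            s2 = np.bincount(flat, weights=vals ** 2, minlength=n)
            m = s / np.maximum(count, 1)
            var = np.maximum(s2 / np.maximum(count, 1) - m ** 2, 0.0)
            out = np.where(count > 0, np.sqrt(var), np.nan)
        elif method == "fraction":
            cls = classes if classes is not None else np.unique(vals)
            result = {}
            for c in cls:
                cc = np.bincount(flat, weights=(vals == c).astype(float), minlength=n)
                frac = np.where(count > 0, cc / np.maximum(count, 1), np.nan)
                result[c] = RasterField(grid, frac.reshape(grid.ny, grid.nx),
                                        name=f"{src.name}_frac_{c}")
            return result
        else:
            raise ValueError(f"unknown harmonisation method {method!r}")
    return RasterField(grid, out.reshape(grid.ny, grid.nx), name=src.name, units=src.units)


def road_density(
    segments: Sequence[tuple[Sequence[tuple[float, float]], str]],
    grid: GridDomain,
) -> dict[str, RasterField]:
    """Summed clipped road length (m) per grid cell, split by road class.

    ``segments`` is a sequence of (coordinate list, class label) polylines
    already in the grid projection.  Lengths are conserved: the per-class
    totals over all cells equal the in-extent polyline lengths.
    """
    classes = sorted({cls for _, cls in segments})
    out = {c: np.zeros((grid.ny, grid.nx)) for c in classes}
    for coords, cls in segments:
        line = LineString(coords)
        xmin, ymin, xmax, ymax = line.bounds
        gxmin, gymin, gxmax, gymax = grid.extent
        ix0 = max(int(np.floor((xmin - grid.x0) / grid.cell)), 0)
        ix1 = min(int(np.floor((xmax - grid.x0) / grid.cell)), grid.nx - 1)
        iy0 = max(int(np.floor((ymin - grid.y0) / grid.cell)), 0)
        iy1 = min(int(np.floor((ymax - grid.y0) / grid.cell)), grid.ny - 1)
        if xmax < gxmin or xmin > gxmax or ymax < gymin or ymin > gymax:
            continue
        for iy in range(iy0, iy1 + 1):
            for ix in range(ix0, ix1 + 1):
                cell_box = box(grid.x0 + ix * grid.cell, grid.y0 + iy * grid.cell,
                               grid.x0 + (ix + 1) * grid.cell, grid.y0 + (iy + 1) * grid.cell)
                seg = line.intersection(cell_box)
                if not seg.is_empty:
                    out[cls][iy, ix] += seg.length
    return {c: RasterField(grid, v, name=f"roads_{c}", units="m") for c, v in out.items()}


def _sample_layer(layer: RasterField, iy: np.ndarray, ix: np.ndarray,
                  dates: pd.DatetimeIndex) -> np.ndarray:
    """Layer values at (cell, date) units; out-of-coverage dates and masked
    cell-days become NaN."""
    if layer.is_temporal:
        ti = layer.dates.get_indexer(dates.normalize())
        out = np.full(len(iy), np.nan)
        ok = ti >= 0
        out[ok] = layer.values[ti[ok], iy[ok], ix[ok]]
        if layer.mask is not None:
            masked = np.zeros(len(iy), dtype=bool)
            masked[ok] = layer.mask[ti[ok], iy[ok], ix[ok]]
            out[masked] = np.nan
        return out
    out = layer.values[iy, ix].astype(float)
    if layer.mask is not None:
        out[layer.mask[iy, ix]] = np.nan
    return out


def assemble_feature_table(
    units: pd.DataFrame,
    static_layers: Mapping[str, RasterField],
    daily_layers: Mapping[str, RasterField],
    add_calendar: bool = True,
) -> pd.DataFrame:
    """Join gridded feature layers onto a table of units.

    ``units`` needs columns ``x, y, date`` plus any identifier columns
    (``monitor_id`` or ``cell``), which are passed through.  One output
    row per input row; every layer contributes one column; missingness is
    explicit NaN.  The same function builds the training (monitor-day)
    and prediction (cell-day) tables so the schemas match by construction.
    """
    for col in ("x", "y", "date"):
        if col not in units.columns:
            raise ValueError(f"units table lacks required column {col!r}")
    layers = {**static_layers, **daily_layers}
    if not layers:
        raise ValueError("no feature layers supplied")
    grids = {id(l.grid): l.grid for l in layers.values()}
    grid = next(iter(grids.values()))
    for g in grids.values():
        if (g.x0, g.y0, g.cell, g.nx, g.ny) != (grid.x0, grid.y0, grid.cell, grid.nx, grid.ny):
            raise ValueError("all feature layers must share the same grid")

    out = units.reset_index(drop=True).copy()
    dates = pd.DatetimeIndex(pd.to_datetime(out["date"]))
    iy, ix = grid.cell_of(out["x"].to_numpy(float), out["y"].to_numpy(float))
    for name, layer in layers.items():
        out[name] = _sample_layer(layer, iy, ix, dates)
    if add_calendar:
        cal = temporal_features(dates)
        for col in cal.columns:
            out[col] = cal[col].to_numpy()
    return out


def check_schema_match(train: pd.DataFrame, predict: pd.DataFrame,
                       feature_cols: Sequence[str]) -> None:
    """Raise if the prediction table lacks any training feature column."""
    missing = [c for c in feature_cols if c not in predict.columns]
    if missing:
        raise ValueError(f"prediction table is missing feature columns: {missing}")
    extra_na = [c for c in feature_cols if predict[c].isna().all() and not train[c].isna().all()]
    if extra_na:
        raise ValueError(f"prediction features entirely missing: {extra_na}")
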