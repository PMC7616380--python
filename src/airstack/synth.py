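"""Synthetic study world for end-to-end pipeline testing.

Generates a small self-contained domain with the statistical structure
the pipeline assumes from its real inputs: a smooth regional pollutant
background, localized traffic peaks along generator-chosen road
polylines (so the NO2-like pollutant has finer-scale structure than the
PM-like ones), a shared meteorology-driven daily signal, spatially
clustered hotspot monitors and dispersed background monitors, gap-free
coarse reanalysis-like proxies, and satellite-like products with
spatially correlated cloud gaps.

Construction of the truth fields (per pollutant, pre-positivity):

    latent(x, y, t) = base + b_bg * B(x, y) + b_peak * P(x, y)
                      + b_urb * U(x, y) + b_tmp * s(t) + noise

where B is a low-rank sum of smooth radial-basis bumps (cheap stand-in
for a Gaussian-process draw), P a road-proximity kernel, U an urban
kernel, and s(t) a seasonal cosine plus an AR(1) meteorology driver.
PM2.5 is additionally coupled to the clean PM10 latent so that the
PM10→PM2.5 reconstruction stage has signal to learn.  Positivity is
enforced with a softplus transform (no point mass at zero).

All randomness flows from a single seed through named
``numpy.random.SeedSequence`` substreams (one per generated field, in
the fixed order of ``_STREAMS``), so regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .features import road_density
from .grids import GridDomain, RasterField
from .qc import Monitor

__all__ = [
    "PollutantParams",
    "WorldParams",
    "ObsParams",
    "SatParams",
    "SyntheticWorld",
    "SatelliteProduct",
    "generate_world",
    "sample_monitor_observations",
    "degrade_to_satellite",
    "spatial_correlogram",
]

POLLUTANTS = ("NO2", "PM10", "PM25")

# fixed substream order — renaming or reordering breaks reproducibility
_STREAMS = (
    "background", "background2", "roads", "urban", "elevation",
    "driver", "met", "ctm", "cams", "monitors",
    "noise_NO2", "noise_PM10", "noise_PM25",
)

CAMS_WAVELENGTHS = ("047", "055", "067", "0865", "124")


@dataclass(frozen=True)
class PollutantParams:
    """Amplitudes (μg/m³) of the latent components of one pollutant."""

    base: float
    background_amp: float
    peak_amp: float
    urban_amp: float
    temporal_amp: float
    noise_sd: float


@dataclass(frozen=True)
class WorldParams:
    """Generating configuration; the defaults are the study conditions
    used throughout the test-bed (40×40 km grid, one year, 60 monitors
    of which a third are hotspots clustered near roads/the urban core)."""

    nx: int = 40
    ny: int = 40
    cell: float = 1000.0
    x0: float = 0.0
    y0: float = 0.0
    start: str = "2018-01-01"
    n_days: int = 365
    n_hotspot: int = 20
    n_background: int = 40
    # smooth regional background: low-rank radial-basis surface
    bg_n_bumps: int = 12
    bg_corr_length: float = 8000.0  # m
    # roads and localized peaks
    n_roads: int = 4
    road_kernel_width: float = 1200.0  # m
    urban_kernel_width: float = 7000.0  # m
    # shared temporal (meteorology-driven) signal
    seasonal_amp: float = 1.0
    ar_phi: float = 0.8
    ar_sd: float = 0.4
    pollutants: Mapping[str, PollutantParams] = field(default_factory=lambda: {
        "NO2": PollutantParams(base=18.0, background_amp=4.0, peak_amp=10.0,
                               urban_amp=4.0, temporal_amp=5.0, noise_sd=1.0),
        "PM10": PollutantParams(base=16.0, background_amp=5.0, peak_amp=2.0,
                                urban_amp=2.0, temporal_amp=4.0, noise_sd=1.0),
        "PM25": PollutantParams(base=9.0, background_amp=1.0, peak_amp=0.0,
                                urban_amp=0.0, temporal_amp=0.5, noise_sd=0.6),
    })
    pm25_from_pm10: float = 0.55  # coupling of PM2.5 to the clean PM10 latent
    # covariate noise levels
    ctm_smooth_sigma: float = 2.0  # grid cells
    ctm_gain: float = 0.9
    ctm_bias: float = 1.0
    ctm_noise_sd: float = 0.5
    met_noise_sd: float = 0.5
    cams_coarse_factor: int = 5
    crs: str = "synthetic-BNG"


@dataclass(frozen=True)
class ObsParams:
    """Observation-process configuration for monitor sampling."""

    noise_sd: float = 1.0
    missing_fraction: float = 0.05
    hotspot_bias: float = 2.0
    hourly: bool = False
    hourly_sd: float = 2.0
    drop_hours: int = 0


@dataclass(frozen=True)
class SatParams:
    """Satellite degradation: proxy = gain × truth + noise under
    spatially correlated cloud gaps; plus a coarse gap-free proxy."""

    pollutant: str = "PM25"
    gain: float = 1.0
    noise_sd: float = 0.0
    cloud_fraction: float = 0.4
    cloud_corr_length: float = 6000.0  # m
    coarse_factor: int = 5
    coarse_bias: float = 0.5
    coarse_noise_sd: float = 0.0


@dataclass
class SyntheticWorld:
    grid: GridDomain
    dates: pd.DatetimeIndex
    true_fields: dict[str, RasterField]
    covariate_fields: dict[str, RasterField]
    monitors: list[Monitor]
    roads: list[tuple[list[tuple[float, float]], str]]
    seed: int
    params: WorldParams
    components: dict  # latent pieces kept for verification


@dataclass
class SatelliteProduct:
    fine: RasterField        # gain×truth + noise, cloud-masked
    coarse: RasterField      # block-averaged truth + bias, gap-free


def _softplus(x: np.ndarray) -> np.ndarray:
    # numerically stable log(1 + exp(x)); ~identity for x >> 0, > 0 always
    return np.logaddexp(0.0, x)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _bump_surface(rng: np.random.Generator, grid: GridDomain, n_bumps: int,
                  corr_length: float) -> np.ndarray:
    """Zero-mean, unit-sd sum of Gaussian radial-basis bumps."""
    gx, gy = grid.meshgrid()
    xmin, ymin, xmax, ymax = grid.extent
    cx = rng.uniform(xmin, xmax, n_bumps)
    cy = rng.uniform(ymin, ymax, n_bumps)
    width = rng.uniform(0.6, 1.4, n_bumps) * corr_length
    amp = rng.normal(size=n_bumps)
    surf = np.zeros_like(gx)
    for k in range(n_bumps):
        surf += amp[k] * np.exp(-((gx - cx[k]) ** 2 + (gy - cy[k]) ** 2) / (2 * width[k] ** 2))
    sd = surf.std()
    if sd > 0:
        surf = (surf - surf.mean()) / sd
    return surf


def _road_polylines(rng: np.random.Generator, grid: GridDomain,
                    n_roads: int) -> list[tuple[list[tuple[float, float]], str]]:
    """Fixed grid-spanning polylines: horizontals/verticals plus a diagonal."""
    xmin, ymin, xmax, ymax = grid.extent
    roads = []
    for k in range(n_roads):
        cls = "highway" if k % 2 == 0 else "secondary"
        if k % 2 == 0:
            yy = rng.uniform(ymin + 0.1 * (ymax - ymin), ymax - 0.1 * (ymax - ymin))
            roads.append(([(xmin, yy), (xmax, yy)], cls))
        else:
            xx = rng.uniform(xmin + 0.1 * (xmax - xmin), xmax - 0.1 * (xmax - xmin))
            roads.append(([(xx, ymin), (xx, ymax)], cls))
    roads.append(([(xmin, ymin), (xmax, ymax)], "secondary"))
    return roads


def _proximity_kernel(grid: GridDomain, roads, width: float) -> np.ndarray:
    """exp(−d²/2w²) with d the distance to the nearest road polyline."""
    import shapely
    from shapely.geometry import LineString

    gx, gy = grid.meshgrid()
    pts = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]))
    d = np.full(gx.size, np.inf)
    for coords, _ in roads:
        d = np.minimum(d, shapely.distance(pts, LineString(coords)))
    return np.exp(-(d.reshape(gx.shape) ** 2) / (2 * width ** 2))


def _block_average(values: np.ndarray, factor: int) -> np.ndarray:
    """Block mean over factor×factor windows; ragged edges use partial blocks."""
    ny, nx = values.shape
    cy = -(-ny // factor)
    cx = -(-nx // factor)
    out = np.empty((cy, cx))
    for j in range(cy):
        for i in range(cx):
            out[j, i] = values[j * factor:(j + 1) * factor, i * factor:(i + 1) * factor].mean()
    return out


def generate_world(params: WorldParams = WorldParams(), seed: int = 0) -> SyntheticWorld:
    """Generate a synthetic world; bit-identical under (params, seed)."""
    grid = GridDomain(params.x0, params.y0, params.cell, params.nx, params.ny, params.crs)
    if params.n_days < 1:
        raise ValueError("n_days must be >= 1")
    dates = pd.date_range(params.start, periods=params.n_days, freq="D")
    rngs = _streams(seed)

    background = _bump_surface(rngs["background"], grid, params.bg_n_bumps, params.bg_corr_length)
    background2 = _bump_surface(rngs["background2"], grid, params.bg_n_bumps, params.bg_corr_length)
    roads = _road_polylines(rngs["roads"], grid, params.n_roads)
    peak = _proximity_kernel(grid, roads, params.road_kernel_width)

    xmin, ymin, xmax, ymax = grid.extent
    ucx = rngs["urban"].uniform(xmin + 0.25 * (xmax - xmin), xmax - 0.25 * (xmax - xmin))
    ucy = rngs["urban"].uniform(ymin + 0.25 * (ymax - ymin), ymax - 0.25 * (ymax - ymin))
    gx, gy = grid.meshgrid()
    urban = np.exp(-(((gx - ucx) ** 2 + (gy - ucy) ** 2)) / (2 * params.urban_kernel_width ** 2))

    # shared temporal driver: winter-peaking seasonal cosine + AR(1)
    doy = dates.dayofyear.to_numpy()
    seasonal = params.seasonal_amp * np.cos(2 * np.pi * (doy - 15) / 365.25)
    ar = np.zeros(params.n_days)
    eps = rngs["driver"].normal(scale=params.ar_sd, size=params.n_days)
    for t in range(1, params.n_days):
        ar[t] = params.ar_phi * ar[t - 1] + eps[t]
    ar[0] = eps[0]
    driver = seasonal + ar

    # clean latents (no noise), then truth = softplus(latent + noise)
    def clean_latent(p: PollutantParams, spatial_extra: np.ndarray | None = None) -> np.ndarray:
        spatial = (p.base + p.background_amp * (background if spatial_extra is None else background2)
                   + p.peak_amp * peak + p.urban_amp * urban)
        if spatial_extra is not None:
            spatial = spatial + spatial_extra
        return spatial[None, :, :] + p.temporal_amp * driver[:, None, None]

    pp = params.pollutants
    latent_no2 = clean_latent(pp["NO2"])
    latent_pm10 = clean_latent(pp["PM10"])
    coupling = params.pm25_from_pm10 * (latent_pm10 - pp["PM10"].base)
    latent_pm25 = clean_latent(pp["PM25"], spatial_extra=np.zeros_like(background)) + coupling

    latents = {"NO2": latent_no2, "PM10": latent_pm10, "PM25": latent_pm25}
    true_fields: dict[str, RasterField] = {}
    for pol in POLLUTANTS:
        noise = rngs[f"noise_{pol}"].normal(scale=pp[pol].noise_sd or 1e-300,
                                            size=latents[pol].shape) if pp[pol].noise_sd > 0 \
            else np.zeros_like(latents[pol])
        true_fields[pol] = RasterField(grid, _softplus(latents[pol] + noise),
                                       dates=dates, name=pol, units="ug/m3")

    # --- covariates -------------------------------------------------------
    met = rngs["met"]
    shape = (params.n_days, params.ny, params.nx)

    def met_field(base_t: np.ndarray, spatial: np.ndarray, name: str, units: str) -> RasterField:
        vals = base_t[:, None, None] + spatial[None, :, :] + met.normal(
            scale=params.met_noise_sd, size=shape)
        return RasterField(grid, vals, dates=dates, name=name, units=units)

    t2m = met_field(283.15 - 6.0 * driver, 0.5 * background, "T2M", "K")
    dew = RasterField(grid, t2m.values - met.uniform(0.5, 6.0, size=shape),
                      dates=dates, name="DEW", units="K")
    blh = met_field(np.maximum(600.0 - 140.0 * driver, 80.0), np.zeros_like(background),
                    "BLH", "m")
    blh = RasterField(grid, np.maximum(blh.values, 30.0), dates=dates, name="BLH", units="m")
    blh12 = RasterField(grid, blh.values * 1.25 + met.normal(scale=20.0, size=shape),
                        dates=dates, name="BLH12", units="m")
    mslp = met_field(101325.0 + 400.0 * ar, np.zeros_like(background), "MSLP", "Pa")
    u10 = met_field(met.normal(scale=2.0, size=params.n_days), np.zeros_like(background),
                    "U10", "m/s")
    v10 = met_field(met.normal(scale=2.0, size=params.n_days), np.zeros_like(background),
                    "V10", "m/s")

    ctm = rngs["ctm"]
    covs: dict[str, RasterField] = {
        "T2M": t2m, "DEW": dew, "BLH": blh, "BLH12": blh12, "MSLP": mslp,
        "U10": u10, "V10": v10,
    }
    for pol in POLLUTANTS:
        smoothed = np.stack([
            gaussian_filter(true_fields[pol].values[t], sigma=params.ctm_smooth_sigma)
            for t in range(params.n_days)
        ])
        covs[f"CTM_{pol}"] = RasterField(
            grid,
            params.ctm_gain * smoothed + params.ctm_bias
            + ctm.normal(scale=params.ctm_noise_sd, size=shape),
            dates=dates, name=f"CTM_{pol}", units="ug/m3")

    # gap-free coarse reanalysis proxies (CAMS-like): block-averaged truth,
    # rescaled per wavelength, nearest-upsampled back to the grid
    cams = rngs["cams"]
    f = params.cams_coarse_factor
    aod_gain = {"047": 1.0, "055": 0.9, "067": 0.75, "0865": 0.6, "124": 0.45}
    pm25_coarse = np.stack([_block_average(true_fields["PM25"].values[t], f)
                            for t in range(params.n_days)])
    no2_coarse = np.stack([_block_average(true_fields["NO2"].values[t], f)
                           for t in range(params.n_days)])
    up_y = np.minimum(np.arange(params.ny) // f, pm25_coarse.shape[1] - 1)
    up_x = np.minimum(np.arange(params.nx) // f, pm25_coarse.shape[2] - 1)
    for z in CAMS_WAVELENGTHS:
        coarse = aod_gain[z] * pm25_coarse / 30.0 + 0.02 \
            + cams.normal(scale=0.005, size=pm25_coarse.shape)
        covs[f"CAMS_AOD_{z}"] = RasterField(grid, coarse[:, up_y][:, :, up_x],
                                            dates=dates, name=f"CAMS_AOD_{z}", units="1")
    cams_no2 = no2_coarse / 30.0 + 0.05 + cams.normal(scale=0.01, size=no2_coarse.shape)
    covs["CAMS_NO2"] = RasterField(grid, cams_no2[:, up_y][:, :, up_x],
                                   dates=dates, name="CAMS_NO2", units="1")

    # statics
    elev_rng = rngs["elevation"]
    elev = 120.0 + 80.0 * _bump_surface(elev_rng, grid, params.bg_n_bumps, params.bg_corr_length)
    covs["ELEV"] = RasterField(grid, elev, name="ELEV", units="m")
    covs["ELEV_SD"] = RasterField(grid, np.abs(elev_rng.normal(scale=10.0, size=elev.shape)),
                                  name="ELEV_SD", units="m")
    urban_frac = np.clip(0.8 * urban + 0.25 * peak, 0.0, 1.0)
    covs["URBAN"] = RasterField(grid, urban_frac, name="URBAN", units="1")
    covs["VEGET"] = RasterField(grid, np.clip(0.9 - urban_frac, 0.0, 1.0),
                                name="VEGET", units="1")
    dens = road_density(roads, grid)
    total_roads = sum(f.values for f in dens.values())
    covs["ROADS"] = RasterField(grid, total_roads, name="ROADS", units="m")

    # --- monitors ---------------------------------------------------------
    mon_rng = rngs["monitors"]
    weights_hot = (peak * np.exp(-(((gx - ucx) ** 2 + (gy - ucy) ** 2))
                                 / (2 * (1.5 * params.urban_kernel_width) ** 2))).ravel()
    weights_hot = weights_hot / weights_hot.sum()
    n_cells = grid.n_cells
    n_mon = params.n_hotspot + params.n_background
    if n_mon > n_cells:
        raise ValueError("more monitors than grid cells")
    hot_cells = mon_rng.choice(n_cells, size=params.n_hotspot, replace=False, p=weights_hot)
    remaining = np.setdiff1d(np.arange(n_cells), hot_cells)
    bg_cells = mon_rng.choice(remaining, size=params.n_background, replace=False)
    networks = ["AURN", "AQE", "KCL", "SAQN", "WAQN"]
    monitors: list[Monitor] = []
    for k, c in enumerate(hot_cells):
        x, y = grid.cell_centers(np.array([c]))
        monitors.append(Monitor(id=f"HS{k:03d}", network=networks[k % 5],
                                x=float(x[0]), y=float(y[0]), type="hotspot"))
    for k, c in enumerate(bg_cells):
        x, y = grid.cell_centers(np.array([c]))
        monitors.append(Monitor(id=f"BG{k:03d}", network=networks[k % 5],
                                x=float(x[0]), y=float(y[0]), type="background"))
    coords = {(m.x, m.y) for m in monitors}
    if len(coords) != len(monitors):
        raise ValueError("duplicate monitor coordinates")
    for m in monitors:
        if not grid.contains(np.array([m.x]), np.array([m.y]))[0]:
            raise AssertionError("monitor outside grid extent")

    components = {
        "background": background,
        "background2": background2,
        "peak": peak,
        "urban": urban,
        "driver": driver,
        "spatial": {
            "NO2": latent_no2[0] - pp["NO2"].temporal_amp * driver[0],
            "PM10": latent_pm10[0] - pp["PM10"].temporal_amp * driver[0],
            "PM25": latent_pm25[0]
            - (pp["PM25"].temporal_amp + params.pm25_from_pm10 * pp["PM10"].temporal_amp)
            * driver[0],
        },
    }
    return SyntheticWorld(grid=grid, dates=dates, true_fields=true_fields,
                          covariate_fields=covs, monitors=monitors, roads=roads,
                          seed=seed, params=params, components=components)


def sample_monitor_observations(
    world: SyntheticWorld,
    obs_params: ObsParams = ObsParams(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw monitor observations from the world's truth fields.

    Daily value = truth at the monitor's cell (+ additive hotspot bias for
    hotspot monitors) + Gaussian noise; a per-monitor fraction of days is
    deleted at random.  With ``hourly=True`` each daily value is expanded
    to 24 hourly values (daily + hourly noise) with ``drop_hours`` hours
    deleted at random per day, to exercise the completeness QC.

    Returns a tidy table (monitor_id, date/time, pollutant, value).
    """
    if not world.monitors:
        raise ValueError("world has no monitors")
    if not 0.0 <= obs_params.missing_fraction <= 1.0:
        raise ValueError("missing_fraction must be in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence([world.seed, 0x0B5]) if seed is None else seed)
    rows = []
    n_days = len(world.dates)
    for m in world.monitors:
        iy, ix = world.grid.cell_of(np.array([m.x]), np.array([m.y]))
        for pol in POLLUTANTS:
            truth = world.true_fields[pol].values[:, iy[0], ix[0]]
            vals = truth + (obs_params.hotspot_bias if m.type == "hotspot" else 0.0)
            if obs_params.noise_sd > 0:
                vals = vals + rng.normal(scale=obs_params.noise_sd, size=n_days)
            keep = rng.random(n_days) >= obs_params.missing_fraction
            rows.append(pd.DataFrame({
                "monitor_id": m.id,
                "date": world.dates[keep],
                "pollutant": pol,
                "value": vals[keep],
            }))
    daily = pd.concat(rows, ignore_index=True)
    if not obs_params.hourly:
        return daily

    hourly_rows = []
    for _, r in daily.iterrows():
        n_keep = 24 - obs_params.drop_hours
        hours = np.sort(rng.choice(24, size=n_keep, replace=False))
        hourly_rows.append(pd.DataFrame({
            "monitor_id": r["monitor_id"],
            "time": pd.Timestamp(r["date"]) + pd.to_timedelta(hours, unit="h"),
            "pollutant": r["pollutant"],
            "value": r["value"] + rng.normal(scale=obs_params.hourly_sd, size=n_keep),
        }))
    return pd.concat(hourly_rows, ignore_index=True)


def degrade_to_satellite(
    world: SyntheticWorld,
    sat_params: SatParams = SatParams(),
    seed: int | None = None,
) -> SatelliteProduct:
    """Degrade a truth field into a cloud-masked satellite-like product
    plus a coarse gap-free reanalysis-like proxy.

    The cloud mask is built per day by thresholding a spatially smoothed
    Gaussian noise field at the (1 − cloud_fraction) quantile, so the
    realized masked share matches the configured fraction and the gaps
    form correlated blobs.
    """
    sp = sat_params
    if sp.gain <= 0:
        raise ValueError("gain must be > 0")
    if not 0.0 <= sp.cloud_fraction < 1.0:
        raise ValueError("cloud_fraction must be in [0, 1); 1 leaves nothing observable")
    truth = world.true_fields[sp.pollutant]
    rng = np.random.default_rng(
        np.random.SeedSequence([world.seed, 0x5A7]) if seed is None else seed)
    n_days, ny, nx = truth.values.shape

    vals = sp.gain * truth.values
    if sp.noise_sd > 0:
        vals = vals + rng.normal(scale=sp.noise_sd, size=vals.shape)
    mask = np.zeros_like(vals, dtype=bool)
    if sp.cloud_fraction > 0:
        sigma = sp.cloud_corr_length / world.grid.cell
        for t in range(n_days):
            smooth = gaussian_filter(rng.normal(size=(ny, nx)), sigma=sigma)
            mask[t] = smooth > np.quantile(smooth, 1.0 - sp.cloud_fraction)
    fine = RasterField(world.grid, vals, dates=truth.dates, mask=mask,
                       name=f"SAT_{sp.pollutant}", units=truth.units)

    f = sp.coarse_factor
    coarse_vals = np.stack([_block_average(truth.values[t], f) for t in range(n_days)])
    coarse_vals = coarse_vals + sp.coarse_bias
    if sp.coarse_noise_sd > 0:
        coarse_vals = coarse_vals + rng.normal(scale=sp.coarse_noise_sd, size=coarse_vals.shape)
    coarse_grid = GridDomain(world.grid.x0, world.grid.y0, world.grid.cell * f,
                             coarse_vals.shape[2], coarse_vals.shape[1], world.grid.crs)
    coarse = RasterField(coarse_grid, coarse_vals, dates=truth.dates,
                         name=f"COARSE_{sp.pollutant}", units=truth.units)
    return SatelliteProduct(fine=fine, coarse=coarse)


def spatial_correlogram(values: np.ndarray, grid: GridDomain,
                        bin_width: float = 2000.0, max_lag: float | None = None,
                        ) -> pd.DataFrame:
    """Binned empirical spatial correlation of a static surface.

    Returns a DataFrame (lag_m, correlation, n_pairs) over cell-centre
    pairs, for checking that the background decorrelates with distance.
    """
    gx, gy = grid.meshgrid()
    x, y, v = gx.ravel(), gy.ravel(), np.asarray(values).ravel()
    v = v - v.mean()
    var = (v ** 2).mean()
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    d = np.hypot(dx, dy)
    prod = v[:, None] * v[None, :]
    iu = np.triu_indices(len(v), k=1)
    d, prod = d[iu], prod[iu]
    if max_lag is None:
        max_lag = d.max() / 2
    bins = np.arange(0, max_lag + bin_width, bin_width)
    idx = np.digitize(d, bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        sel = idx == b
        if sel.sum() > 0:
            rows.append(((bins[b] + bins[b + 1]) / 2, prod[sel].mean() / var, int(sel.sum())))
    return pd.DataFrame(rows, columns=["lag_m", "correlation", "n_pairs"])
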