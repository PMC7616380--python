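"""Grid domain and raster containers for the 1-km modelling grid.

The study domain is a regular square grid in a projected planar CRS
(British-National-Grid-like: eastings/northings in metres).  Cell indexing
is row-major from the origin corner: the origin ``(x0, y0)`` is the
south-west corner of cell ``(iy=0, ix=0)``; ``ix`` counts columns eastward,
``iy`` counts rows northward, and the flat cell id is ``iy * nx + ix``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["GridDomain", "RasterField", "CellDayIndex"]


@dataclass(frozen=True)
class GridDomain:
    """A regular square grid in a projected planar CRS.

    Parameters
    ----------
    x0, y0 : float
        Easting/northing of the south-west corner of the grid, in metres.
    cell : float
        Cell edge length in metres (1000 for the 1-km target grid).
    nx, ny : int
        Number of columns (east) and rows (north).
    crs : str
        Free-text CRS label; distances are always computed as planar
        Euclidean metres.
    """

    x0: float
    y0: float
    cell: float
    nx: int
    ny: int
    crs: str = "planar-metres"

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError(f"cell size must be > 0, got {self.cell}")
        if self.nx < 1 or self.ny < 1:
            raise ValueError(f"grid dimensions must be >= 1, got nx={self.nx}, ny={self.ny}")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.cell

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid rectangle."""
        return (self.x0, self.y0, self.x0 + self.nx * self.cell, self.y0 + self.ny * self.cell)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        return (np.asarray(x) >= xmin) & (np.asarray(x) < xmax) & (np.asarray(y) >= ymin) & (np.asarray(y) < ymax)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices (iy, ix) of the cells containing points (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(self.contains(x, y)):
            raise ValueError("point(s) outside the grid extent")
        ix = np.floor((x - self.x0) / self.cell).astype(np.int64)
        iy = np.floor((y - self.y0) / self.cell).astype(np.int64)
        return iy, ix

    def flat_index(self, iy: np.ndarray, ix: np.ndarray) -> np.ndarray:
        return np.asarray(iy, dtype=np.int64) * self.nx + np.asarray(ix, dtype=np.int64)

    def unflatten(self, flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        flat = np.asarray(flat, dtype=np.int64)
        return flat // self.nx, flat % self.nx

    def cell_centers(self, flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        iy, ix = self.unflatten(flat)
        return self.x0 + (ix + 0.5) * self.cell, self.y0 + (iy + 0.5) * self.cell

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (ny, nx) arrays of cell-centre eastings and northings."""
        return np.meshgrid(self.x_centers, self.y_centers)


@dataclass
class RasterField:
    """A gridded variable, static ``(ny, nx)`` or temporal ``(nt, ny, nx)``.

    ``mask`` marks missing cell(-day)s with ``True``; ``mask is None`` means
    gap-free.  Values under the mask are unspecified and must not be read.
    """

    grid: GridDomain
    values: np.ndarray
    dates: pd.DatetimeIndex | None = None
    mask: np.ndarray | None = None
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dates is not None:
            self.dates = pd.DatetimeIndex(self.dates)
            expected = (len(self.dates), self.grid.ny, self.grid.nx)
        else:
            expected = (self.grid.ny, self.grid.nx)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != expected {expected}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")

    @property
    def is_temporal(self) -> bool:
        return self.dates is not None

    @property
    def n_times(self) -> int:
        return len(self.dates) if self.dates is not None else 1

    def observed_values(self) -> np.ndarray:
        if self.mask is None:
            return self.values
        return self.values[~self.mask]

    def at_cells(self, iy: np.ndarray, ix: np.ndarray, it: int | None = None) -> np.ndarray:
        """Values at cell indices; for temporal fields ``it`` selects the day."""
        if self.is_temporal:
            if it is None:
                return self.values[:, iy, ix]
            return self.values[it, iy, ix]
        return self.values[iy, ix]

    def to_dataarray(self) -> xr.DataArray:
        coords: dict = {
            "x": ("x", self.grid.x_centers),
            "y": ("y", self.grid.y_centers),
        }
        if self.is_temporal:
            dims = ("time", "y", "x")
            coords["time"] = ("time", self.dates)
        else:
            dims = ("y", "x")
        vals = self.values
        if self.mask is not None:
            vals = np.where(self.mask, np.nan, vals)
        da = xr.DataArray(vals, dims=dims, coords=coords, name=self.name or "field")
        da.attrs["units"] = self.units
        da.attrs["crs"] = self.grid.crs
        da.attrs["cell_size_m"] = self.grid.cell
        return da

    @classmethod
    def from_dataarray(cls, da: xr.DataArray, grid: GridDomain | None = None) -> "RasterField":
        if grid is None:
            xs = np.asarray(da["x"])
            ys = np.asarray(da["y"])
            cell = float(xs[1] - xs[0]) if xs.size > 1 else float(ys[1] - ys[0])
            grid = GridDomain(
                x0=float(xs[0] - cell / 2),
                y0=float(ys[0] - cell / 2),
                cell=cell,
                nx=xs.size,
                ny=ys.size,
                crs=str(da.attrs.get("crs", "planar-metres")),
            )
        dates = pd.DatetimeIndex(da["time"]) if "time" in da.dims else None
        vals = np.asarray(da, dtype=float)
        mask = np.isnan(vals)
        if not mask.any():
            mask = None
        return cls(grid=grid, values=np.nan_to_num(vals), dates=dates,
                   mask=mask, name=str(da.name or ""), units=str(da.attrs.get("units", "")))


@dataclass
class CellDayIndex:
    """The unit index for full-grid prediction: every (cell, day) pair.

    Built lazily — the full cross product is only materialised chunk by
    chunk, so constructing the index for a national grid × a full year is
    cheap while ``len()`` still reports the exact number of cell-value
    slots to be predicted.
    """

    cell_ids: np.ndarray
    dates: pd.DatetimeIndex

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        self.dates = pd.DatetimeIndex(self.dates)
        if self.cell_ids.ndim != 1:
            raise ValueError("cell_ids must be one-dimensional")
        if np.unique(self.cell_ids).size != self.cell_ids.size:
            raise ValueError("cell_ids must be unique")

    def __len__(self) -> int:
        return int(self.cell_ids.size) * len(self.dates)

    @property
    def n_slots(self) -> int:
        return len(self)

    def iter_days(self) -> Iterator[tuple[pd.Timestamp, np.ndarray]]:
        for date in self.dates:
            yield date, self.cell_ids

    @classmethod
    def for_grid(cls, grid: GridDomain, dates: pd.DatetimeIndex) -> "CellDayIndex":
        return cls(cell_ids=np.arange(grid.n_cells, dtype=np.int64), dates=dates)

    @classmethod
    def for_cell_count(cls, n_cells: int, dates: pd.DatetimeIndex) -> "CellDayIndex":
        if n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        return cls(cell_ids=np.arange(int(n_cells), dtype=np.int64), dates=dates)
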