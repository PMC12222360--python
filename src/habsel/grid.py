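"""Raster grid primitives and plain-text geospatial I/O.

All analysis layers live on a single shared north-up grid in projected
meters.  Rasters are exchanged as ESRI ASCII grids (``.asc``) and vector
features as GeoJSON with coordinates in the same projected CRS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import mapping, shape


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid.

    Parameters
    ----------
    ncols, nrows
        Grid dimensions in cells.
    cellsize
        Cell edge length in meters (square cells).
    x0, y0
        Coordinates of the lower-left corner of the grid, in meters.
    """

    ncols: int
    nrows: int
    cellsize: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.ncols <= 0 or self.nrows <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cellsize <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def width(self) -> float:
        return self.ncols * self.cellsize

    @property
    def height(self) -> float:
        return self.nrows * self.cellsize

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.x0 + self.width, self.y0 + self.height)

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.ncols) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        """Cell-center y coordinates for each row, row 0 = northernmost."""
        return self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center coordinate arrays, each of shape (nrows, ncols)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (x, y).

        Points on the outer edge are clipped into the nearest cell.
        """
        col = np.clip(((np.asarray(x) - self.x0) / self.cellsize).astype(int), 0, self.ncols - 1)
        row_from_bottom = np.clip(
            ((np.asarray(y) - self.y0) / self.cellsize).astype(int), 0, self.nrows - 1
        )
        row = self.nrows - 1 - row_from_bottom
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)


@dataclass
class CovariateStack:
    """Named covariate layers sharing one grid.

    ``standardization`` maps layer name -> (mean, sd) for layers that have
    been z-scored, so model coefficients can be back-transformed.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            self.layers[name] = self._check(name, arr)

    def _check(self, name: str, arr: np.ndarray) -> np.ndarray:
        arr = np.asarray(arr, dtype=float)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"layer {name!r} has shape {arr.shape}, grid expects {self.grid.shape}"
            )
        return arr

    def add(self, name: str, arr: np.ndarray) -> None:
        self.layers[name] = self._check(name, arr)

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.layers:
            raise KeyError(f"unknown layer {name!r}; have {sorted(self.layers)}")
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def names(self) -> list[str]:
        return sorted(self.layers)

    def extract(self, names: list[str], x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Values of the named layers at points (x, y), shape (npoints, nlayers)."""
        row, col = self.grid.index_of(x, y)
        return np.column_stack([self[name][row, col] for name in names])

    def copy(self) -> "CovariateStack":
        return CovariateStack(
            grid=self.grid,
            layers={k: v.copy() for k, v in self.layers.items()},
            standardization=dict(self.standardization),
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(path, arr: np.ndarray, grid: GridSpec, nodata: float = -9999.0) -> None:
    arr = np.asarray(arr, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    out = np.where(np.isnan(arr), nodata, arr)
    header = (
        f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
        f"xllcorner {grid.x0!r}\nyllcorner {grid.y0!r}\n"
        f"cellsize {grid.cellsize!r}\nNODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        arr = np.loadtxt(fh)
    grid = GridSpec(
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        cellsize=header["cellsize"],
        x0=header["xllcorner"],
        y0=header["yllcorner"],
    )
    arr = arr.reshape(grid.shape)
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    return arr, grid


# ---------------------------------------------------------------------------
# GeoJSON I/O (projected coordinates; CRS is carried in the run config)


def write_geojson(path, geometries, properties=None) -> None:
    """Write shapely geometries as a GeoJSON FeatureCollection."""
    geometries = list(geometries)
    if properties is None:
        properties = [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in zip(geometries, properties, strict=True)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path):
    """Read a GeoJSON FeatureCollection into (geometries, properties) lists."""
    with open(path) as fh:
        doc = json.load(fh)
    geoms = [shape(feat["geometry"]) for feat in doc["features"]]
    props = [feat.get("properties", {}) for feat in doc["features"]]
    return geoms, props
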