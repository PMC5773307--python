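"""Planar single-band raster grids and binary masks.

All grids are planar with square cells; ``cell_size`` is expressed in
kilometres so that areas come out directly in km². Arrays follow image
convention: row 0 is the first row, column 0 the first column, and the
cell (i, j) spans the half-open square
``[origin_x + j*w, origin_x + (j+1)*w) x [origin_y + i*w, origin_y + (i+1)*w)``
in grid coordinates (also km).

Rasters are (de)serialized as ESRI ASCII grids (plain text), which every
GIS reads; the float32 GeoTIFF route is intentionally not used so that
artifacts stay text-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA_DEFAULT = -9999.0


class GeometryError(ValueError):
    """Raised when two grids that must share a geometry do not."""


@dataclass
class GridLayer:
    """A single-band raster: values, cell size (km), origin, nodata sentinel."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("GridLayer values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        bad = ~np.isfinite(self.values) & ~np.isclose(self.values, self.nodata)
        if bad.any():
            raise ValueError("GridLayer values must be finite or nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        with np.errstate(invalid="ignore"):
            return np.isfinite(self.values) & (self.values != self.nodata)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def same_geometry(self, other: "GridLayer | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_geometry(self, other: "GridLayer | BinaryMask") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"grid geometry mismatch: {self.shape}@{self.cell_size} vs "
                f"{other.shape}@{other.cell_size}"
            )

    def with_values(self, values: np.ndarray) -> "GridLayer":
        return GridLayer(np.asarray(values, dtype=float), self.cell_size,
                         self.origin, self.nodata)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map grid coordinates to (row, col) indices; half-open cells."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.cell_size).astype(int)
        return row, col

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.cell_size
        return x, y


@dataclass
class BinaryMask:
    """A {0,1} raster sharing GridLayer geometry; area is count × cell area."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("BinaryMask values must be 0 or 1")
        self.values = vals.astype(np.uint8)
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area_km2(self) -> float:
        return float(self.values.sum()) * self.cell_size**2

    # duck-typed with GridLayer for geometry checks
    same_geometry = GridLayer.same_geometry
    require_same_geometry = GridLayer.require_same_geometry

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)


def write_ascii_grid(layer: GridLayer | BinaryMask, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    if isinstance(layer, BinaryMask):
        values, nodata = layer.values.astype(float), NODATA_DEFAULT
    else:
        values, nodata = layer.values, layer.nodata
    nrows, ncols = values.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {layer.origin[0]}\n"
        f"yllcorner {layer.origin[1]}\n"
        f"cellsize {layer.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI convention: first data row is the top (largest row index here)
        np.savetxt(fh, values[::-1], fmt="%.8g")


def read_ascii_grid(path: str | Path) -> GridLayer:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    return GridLayer(
        values[::-1].copy(),
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=nodata,
    )
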