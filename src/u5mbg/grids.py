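"""Raster grid geometry and plain-text raster I/O.

All gridded data in this package live on a shared axis-aligned grid in
geographic coordinates (decimal degrees, square cells).  Rasters are stored
on disk as single-band ESRI ASCII grids (``.asc``) — a plain-text format
carrying the full grid geometry (llcorner, cell size, nodata) that GDAL,
rasterio and QGIS all read natively.

Array convention: ``values[row, col]`` with row 0 at the *south* edge, so the
centre of cell ``(r, c)`` is ``(x_origin + (c + 0.5) * cell_size,
y_origin + (r + 0.5) * cell_size)``.  ESRI ASCII stores rows north-to-south;
the reader/writer flips accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class RasterGrid:
    """Geometry of a regular lon/lat grid (origin = lower-left corner)."""

    x_origin: float
    y_origin: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_note: str = "geographic lon/lat (degrees) assumed"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def x_centers(self) -> np.ndarray:
        return self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.y_origin + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of (lon, lat) centres in row-major order."""
        lon, lat = np.meshgrid(self.x_centers(), self.y_centers())
        return np.column_stack([lon.ravel(), lat.ravel()])

    def index_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given points."""
        col = np.floor((np.asarray(lon) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((np.asarray(lat) - self.y_origin) / self.cell_size).astype(int)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col


@dataclass
class CovariateStack:
    """Named covariate layers sharing one grid, plus a validity mask.

    Continuous layers are standardized (mean 0, sd 1) over masked-in cells;
    ``landcover`` holds small non-negative integer class codes.
    """

    grid: RasterGrid
    layers: dict[str, np.ndarray]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
            if not np.all(np.isfinite(arr[self.mask])):
                raise ValueError(f"layer {name!r} has non-finite values inside the mask")
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def values_at(self, lon: np.ndarray, lat: np.ndarray,
                  names: list[str] | None = None,
                  buffer_radius: float = 0.0) -> np.ndarray:
        """Covariate values at points, as an (n, p) design block.

        With ``buffer_radius`` (degrees) > 0, each value is the mean over
        masked-in cells whose centre lies within the radius — the
        buffer-averaged extraction mode used to soften location displacement.
        """
        names = names or self.names
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        out = np.empty((lon.size, len(names)))
        if buffer_radius <= 0:
            row, col = self.grid.index_of(lon, lat)
            for j, name in enumerate(names):
                out[:, j] = self.layers[name][row, col]
            return out
        centers = self.grid.cell_centers()
        flat_mask = self.mask.ravel()
        for i in range(lon.size):
            d2 = (centers[:, 0] - lon[i]) ** 2 + (centers[:, 1] - lat[i]) ** 2
            sel = (d2 <= buffer_radius**2) & flat_mask
            if not sel.any():  # fall back to nearest masked cell
                sel = np.zeros_like(flat_mask)
                sel[np.argmin(np.where(flat_mask, d2, np.inf))] = True
            for j, name in enumerate(names):
                out[i, j] = self.layers[name].ravel()[sel].mean()
        return out


def write_ascii_grid(path: str | Path, grid: RasterGrid, values: np.ndarray,
                     nodata: float = NODATA) -> None:
    """Write a single-band ESRI ASCII grid; NaN cells become nodata."""
    if values.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    out = np.asarray(values, dtype=np.float32).copy()
    out[~np.isfinite(out)] = nodata
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {grid.y_origin!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI ASCII rows run north -> south
        for r in range(grid.n_rows - 1, -1, -1):
            fh.write(" ".join(repr(float(v)) for v in out[r]) + "\n")


def read_ascii_grid(path: str | Path,
                    reference: RasterGrid | None = None) -> tuple[RasterGrid, np.ndarray]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN.

    If ``reference`` is given, the file's geometry must match it exactly.
    """
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=np.float64)
    grid = RasterGrid(
        x_origin=header["xllcorner"], y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
        n_rows=int(header["nrows"]), n_cols=int(header["ncols"]),
    )
    values = np.atleast_2d(values)[::-1].copy()  # back to south-up
    nodata = header.get("nodata_value", NODATA)
    values[values == nodata] = np.nan
    if reference is not None:
        same = (
            grid.n_rows == reference.n_rows and grid.n_cols == reference.n_cols
            and np.isclose(grid.cell_size, reference.cell_size)
            and np.isclose(grid.x_origin, reference.x_origin)
            and np.isclose(grid.y_origin, reference.y_origin)
        )
        if not same:
            raise ValueError(f"raster {path} geometry does not match the reference grid")
    return grid, values
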