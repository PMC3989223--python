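"""Regular raster grids in projected kilometre coordinates.

Cell-centre registration, row-major from the lower-left (south-west)
corner: ``values[0, 0]`` is the centre of the south-westernmost cell and
``values[r, c]`` sits at ``(xmin + (c + 0.5) * cell, ymin + (r + 0.5) * cell)``.
Rasters serialize to ESRI ASCII grids (``.asc``), a plain-text format that
every GIS package reads; the coordinate frame is planar km in an arbitrary
projected CRS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Grid", "Raster", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular cell-centre-registered grid."""

    xmin: float
    ymin: float
    cell: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")

    @classmethod
    def from_extent(
        cls, xmin: float, xmax: float, ymin: float, ymax: float, cell: float
    ) -> "Grid":
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("extent must be strictly positive in both dimensions")
        nx = int(np.ceil((xmax - xmin) / cell))
        ny = int(np.ceil((ymax - ymin) / cell))
        return cls(xmin=xmin, ymin=ymin, cell=cell, nx=nx, ny=ny)

    @property
    def xmax(self) -> float:
        return self.xmin + self.nx * self.cell

    @property
    def ymax(self) -> float:
        return self.ymin + self.ny * self.cell

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def x_centers(self) -> np.ndarray:
        return self.xmin + (np.arange(self.nx) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        return self.ymin + (np.arange(self.ny) + 0.5) * self.cell

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of centre coordinates, each of shape ``(ny, nx)``."""
        X, Y = np.meshgrid(self.x_centers(), self.y_centers())
        return X, Y

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; clipped to the grid."""
        col = int(np.clip((x - self.xmin) // self.cell, 0, self.nx - 1))
        row = int(np.clip((y - self.ymin) // self.cell, 0, self.ny - 1))
        return row, col

    def edge_mask(self) -> np.ndarray:
        """Boolean mask of the outermost ring of cells."""
        m = np.zeros((self.ny, self.nx), dtype=bool)
        m[0, :] = m[-1, :] = True
        m[:, 0] = m[:, -1] = True
        return m


@dataclass
class Raster:
    """Values on a :class:`Grid`; shape ``(ny, nx)``, row 0 southernmost."""

    grid: Grid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )

    def sample(self, x: float, y: float) -> float:
        """Value of the cell containing (x, y)."""
        r, c = self.grid.cell_index(x, y)
        return float(self.values[r, c])

    def bilinear(self, x, y) -> np.ndarray:
        """Bilinear interpolation between cell centres (clamped at edges)."""
        g = self.grid
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        fx = np.clip((x - g.xmin) / g.cell - 0.5, 0.0, g.nx - 1.0)
        fy = np.clip((y - g.ymin) / g.cell - 0.5, 0.0, g.ny - 1.0)
        c0 = np.floor(fx).astype(int)
        r0 = np.floor(fy).astype(int)
        c1 = np.minimum(c0 + 1, g.nx - 1)
        r1 = np.minimum(r0 + 1, g.ny - 1)
        tx = fx - c0
        ty = fy - r0
        v = self.values
        out = (
            v[r0, c0] * (1 - tx) * (1 - ty)
            + v[r0, c1] * tx * (1 - ty)
            + v[r1, c0] * (1 - tx) * ty
            + v[r1, c1] * tx * ty
        )
        return out


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc). NaN becomes the NODATA value."""
    g = raster.grid
    vals = np.where(np.isfinite(raster.values), raster.values, _NODATA)
    header = (
        f"ncols {g.nx}\n"
        f"nrows {g.ny}\n"
        f"xllcorner {g.xmin!r}\n"
        f"yllcorner {g.ymin!r}\n"
        f"cellsize {g.cell!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(header)
        # .asc stores rows north to south
        np.savetxt(fh, vals[::-1], fmt="%.8g")


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nx, ny = int(header["ncols"]), int(header["nrows"])
    grid = Grid(
        xmin=header["xllcorner"],
        ymin=header["yllcorner"],
        cell=header["cellsize"],
        nx=nx,
        ny=ny,
    )
    data = np.atleast_2d(data)[::-1]
    nodata = header.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    return Raster(grid=grid, values=data)
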