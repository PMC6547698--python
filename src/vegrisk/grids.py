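"""Gridded climate surfaces and the coarse equal-area assemblage grid.

A :class:`ClimateField` is a single-band raster on a regular grid in a
projected equal-area coordinate system (units: km).  Cell membership uses
half-open intervals ``[west, east) x [south, north)`` so every point maps to
at most one cell.  Missing data are NaN.

A :class:`CoarseGrid` partitions the same extent into square assemblage
cells (default edge 100 km); because the projection is equal-area, counts of
coarse cells are areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClimateField",
    "CoarseGrid",
    "sample_climate",
    "median_anomaly",
    "aggregate_to_coarse",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass
class ClimateField:
    """One georeferenced climate surface (e.g. MAT in degC or MAP in mm).

    Parameters
    ----------
    values : ndarray, shape (ny, nx)
        Cell values; row 0 is the southernmost row.  NaN marks nodata.
    x0, y0 : float
        Coordinates of the grid's south-west corner.
    cell : float
        Cell edge length (same units as coordinates, km here).
    variable : str
        ``"MAT"`` or ``"MAP"`` (free-form labels are allowed).
    epoch : str
        ``"current"`` or ``"future:<gcm>"``.
    """

    values: np.ndarray
    x0: float
    y0: float
    cell: float
    variable: str = "MAT"
    epoch: str = "current"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ClimateField values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell,
            self.y0 + self.ny * self.cell,
        )

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.cell

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell containing each point (half-open cells).

        Points outside the extent get index -1 in both row and column.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell).astype(int)
        row = np.floor((y - self.y0) / self.cell).astype(int)
        with np.errstate(invalid="ignore"):
            bad = (
                ~np.isfinite(x)
                | ~np.isfinite(y)
                | (col < 0)
                | (col >= self.nx)
                | (row < 0)
                | (row >= self.ny)
            )
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def same_geometry(self, other: "ClimateField") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.x0, other.x0)
            and math.isclose(self.y0, other.y0)
            and math.isclose(self.cell, other.cell)
        )

    def copy_with(self, values: np.ndarray, **kw) -> "ClimateField":
        return replace(self, values=np.asarray(values, dtype=float), **kw)


def sample_climate(
    field: ClimateField, x: Sequence[float], y: Sequence[float]
) -> np.ndarray:
    """Value of the fine cell containing each point.

    Points outside the extent, with non-finite coordinates, or landing on a
    nodata cell yield NaN; callers drop those records (and log the count)
    before limit estimation.
    """
    if not np.isfinite(field.values).any():
        raise ValueError("climate field has no defined cells")
    row, col = field.index_of(np.asarray(x, float), np.asarray(y, float))
    out = np.full(row.shape, np.nan)
    ok = row >= 0
    out[ok] = field.values[row[ok], col[ok]]
    return out


def median_anomaly(
    current: ClimateField, futures: Iterable[ClimateField]
) -> ClimateField:
    """Per-cell median of (future - current) across GCM layers.

    NaN in any layer propagates to the anomaly; with an even layer count the
    median is the mean of the two central values.
    """
    futures = list(futures)
    if not futures:
        raise ValueError("at least one future layer is required")
    for f in futures:
        if not current.same_geometry(f):
            raise ValueError(
                f"future layer {f.epoch!r} does not share the current grid geometry"
            )
        if f.variable != current.variable:
            raise ValueError(
                f"future layer {f.epoch!r} has variable {f.variable!r}, "
                f"expected {current.variable!r}"
            )
    stack = np.stack([f.values - current.values for f in futures], axis=0)
    med = np.median(stack, axis=0)  # NaN anywhere -> NaN, as required
    return current.copy_with(med, epoch="anomaly")


@dataclass
class CoarseGrid:
    """Square equal-area assemblage cells covering a rectangular extent.

    Cell ids run row-major from the south-west corner:
    ``cell_id = row * ncols + col``.
    """

    x0: float
    y0: float
    edge: float
    nrows: int
    ncols: int

    @classmethod
    def from_extent(
        cls, extent: tuple[float, float, float, float], edge: float = 100.0
    ) -> "CoarseGrid":
        xmin, ymin, xmax, ymax = extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("degenerate extent")
        ncols = int(math.ceil((xmax - xmin) / edge - 1e-9))
        nrows = int(math.ceil((ymax - ymin) / edge - 1e-9))
        return cls(x0=xmin, y0=ymin, edge=edge, nrows=nrows, ncols=ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Cell id containing each point; -1 outside the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.edge).astype(int)
        row = np.floor((y - self.y0) / self.edge).astype(int)
        with np.errstate(invalid="ignore"):
            bad = (
                ~np.isfinite(x)
                | ~np.isfinite(y)
                | (col < 0)
                | (col >= self.ncols)
                | (row < 0)
                | (row >= self.nrows)
            )
        return np.where(bad, -1, row * self.ncols + col)

    def cell_centers(self) -> pd.DataFrame:
        ids = np.arange(self.n_cells)
        rows, cols = divmod(ids, self.ncols)
        return pd.DataFrame(
            {
                "cell_id": ids,
                "x": self.x0 + (cols + 0.5) * self.edge,
                "y": self.y0 + (rows + 0.5) * self.edge,
            }
        )


def aggregate_to_coarse(
    field: ClimateField, grid: CoarseGrid, min_land_fraction: float = 0.01
) -> pd.DataFrame:
    """Unweighted mean of fine-cell values within each coarse cell.

    Returns a frame with columns ``cell_id``, ``value``, ``land_fraction``
    (share of the coarse cell's fine cells that carry data).  Coarse cells
    whose land fraction falls below ``min_land_fraction`` are excluded.
    """
    xs = field.x_centers()
    ys = field.y_centers()
    xg, yg = np.meshgrid(xs, ys)
    ids = grid.cell_of(xg.ravel(), yg.ravel())
    vals = field.values.ravel()
    inside = ids >= 0
    ids, vals = ids[inside], vals[inside]
    if ids.size == 0:
        raise ValueError("coarse grid does not intersect the field extent")

    n_total = np.bincount(ids, minlength=grid.n_cells).astype(float)
    has_data = np.isfinite(vals)
    n_data = np.bincount(ids[has_data], minlength=grid.n_cells).astype(float)
    sums = np.bincount(
        ids[has_data], weights=vals[has_data], minlength=grid.n_cells
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(n_data > 0, sums / np.maximum(n_data, 1), np.nan)
        frac = np.where(n_total > 0, n_data / np.maximum(n_total, 1), 0.0)
    out = pd.DataFrame(
        {
            "cell_id": np.arange(grid.n_cells),
            "value": means,
            "land_fraction": frac,
        }
    )
    return out[(out["land_fraction"] >= min_land_fraction)].reset_index(drop=True)


# -- plain-text raster I/O (ESRI ASCII grid) --------------------------------

def write_ascii_grid(field: ClimateField, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a field as an ESRI ASCII grid (rows listed north to south)."""
    path = Path(path)
    vals = np.where(np.isfinite(field.values), field.values, nodata)
    with path.open("w") as fh:
        fh.write(f"ncols {field.nx}\n")
        fh.write(f"nrows {field.ny}\n")
        fh.write(f"xllcorner {float(field.x0)!r}\n")
        fh.write(f"yllcorner {float(field.y0)!r}\n")
        fh.write(f"cellsize {float(field.cell)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        for row in vals[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(
    path: str | Path, variable: str = "MAT", epoch: str = "current"
) -> ClimateField:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    vals = np.array(rows[::-1], dtype=float)  # file is north-first; row 0 = south
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    return ClimateField(
        values=vals,
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell=header["cellsize"],
        variable=variable,
        epoch=epoch,
    )
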