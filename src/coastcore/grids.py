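"""Minimal single-band raster container and text-format I/O.

Everything downstream works on projected-meter grids with square cells.
A :class:`Raster` is a float array (NaN = NoData) plus grid geometry:
``origin`` is the (x, y) of the *lower-left corner* of the grid, row 0 is
the northernmost row, and cell centers sit at half-cell offsets.  Areas
are always cell counts times ``cell_m**2``.

I/O uses the ESRI ASCII grid format (plain text, one header + rows of
values), which keeps every artifact of the pipeline human-readable and
diff-able.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

_NODATA_OUT = -9999.0


@dataclasses.dataclass
class Raster:
    """A single-band raster on a square-celled, projected-meter grid.

    Parameters
    ----------
    data : ndarray of float
        2-D array, row 0 = north. NaN marks NoData (sea, off-island).
    cell_m : float
        Cell edge length in meters.
    origin : tuple of float
        (x, y) of the lower-left corner of the grid in projected meters.
    crs_epsg : int
        EPSG code of the projected CRS (metadata only).
    """

    data: np.ndarray
    cell_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_epsg: int = 32652

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_m <= 0:
            raise ValueError("cell_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean land/valid mask (True where data is finite)."""
        return np.isfinite(self.data)

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_m, other.cell_m)
            and np.allclose(self.origin, other.origin)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-center coordinates in meters."""
        nrow, ncol = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.cell_m
        ys = y0 + (nrow - np.arange(nrow) - 0.5) * self.cell_m
        return np.meshgrid(xs, ys)

    def xy_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map projected coordinates to (row, col) indices (floor of cell)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nrow = self.shape[0]
        col = np.floor((x - self.origin[0]) / self.cell_m).astype(int)
        row = nrow - 1 - np.floor((y - self.origin[1]) / self.cell_m).astype(int)
        return row, col

    def copy_with(self, data: np.ndarray) -> "Raster":
        """New raster with the same geometry and different values."""
        data = np.asarray(data, dtype=float)
        if data.shape != self.shape:
            raise ValueError("shape mismatch with grid geometry")
        return Raster(data, self.cell_m, self.origin, self.crs_epsg)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc); NaN becomes the nodata sentinel."""
    nrow, ncol = raster.shape
    x0, y0 = raster.origin
    header = (
        f"ncols {ncol}\n"
        f"nrows {nrow}\n"
        f"xllcorner {x0:.6f}\n"
        f"yllcorner {y0:.6f}\n"
        f"cellsize {raster.cell_m:.6f}\n"
        f"NODATA_value {_NODATA_OUT}\n"
    )
    body = np.where(np.isfinite(raster.data), raster.data, _NODATA_OUT)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")


def read_ascii_grid(path: str | Path, crs_epsg: int = 32652) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", _NODATA_OUT)
    data[data == nodata] = np.nan
    return Raster(
        data,
        cell_m=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        crs_epsg=crs_epsg,
    )
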