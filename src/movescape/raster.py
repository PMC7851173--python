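"""Gridded raster container and text I/O.

Rasters are stored row-major north-to-south (``values[0]`` is the
northernmost row) on a square-celled planar grid.  Missing cells are held
as ``nan`` in memory; a nodata sentinel is only used on disk.  The on-disk
dialect is the ESRI ASCII grid, a plain-text format understood by every
GIS package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridRaster", "aggregate_mean"]


@dataclass
class GridRaster:
    """A rectangular single-band raster with square cells.

    Parameters
    ----------
    values
        2-D float array, row 0 = northernmost row.  ``nan`` marks nodata.
    x_origin, y_origin
        Coordinates of the *lower-left corner* of the grid (same units as
        ``cell_size``; kilometres for projected grids, degrees otherwise).
    cell_size
        Cell edge length (> 0).
    crs_tag
        Free-form tag describing the coordinate system (e.g. ``"aeqd-km"``).
    """

    values: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 1.0
    crs_tag: str = "aeqd-km"
    nodata: float = field(default=-9999.0, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid's outer edges."""
        nr, nc = self.shape
        return (
            self.x_origin,
            self.x_origin + nc * self.cell_size,
            self.y_origin,
            self.y_origin + nr * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (x of columns, y of rows) of cell-centre coordinates."""
        nr, nc = self.shape
        xs = self.x_origin + (np.arange(nc) + 0.5) * self.cell_size
        ys = self.y_origin + (nr - np.arange(nr) - 0.5) * self.cell_size
        return xs, ys

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; raises if outside."""
        nr, nc = self.shape
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row = int(np.floor((self.y_origin + nr * self.cell_size - y) / self.cell_size))
        if not (0 <= row < nr and 0 <= col < nc):
            raise IndexError(f"point ({x}, {y}) outside raster extent {self.extent}")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        xmin, xmax, ymin, ymax = self.extent
        return xmin <= x < xmax and ymin < y <= ymax

    # ------------------------------------------------------------------ sampling
    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell values at points (vectorized); nan outside extent."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        nr, nc = self.shape
        col = np.floor((x - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin + nr * self.cell_size - y) / self.cell_size).astype(int)
        ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
        out = np.full(x.shape, np.nan)
        out[ok] = self.values[row[ok], col[ok]]
        return out

    def mean_in_radius(self, x: float, y: float, radius: float) -> float:
        """Mean of non-nodata cell values whose centres lie within ``radius``.

        Returns ``nan`` when the point is outside the extent or no valid
        cell centre falls inside the disc (the caller's missing sentinel).
        """
        if not self.contains(x, y):
            import warnings

            warnings.warn(f"point ({x:.3f}, {y:.3f}) outside raster extent", stacklevel=2)
            return float("nan")
        xs, ys = self.cell_centers()
        # restrict to the bounding box of the disc for speed
        jmask = np.abs(xs - x) <= radius
        imask = np.abs(ys - y) <= radius
        if not jmask.any() or not imask.any():
            # radius smaller than half a cell: fall back to the containing cell
            r, c = self.index_of(x, y)
            return float(self.values[r, c])
        sub = self.values[np.ix_(imask, jmask)]
        dx = xs[jmask][None, :] - x
        dy = ys[imask][:, None] - y
        disc = dx * dx + dy * dy <= radius * radius
        vals = sub[disc]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            r, c = self.index_of(x, y)
            v = self.values[r, c]
            return float(v) if np.isfinite(v) else float("nan")
        return float(vals.mean())

    # ------------------------------------------------------------------ I/O
    def to_ascii(self, path) -> None:
        """Write as ESRI ASCII grid (text)."""
        nr, nc = self.shape
        out = np.where(np.isfinite(self.values), self.values, self.nodata)
        header = (
            f"ncols {nc}\n"
            f"nrows {nr}\n"
            f"xllcorner {self.x_origin!r}\n"
            f"yllcorner {self.y_origin!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.10g")

    @classmethod
    def from_ascii(cls, path, crs_tag: str = "aeqd-km") -> "GridRaster":
        """Read an ESRI ASCII grid."""
        meta: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value",
                }:
                    meta[parts[0].lower()] = float(parts[1])
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            values = np.loadtxt(fh, ndmin=2)
        for key in ("ncols", "nrows", "cellsize"):
            if key not in meta:
                raise ValueError(f"ASCII grid missing header field {key!r}")
        if values.shape != (int(meta["nrows"]), int(meta["ncols"])):
            raise ValueError("ASCII grid body does not match declared shape")
        nodata = meta.get("nodata_value", -9999.0)
        values = np.where(values == nodata, np.nan, values)
        return cls(
            values=values,
            x_origin=meta.get("xllcorner", 0.0),
            y_origin=meta.get("yllcorner", 0.0),
            cell_size=meta["cellsize"],
            crs_tag=crs_tag,
            nodata=nodata,
        )

    def copy_with(self, values: np.ndarray) -> "GridRaster":
        """New raster with the same grid geometry but different values."""
        return GridRaster(
            values=np.asarray(values, dtype=float),
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            cell_size=self.cell_size,
            crs_tag=self.crs_tag,
            nodata=self.nodata,
        )


def aggregate_mean(fine: GridRaster, factor: int) -> GridRaster:
    """Block-mean aggregation of a fine raster to ``factor`` x coarser cells.

    The coarse grid must tile an integer number of fine cells; masked
    (nan) fine cells are excluded from each block mean, and an all-masked
    block stays masked.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("aggregation factor must be a positive integer")
    factor = int(factor)
    nr, nc = fine.shape
    if nr % factor or nc % factor:
        raise ValueError(
            f"grid of shape {fine.shape} is not tiled by an aggregation factor of {factor}"
        )
    blocks = fine.values.reshape(nr // factor, factor, nc // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(nr // factor, nc // factor, -1)
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            coarse = np.nanmean(blocks, axis=2)
    return GridRaster(
        values=coarse,
        x_origin=fine.x_origin,
        y_origin=fine.y_origin,
        cell_size=fine.cell_size * factor,
        crs_tag=fine.crs_tag,
        nodata=fine.nodata,
    )
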