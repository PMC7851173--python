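"""Vessel-density gridding, encounter-probability layers, and overlap statistics.

On a shared 8 x 8 km grid the package combines a whale density surface
N_i (from an external species distribution model), the predicted
long-term velocity nu_i (residence time is 1/nu_i), and per-fleet vessel
density VD_i into:

    RPEW_i  = N_i (1/nu_i) / sum_i N_i (1/nu_i)         (whale encounter)
    RPVEW_i = Pw_i Pt_i Pv_i / sum_i Pw_i Pt_i Pv_i     (vessel-whale encounter)

with Pw_i = N_i / sum N, Pt_i = (1/nu_i) / sum (1/nu), Pv_i = VD_i / sum VD.
Overlap between layers is quantified with Schoener's D and Warren's I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import GridRaster, aggregate_mean
from .tracks import AzimuthalEquidistant, VesselRecord

__all__ = [
    "RiskLayers",
    "vessel_density",
    "aggregate_mean",
    "rpew",
    "rpvew",
    "overlap_stats",
    "schoener_d",
    "warren_i",
    "traverse_cells",
]


def traverse_cells(grid: GridRaster, x0: float, y0: float, x1: float, y1: float):
    """Cells (row, col) crossed by the straight segment between two points.

    Amanatides-Woo grid traversal; endpoints outside the grid contribute
    only the in-grid portion of the segment.
    """
    cs = grid.cell_size
    nr, nc = grid.shape
    ytop = grid.y_origin + nr * cs

    # parametric clip of [0, 1] to the grid box
    dx, dy = x1 - x0, y1 - y0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 - grid.x_origin),
        (dx, grid.x_origin + nc * cs - x0),
        (-dy, y0 - grid.y_origin),
        (dy, ytop - y0),
    ):
        if p == 0.0:
            if q < 0:
                return []
            continue
        t = q / p
        if p < 0:
            t0 = max(t0, t)
        else:
            t1 = min(t1, t)
    if t0 > t1:
        return []
    ax, ay = x0 + t0 * dx, y0 + t0 * dy
    bx, by = x0 + t1 * dx, y0 + t1 * dy

    eps = 1e-12
    col = min(int((ax - grid.x_origin) / cs), nc - 1)
    row = min(int((ytop - ay) / cs), nr - 1)
    col_end = min(int((bx - grid.x_origin) / cs), nc - 1)
    row_end = min(int((ytop - by) / cs), nr - 1)

    cells = [(row, col)]
    sdx, sdy = bx - ax, by - ay
    step_col = 1 if sdx > 0 else -1
    step_row = 1 if sdy < 0 else -1  # moving south increases the row index
    t_max_x = np.inf
    t_max_y = np.inf
    if sdx != 0:
        next_xb = grid.x_origin + (col + (1 if step_col > 0 else 0)) * cs
        t_max_x = (next_xb - ax) / sdx
        t_dx = cs / abs(sdx)
    if sdy != 0:
        next_yb = ytop - (row + (1 if step_row > 0 else 0)) * cs
        t_max_y = (next_yb - ay) / sdy
        t_dy = cs / abs(sdy)
    guard = 0
    while (row, col) != (row_end, col_end) and guard < nr + nc + 4:
        guard += 1
        if t_max_x <= t_max_y + eps:
            col += step_col
            t_max_x += t_dx
        else:
            row += step_row
            t_max_y += t_dy
        if not (0 <= row < nr and 0 <= col < nc):
            break
        cells.append((row, col))
    return cells


def vessel_density(
    records: list[VesselRecord],
    grid: GridRaster,
    projection: AzimuthalEquidistant | None = None,
    months: list[str] | None = None,
    crossing: str = "segment",
) -> GridRaster:
    """Mean daily count of unique vessels crossing each grid cell.

    Per month, for each day with at least one record anywhere, the unique
    vessels whose (interpolated) path crosses each cell are counted; the
    per-day counts are summed and divided by the number of days with
    data in that month, and the monthly layers are then averaged
    cell-wise into a single layer.

    Parameters
    ----------
    records
        Vessel position reports (one fleet; filter upstream).
    grid
        8 x 8 km template raster defining the output geometry.
    projection
        Maps lon/lat to the grid's planar CRS.  When omitted, coordinates
        are taken to be already planar (lon = x, lat = y; convenient for
        synthetic data expressed in km).
    months
        Restrict to these "YYYY-MM" labels; default: all months present.
    crossing
        "segment": straight-line rasterization credits every traversed
        cell between consecutive same-day fixes; "containment": only
        cells containing a fix are credited.
    """
    if crossing not in ("segment", "containment"):
        raise ValueError("crossing must be 'segment' or 'containment'")
    if not records:
        raise ValueError("no vessel records supplied")
    df = pd.DataFrame(
        {
            "vessel_id": [r.vessel_id for r in records],
            "timestamp": pd.to_datetime([r.timestamp for r in records], utc=True),
            "lon": [r.lon for r in records],
            "lat": [r.lat for r in records],
        }
    )
    if projection is not None:
        x, y = projection.forward(df["lon"].to_numpy(), df["lat"].to_numpy())
    else:
        x, y = df["lon"].to_numpy(), df["lat"].to_numpy()
    df["x"], df["y"] = x, y
    df["month"] = df["timestamp"].dt.strftime("%Y-%m")
    df["day"] = df["timestamp"].dt.strftime("%Y-%m-%d")
    if months is not None:
        df = df[df["month"].isin(months)]
        for month in months:
            if month not in set(df["month"]):
                warnings.warn(f"month {month} has no days with data; skipped", stacklevel=2)
    if df.empty:
        raise ValueError("no vessel records in the requested months")

    monthly = []
    for _, mdf in df.groupby("month", sort=True):
        counts = np.zeros(grid.shape)
        n_days = mdf["day"].nunique()
        for _, ddf in mdf.groupby("day", sort=True):
            for _, vdf in ddf.groupby("vessel_id", sort=True):
                vdf = vdf.sort_values("timestamp", kind="stable")
                xs = vdf["x"].to_numpy()
                ys = vdf["y"].to_numpy()
                crossed: set[tuple[int, int]] = set()
                for i in range(len(xs)):
                    if grid.contains(xs[i], ys[i]):
                        crossed.add(grid.index_of(xs[i], ys[i]))
                if crossing == "segment":
                    for i in range(len(xs) - 1):
                        crossed.update(
                            traverse_cells(grid, xs[i], ys[i], xs[i + 1], ys[i + 1])
                        )
                for rc in crossed:
                    counts[rc] += 1.0
        monthly.append(counts / n_days)
    vd = np.mean(monthly, axis=0)
    vd[~np.isfinite(grid.values)] = np.nan
    return grid.copy_with(vd)


def _normalize(values: np.ndarray) -> np.ndarray:
    """Normalize non-negative values to sum to 1 over valid (finite) cells."""
    valid = np.isfinite(values)
    total = values[valid].sum()
    if total <= 0:
        raise ValueError("layer sums to zero over valid cells; cannot normalize")
    out = np.where(valid, values / total, np.nan)
    return out


def rpew(density_n: GridRaster, nu8: GridRaster) -> GridRaster:
    """Relative probability of encountering a whale.

    RPEW_i = N_i (1/nu_i) / sum_i N_i (1/nu_i): encounter probability
    increases with predicted density and with residence time 1/nu_i.
    """
    if density_n.shape != nu8.shape:
        raise ValueError("density and nu rasters are not aligned")
    nu = nu8.values
    if np.nanmin(nu) <= 0:
        raise ValueError("nu must be strictly positive on valid cells")
    raw = density_n.values / nu
    return density_n.copy_with(_normalize(raw))


def rpvew(density_n: GridRaster, nu8: GridRaster, vd: GridRaster) -> "RiskLayers":
    """Relative probability of a vessel encountering a whale, with factors.

    Each factor (whale probability Pw, time allocation Pt, vessel
    probability Pv) is normalized to sum to 1, multiplied cell-wise, and
    the product renormalized.
    """
    for other in (nu8, vd):
        if other.shape != density_n.shape:
            raise ValueError("risk layers are not aligned")
    if np.nansum(vd.values) <= 0:
        raise ValueError("vessel density is identically zero for this fleet")
    pw = _normalize(density_n.values)
    with np.errstate(divide="ignore"):
        pt = _normalize(1.0 / nu8.values)
    pv = _normalize(vd.values)
    prod = pw * pt * pv
    return RiskLayers(
        vd=vd,
        density_n=density_n,
        nu8=nu8,
        pw=density_n.copy_with(pw),
        pt=density_n.copy_with(pt),
        pv=density_n.copy_with(pv),
        rpew=rpew(density_n, nu8),
        rpvew=density_n.copy_with(_normalize(prod)),
    )


@dataclass
class RiskLayers:
    """Gridded inputs and derived encounter-probability layers (one fleet)."""

    vd: GridRaster
    density_n: GridRaster
    nu8: GridRaster
    pw: GridRaster
    pt: GridRaster
    pv: GridRaster
    rpew: GridRaster
    rpvew: GridRaster

    def to_frame(self) -> pd.DataFrame:
        nr, nc = self.vd.shape
        rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "vd": self.vd.values.ravel(),
                "n": self.density_n.values.ravel(),
                "nu": self.nu8.values.ravel(),
                "pw": self.pw.values.ravel(),
                "pt": self.pt.values.ravel(),
                "pv": self.pv.values.ravel(),
                "rpew": self.rpew.values.ravel(),
                "rpvew": self.rpvew.values.ravel(),
            }
        )


def schoener_d(p, q) -> float:
    """Schoener's D between two spatial distributions: 1 - 1/2 sum |p - q|.

    Inputs are normalized to sum to 1 if they do not already.
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    p = p / p.sum()
    q = q / q.sum()
    return 1.0 - 0.5 * float(np.abs(p - q).sum())


def warren_i(p, q) -> float:
    """Warren's I between two spatial distributions: 1 - 1/2 sum (sqrt p - sqrt q)^2."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    p = p / p.sum()
    q = q / q.sum()
    return 1.0 - 0.5 * float(((np.sqrt(p) - np.sqrt(q)) ** 2).sum())


def overlap_stats(layer_a: GridRaster, layer_b: GridRaster) -> tuple[float, float]:
    """Schoener's D and Warren's I between two non-negative layers.

    Each layer is min-max rescaled to [0, 1], normalized to sum to 1 over
    the cells valid in both, then
    D = 1 - 1/2 sum |p_i - q_i| and I = 1 - 1/2 sum (sqrt p_i - sqrt q_i)^2.
    Both range from 0 (disjoint) to 1 (identical distributions).
    """
    if layer_a.shape != layer_b.shape:
        raise ValueError("overlap layers are not aligned")
    a = layer_a.values.astype(float).copy()
    b = layer_b.values.astype(float).copy()
    valid = np.isfinite(a) & np.isfinite(b)
    a, b = a[valid], b[valid]
    out = []
    for v in (a, b):
        lo, hi = v.min(), v.max()
        if hi <= lo:
            raise ValueError("constant layer: min-max rescale is degenerate")
        out.append((v - lo) / (hi - lo))
    p, q = out
    return schoener_d(p, q), warren_i(p, q)
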