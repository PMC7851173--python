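"""Environmental covariate layers and their extraction along tracks.

Three layers drive the movement model: log-transformed distance to areas
of high spring chlorophyll-a concentration (DAHCC), sea-surface
temperature (SST), and SST gradient magnitude (thermal fronts).  Layers
are extracted at estimated whale locations with a 3-km-radius mean,
z-scored, and missing values are set to 0 (the standardized mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import GridRaster

__all__ = [
    "CovariateStack",
    "build_dahcc",
    "thermal_gradient",
    "extract_mean_radius",
    "standardize_and_fill",
    "flag_correlated",
]


class DegenerateCovariateError(ValueError):
    """Raised when a covariate has zero spread and cannot be standardized."""


@dataclass
class CovariateStack:
    """Co-registered covariate rasters plus standardization constants.

    ``layers`` maps a covariate name either to a single raster (used for
    all times) or to a dict keyed by time (year for DAHCC, an ISO date
    string for daily layers).  ``standardization`` maps covariate names to
    (mean, sd) pairs; when absent, constants are computed from the
    extracted series at standardization time.
    """

    layers: dict[str, GridRaster | dict]
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    def layer_for(self, name: str, when=None) -> GridRaster:
        layer = self.layers[name]
        if isinstance(layer, GridRaster):
            return layer
        if when is None:
            raise KeyError(f"layer {name!r} is time-keyed; a time key is required")
        return layer[when]

    def extract(
        self,
        xy: np.ndarray,
        when=None,
        radius: float = 3.0,
    ) -> pd.DataFrame:
        """Mean covariate values within ``radius`` km of each point.

        Parameters
        ----------
        xy
            (n, 2) projected coordinates in the rasters' planar CRS (km).
        when
            Optional per-point sequence of time keys for time-keyed layers.
        """
        xy = np.asarray(xy, dtype=float)
        out = {}
        for name in self.names:
            vals = np.empty(len(xy))
            for i, (x, y) in enumerate(xy):
                key = None if when is None else when[i]
                layer = self.layers[name]
                ras = layer if isinstance(layer, GridRaster) else layer[key]
                vals[i] = extract_mean_radius(ras, (x, y), radius)
            out[name] = vals
        return pd.DataFrame(out)

    def compute_standardization(self) -> None:
        """Fill standardization constants from full-raster statistics."""
        for name in self.names:
            layer = self.layers[name]
            rasters = [layer] if isinstance(layer, GridRaster) else list(layer.values())
            vals = np.concatenate([r.values[np.isfinite(r.values)].ravel() for r in rasters])
            sd = float(vals.std(ddof=0))
            if sd <= 0:
                raise DegenerateCovariateError(f"covariate {name!r} has zero spread")
            self.standardization[name] = (float(vals.mean()), sd)


def build_dahcc(spring_chla: GridRaster, percentile: float = 95.0) -> GridRaster:
    """Log distance to areas of high spring chlorophyll-a concentration.

    Cells at or above the given percentile of the (non-masked) chlorophyll
    distribution form the high-concentration set.  Each marine cell gets
    ``log(d + cell_size/2)`` where ``d`` is the planar distance (km) from
    its centre to the nearest high-set cell centre; high-set cells
    therefore take ``log(cell_size/2)``, the floor that keeps the log
    finite at zero distance.  Masked (land) cells stay masked.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must be in (0, 100)")
    vals = spring_chla.values
    marine = np.isfinite(vals)
    if not marine.any():
        raise ValueError("chlorophyll raster is fully masked")
    finite = vals[marine]
    threshold = np.percentile(finite, percentile)
    high = marine & (vals >= threshold)
    if finite.min() == finite.max():
        raise ValueError(
            "chlorophyll raster is flat: no percentile exceedance defines a high-concentration set"
        )
    if not high.any():
        raise ValueError("no cells reach the high-concentration threshold")
    # distance (km) from each cell centre to the nearest high cell centre
    dist = ndimage.distance_transform_edt(~high, sampling=spring_chla.cell_size)
    floor = spring_chla.cell_size / 2.0
    out = np.log(dist + floor)
    out[~marine] = np.nan
    return spring_chla.copy_with(out)


def thermal_gradient(sst: GridRaster, median_window: int = 3) -> GridRaster:
    """SST gradient magnitude (degC / km) after a median pre-filter.

    The SST field is median-filtered with an odd square window to suppress
    impulse noise, then the gradient magnitude sqrt((dT/dx)^2 + (dT/dy)^2)
    is computed with central differences (one-sided at the edges).
    """
    if median_window < 1 or median_window % 2 == 0:
        raise ValueError("median_window must be a positive odd integer")
    nr, nc = sst.shape
    if nr < median_window or nc < median_window:
        raise ValueError(
            f"raster of shape {sst.shape} is smaller than the {median_window}x{median_window} window"
        )
    vals = sst.values
    marine = np.isfinite(vals)
    filled = vals
    if not marine.all():
        # fill masked cells from the nearest marine cell so filtering and
        # differencing stay defined; the mask is re-applied afterwards
        idx = ndimage.distance_transform_edt(~marine, return_distances=False, return_indices=True)
        filled = vals[tuple(idx)]
    smooth = ndimage.median_filter(filled, size=median_window, mode="nearest")
    # rows run north to south: axis 0 steps are -cell_size in y
    d_dy, d_dx = np.gradient(smooth, -sst.cell_size, sst.cell_size)
    mag = np.hypot(d_dx, d_dy)
    mag[~marine] = np.nan
    return sst.copy_with(mag)


def extract_mean_radius(raster: GridRaster, point, radius: float = 3.0) -> float:
    """Mean of non-masked cell values whose centres lie within ``radius`` km.

    Returns nan (the missing sentinel) for points outside the raster
    extent or discs containing no valid cell centre.
    """
    x, y = point
    return raster.mean_in_radius(float(x), float(y), float(radius))


def standardize_and_fill(
    values: pd.DataFrame,
    stats: dict[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Z-score covariate series and replace missing entries with 0.

    Parameters
    ----------
    values
        One row per relocation, one column per covariate; nan = missing.
    stats
        Optional (mean, sd) per covariate.  When omitted, constants are
        computed from each column's non-missing entries (per-track
        standardization, the default convention for per-individual fits).

    Returns
    -------
    X : (n, p) design matrix;  stats : the constants used.
    """
    used: dict[str, tuple[float, float]] = {}
    cols = []
    for name in values.columns:
        v = values[name].to_numpy(dtype=float)
        if stats is not None and name in stats:
            mean, sd = stats[name]
        else:
            finite = v[np.isfinite(v)]
            if finite.size == 0:
                raise DegenerateCovariateError(f"covariate {name!r} is entirely missing")
            mean, sd = float(finite.mean()), float(finite.std(ddof=0))
        if sd <= 0:
            raise DegenerateCovariateError(
                f"covariate {name!r} is constant (sd = 0) and cannot be standardized"
            )
        z = (v - mean) / sd
        z[~np.isfinite(z)] = 0.0  # missing -> standardized mean
        used[name] = (mean, sd)
        cols.append(z)
    return np.column_stack(cols), used


def flag_correlated(X: np.ndarray | pd.DataFrame, threshold: float = 0.5) -> list[tuple]:
    """Pairs of covariates whose absolute Pearson correlation is >= threshold.

    Mirrors the pre-model screening rule used to keep collinear covariates
    out of the same design matrix.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = list(range(arr.shape[1]))
    r = np.corrcoef(arr, rowvar=False)
    flagged = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(r[i, j]) >= threshold:
                flagged.append((names[i], names[j], float(r[i, j])))
    return flagged
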