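"""Argos-style telemetry and vessel-track tables.

Reads delimited text tables into per-animal tracks, validates coordinates
and location classes, imputes missing error ellipses from per-class donor
means, applies a spike-aware maximum-speed filter, and projects tracks
into a planar azimuthal-equidistant frame (kilometres) for state-space
modelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ArgosRelocation",
    "ArgosTrack",
    "VesselRecord",
    "AzimuthalEquidistant",
    "read_argos_table",
    "read_vessel_table",
    "impute_ellipses_by_class",
    "speed_filter",
    "project_track",
    "truncate_after",
    "great_circle_km",
]

LOCATION_CLASSES = ("3", "2", "1", "0", "A", "B")
FLEETS = ("industrial_fishery", "artisanal_fishery", "aquaculture", "transport")

EARTH_RADIUS_KM = 6371.0088


class TrackFormatError(ValueError):
    """Raised for malformed track/vessel tables."""


class DegenerateTrackError(ValueError):
    """Raised when filtering reduces a track below two relocations."""


@dataclass
class ArgosRelocation:
    """One satellite relocation: time, position, quality and error ellipse."""

    timestamp: datetime
    lon: float
    lat: float
    location_class: str
    ellipse_semi_major: float | None = None  # metres
    ellipse_semi_minor: float | None = None  # metres
    ellipse_orientation: float | None = None  # degrees clockwise from north

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise TrackFormatError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 360.0):
            raise TrackFormatError(f"longitude {self.lon} outside [-180, 360]")
        self.location_class = str(self.location_class)
        if self.location_class not in LOCATION_CLASSES:
            raise TrackFormatError(
                f"unknown Argos location class {self.location_class!r}; "
                f"expected one of {LOCATION_CLASSES}"
            )
        if self.ellipse_semi_major is not None and self.ellipse_semi_minor is not None:
            if self.ellipse_semi_minor > self.ellipse_semi_major:
                raise TrackFormatError("ellipse semi-minor exceeds semi-major")
            if self.ellipse_semi_minor < 0:
                raise TrackFormatError("ellipse axes must be non-negative")
        if self.ellipse_orientation is not None:
            self.ellipse_orientation = float(self.ellipse_orientation) % 180.0

    @property
    def has_ellipse(self) -> bool:
        return (
            self.ellipse_semi_major is not None
            and self.ellipse_semi_minor is not None
            and self.ellipse_orientation is not None
        )


@dataclass
class ArgosTrack:
    """Time-ordered relocations for one animal, optionally projected to km."""

    animal_id: str
    relocations: list[ArgosRelocation]
    projected_xy: np.ndarray | None = None  # (n, 2) km
    projection: "AzimuthalEquidistant | None" = None

    def __post_init__(self) -> None:
        if len(self.relocations) < 2:
            raise DegenerateTrackError(
                f"track {self.animal_id!r} has {len(self.relocations)} relocation(s); need >= 2"
            )
        ts = [r.timestamp for r in self.relocations]
        if any(t1 <= t0 for t0, t1 in zip(ts, ts[1:])):
            raise TrackFormatError(
                f"track {self.animal_id!r}: timestamps not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.relocations)

    @property
    def n(self) -> int:
        return len(self.relocations)

    def lonlat(self) -> np.ndarray:
        return np.array([[r.lon, r.lat] for r in self.relocations])

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex([r.timestamp for r in self.relocations])

    def hours_from_start(self) -> np.ndarray:
        ts = self.timestamps()
        return ((ts - ts[0]).total_seconds() / 3600.0).to_numpy()

    def dt_hours(self) -> np.ndarray:
        """Interval lengths in hours (length n - 1)."""
        return np.diff(self.hours_from_start())

    def ellipses(self) -> np.ndarray:
        """(n, 3) array of semi-major (m), semi-minor (m), orientation (deg)."""
        out = np.full((self.n, 3), np.nan)
        for i, r in enumerate(self.relocations):
            if r.has_ellipse:
                out[i] = (r.ellipse_semi_major, r.ellipse_semi_minor, r.ellipse_orientation)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "timestamp": self.timestamps(),
                "lon": [r.lon for r in self.relocations],
                "lat": [r.lat for r in self.relocations],
                "location_class": [r.location_class for r in self.relocations],
                "ellipse_semi_major": [r.ellipse_semi_major for r in self.relocations],
                "ellipse_semi_minor": [r.ellipse_semi_minor for r in self.relocations],
                "ellipse_orientation": [r.ellipse_orientation for r in self.relocations],
            }
        )
        if self.projected_xy is not None:
            df["x_km"] = self.projected_xy[:, 0]
            df["y_km"] = self.projected_xy[:, 1]
        return df


@dataclass
class VesselRecord:
    """One vessel position report."""

    vessel_id: str
    fleet: str
    timestamp: datetime
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if self.fleet not in FLEETS:
            raise TrackFormatError(
                f"unknown fleet {self.fleet!r}; expected one of {FLEETS}"
            )
        if not (-90.0 <= self.lat <= 90.0):
            raise TrackFormatError(f"latitude {self.lat} outside [-90, 90]")


# --------------------------------------------------------------------------- projection
@dataclass
class AzimuthalEquidistant:
    """Spherical azimuthal-equidistant projection centred on (lon0, lat0).

    Distances from the centre are preserved exactly; output in kilometres.
    Adequate for regional tracks (planar distortion grows beyond ~1000 km
    from the centre, for which a warning is emitted at projection time).
    """

    lon0: float
    lat0: float
    radius_km: float = EARTH_RADIUS_KM

    def forward(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        lam0, phi0 = np.radians(self.lon0), np.radians(self.lat0)
        dlam = lon - lam0
        cosc = np.sin(phi0) * np.sin(lat) + np.cos(phi0) * np.cos(lat) * np.cos(dlam)
        cosc = np.clip(cosc, -1.0, 1.0)
        c = np.arccos(cosc)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(c), 1.0)
        x = self.radius_km * k * np.cos(lat) * np.sin(dlam)
        y = self.radius_km * k * (
            np.cos(phi0) * np.sin(lat) - np.sin(phi0) * np.cos(lat) * np.cos(dlam)
        )
        return x, y

    def inverse(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float) / self.radius_km
        y = np.asarray(y, dtype=float) / self.radius_km
        lam0, phi0 = np.radians(self.lon0), np.radians(self.lat0)
        c = np.hypot(x, y)
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc_over_c = np.where(c > 1e-12, np.sin(c) / c, 1.0)
        lat = np.arcsin(np.cos(c) * np.sin(phi0) + y * sinc_over_c * np.cos(phi0))
        lon = lam0 + np.arctan2(
            x * sinc_over_c,
            np.cos(c) * np.cos(phi0) - y * sinc_over_c * np.sin(phi0),
        )
        return np.degrees(lon), np.degrees(lat)


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in kilometres (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


# --------------------------------------------------------------------------- readers
_DEFAULT_ARGOS_COLUMNS = {
    "animal_id": "animal_id",
    "timestamp": "timestamp",
    "lon": "lon",
    "lat": "lat",
    "location_class": "location_class",
    "ellipse_semi_major": "ellipse_semi_major",
    "ellipse_semi_minor": "ellipse_semi_minor",
    "ellipse_orientation": "ellipse_orientation",
}

_MANDATORY_ARGOS = ("animal_id", "timestamp", "lon", "lat", "location_class")


def read_argos_table(path, columns: dict[str, str] | None = None) -> list[ArgosTrack]:
    """Read a delimited relocation table into one :class:`ArgosTrack` per animal.

    Parameters
    ----------
    path
        CSV file with one row per relocation; timestamps ISO-8601.
    columns
        Optional mapping from canonical field names to the file's column
        names (defaults assume canonical names).

    Rows are sorted by timestamp within each animal; exact duplicate
    timestamps are resolved by keeping the first occurrence (logged).
    """
    colmap = dict(_DEFAULT_ARGOS_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    for canon in _MANDATORY_ARGOS:
        if colmap[canon] not in df.columns:
            raise TrackFormatError(
                f"track table {path} is missing mandatory column {colmap[canon]!r} ({canon})"
            )
    try:
        ts = pd.to_datetime(df[colmap["timestamp"]], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        # locate the offending row for a useful message
        for i, raw in enumerate(df[colmap["timestamp"]]):
            try:
                pd.to_datetime(raw, utc=True)
            except (ValueError, TypeError):
                raise TrackFormatError(
                    f"unparseable timestamp {raw!r} at data row {i + 1} of {path}"
                ) from None
        raise
    df = df.assign(_ts=ts)

    tracks: list[ArgosTrack] = []
    for animal_id, grp in df.groupby(colmap["animal_id"], sort=True):
        grp = grp.sort_values("_ts", kind="stable")
        dup = grp["_ts"].duplicated(keep="first")
        if dup.any():
            logger.info(
                "track %s: dropped %d duplicate-timestamp row(s), kept first",
                animal_id,
                int(dup.sum()),
            )
            grp = grp[~dup]
        relocs = []
        for _, row in grp.iterrows():
            def _opt(name: str) -> float | None:
                col = colmap[name]
                if col not in grp.columns:
                    return None
                v = row[col]
                return None if pd.isna(v) else float(v)

            relocs.append(
                ArgosRelocation(
                    timestamp=row["_ts"].to_pydatetime(),
                    lon=float(row[colmap["lon"]]),
                    lat=float(row[colmap["lat"]]),
                    location_class=str(row[colmap["location_class"]]),
                    ellipse_semi_major=_opt("ellipse_semi_major"),
                    ellipse_semi_minor=_opt("ellipse_semi_minor"),
                    ellipse_orientation=_opt("ellipse_orientation"),
                )
            )
        tracks.append(ArgosTrack(animal_id=str(animal_id), relocations=relocs))
    return tracks


_DEFAULT_VESSEL_COLUMNS = {
    "vessel_id": "vessel_id",
    "fleet": "fleet",
    "timestamp": "timestamp",
    "lon": "lon",
    "lat": "lat",
}


def read_vessel_table(path, columns: dict[str, str] | None = None) -> list[VesselRecord]:
    """Read a delimited vessel tracking table; validates fleet labels."""
    colmap = dict(_DEFAULT_VESSEL_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"vessel table {path} is empty", stacklevel=2)
        return []
    for canon, col in colmap.items():
        if col not in df.columns:
            raise TrackFormatError(
                f"vessel table {path} is missing mandatory column {col!r} ({canon})"
            )
    ts = pd.to_datetime(df[colmap["timestamp"]], utc=True, format="ISO8601")
    records = [
        VesselRecord(
            vessel_id=str(row[colmap["vessel_id"]]),
            fleet=str(row[colmap["fleet"]]),
            timestamp=t.to_pydatetime(),
            lon=float(row[colmap["lon"]]),
            lat=float(row[colmap["lat"]]),
        )
        for (_, row), t in zip(df.iterrows(), ts)
    ]
    return records


# --------------------------------------------------------------------------- operations
def impute_ellipses_by_class(
    donors: list[ArgosTrack], recipients: list[ArgosTrack]
) -> list[ArgosTrack]:
    """Fill missing error ellipses from per-class donor means.

    For each Argos location class the arithmetic mean of semi-major,
    semi-minor and orientation over all donor relocations of that class is
    assigned to recipient relocations of the same class that lack an
    ellipse.  Relocations that already carry an ellipse are untouched.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for track in donors:
        for r in track.relocations:
            if r.has_ellipse:
                v = np.array([r.ellipse_semi_major, r.ellipse_semi_minor, r.ellipse_orientation])
                sums[r.location_class] = sums.get(r.location_class, np.zeros(3)) + v
                counts[r.location_class] = counts.get(r.location_class, 0) + 1
    means = {cls: sums[cls] / counts[cls] for cls in sums}

    out: list[ArgosTrack] = []
    for track in recipients:
        relocs = []
        for r in track.relocations:
            if r.has_ellipse:
                relocs.append(r)
                continue
            if r.location_class not in means:
                raise ValueError(
                    f"no donor ellipses for location class {r.location_class!r} "
                    f"(track {track.animal_id!r})"
                )
            smaj, smin, orient = means[r.location_class]
            relocs.append(
                replace(
                    r,
                    ellipse_semi_major=float(smaj),
                    ellipse_semi_minor=float(smin),
                    ellipse_orientation=float(orient),
                )
            )
        out.append(
            ArgosTrack(
                animal_id=track.animal_id,
                relocations=relocs,
                projected_xy=track.projected_xy,
                projection=track.projection,
            )
        )
    return out


def _implied_speeds_ms(relocs: list[ArgosRelocation]) -> np.ndarray:
    """Speeds (m/s) between consecutive relocations via great-circle distance."""
    lon = np.array([r.lon for r in relocs])
    lat = np.array([r.lat for r in relocs])
    ts = np.array([r.timestamp.timestamp() for r in relocs])
    dist_m = great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:]) * 1000.0
    dt_s = np.diff(ts)
    return dist_m / dt_s


def speed_filter(track: ArgosTrack, vmax: float = 3.0) -> ArgosTrack:
    """Iteratively remove relocations implying speeds above ``vmax`` (m/s).

    At each pass the worst-offending consecutive pair is located and the
    interior point whose removal best reduces the local implied speeds is
    dropped (ties broken by removing the later point; the first and last
    relocations are never removed).  Terminates when all consecutive
    implied speeds are <= ``vmax``.
    """
    relocs = list(track.relocations)
    while True:
        if len(relocs) < 2:
            raise DegenerateTrackError(
                f"speed filter reduced track {track.animal_id!r} below 2 relocations"
            )
        speeds = _implied_speeds_ms(relocs)
        worst = int(np.argmax(speeds))
        if speeds[worst] <= vmax:
            break
        i, j = worst, worst + 1  # candidate removals: endpoints of the worst leg
        candidates = [k for k in (j, i) if 0 < k < len(relocs) - 1]  # later first
        if not candidates:
            raise DegenerateTrackError(
                f"track {track.animal_id!r}: speed {speeds[worst]:.2f} m/s between the "
                "first and last relocations cannot be removed"
            )

        def _local_max_after_removal(k: int) -> float:
            sub = relocs[max(k - 1, 0) : k] + relocs[k + 1 : k + 2]
            if len(sub) < 2:
                return 0.0
            return float(_implied_speeds_ms(sub).max())

        best = min(candidates, key=_local_max_after_removal)  # ties keep the later (first listed)
        del relocs[best]

    filtered = ArgosTrack(animal_id=track.animal_id, relocations=relocs)
    assert (_implied_speeds_ms(relocs) <= vmax + 1e-12).all()
    return filtered


def project_track(
    track: ArgosTrack, projection: AzimuthalEquidistant | None = None
) -> ArgosTrack:
    """Fill ``projected_xy`` (km) under a planar projection.

    The default projection is azimuthal equidistant centred on the track's
    centroid, so coordinates are small and locally near-Euclidean.
    """
    lonlat = track.lonlat()
    if projection is None:
        projection = AzimuthalEquidistant(
            lon0=float(lonlat[:, 0].mean()), lat0=float(lonlat[:, 1].mean())
        )
    x, y = projection.forward(lonlat[:, 0], lonlat[:, 1])
    xy = np.column_stack([x, y])
    if np.hypot(x, y).max() > 1000.0:
        warnings.warn(
            f"track {track.animal_id!r} spans more than 1000 km from the projection "
            "centre; planar distortion may be appreciable",
            stacklevel=2,
        )
    return ArgosTrack(
        animal_id=track.animal_id,
        relocations=list(track.relocations),
        projected_xy=xy,
        projection=projection,
    )


def truncate_after(track: ArgosTrack, timestamp) -> ArgosTrack:
    """Drop relocations after ``timestamp`` (e.g. a pre-migration cut-off)."""
    cutoff = pd.Timestamp(timestamp)
    if cutoff.tzinfo is None:
        cutoff = cutoff.tz_localize("UTC")
    relocs = [r for r in track.relocations if pd.Timestamp(r.timestamp) <= cutoff]
    if len(relocs) < 2:
        raise DegenerateTrackError(
            f"truncation leaves track {track.animal_id!r} with fewer than 2 relocations"
        )
    return ArgosTrack(animal_id=track.animal_id, relocations=relocs)
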