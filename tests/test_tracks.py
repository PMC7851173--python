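"""Telemetry table reading, filtering, imputation and projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from movescape.tracks import (
    ArgosRelocation,
    ArgosTrack,
    AzimuthalEquidistant,
    DegenerateTrackError,
    TrackFormatError,
    great_circle_km,
    impute_ellipses_by_class,
    project_track,
    read_argos_table,
    read_vessel_table,
    speed_filter,
    truncate_after,
)

from conftest import make_track


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadArgosTable:
    def test_single_animal(self, tmp_path):
        path = _write(
            tmp_path,
            "t.csv",
            "animal_id,timestamp,lon,lat,location_class\n"
            "w1,2019-03-01T00:00:00Z,-73.5,-43.5,3\n"
            "w1,2019-03-01T01:00:00Z,-73.51,-43.51,2\n"
            "w1,2019-03-01T02:00:00Z,-73.52,-43.52,B\n",
        )
        (track,) = read_argos_table(path)
        assert track.animal_id == "w1"
        assert track.n == 3
        assert [r.location_class for r in track.relocations] == ["3", "2", "B"]

    def test_interleaved_animals_are_split_and_sorted(self, tmp_path):
        path = _write(
            tmp_path,
            "t.csv",
            "animal_id,timestamp,lon,lat,location_class\n"
            "w1,2019-03-01T02:00:00Z,-73.5,-43.5,1\n"
            "w2,2019-03-01T00:00:00Z,-73.6,-43.6,1\n"
            "w1,2019-03-01T00:00:00Z,-73.5,-43.5,1\n"
            "w2,2019-03-01T01:00:00Z,-73.6,-43.6,1\n",
        )
        tracks = read_argos_table(path)
        assert [t.animal_id for t in tracks] == ["w1", "w2"]
        for t in tracks:
            ts = t.timestamps()
            assert (ts[1:] > ts[:-1]).all()

    def test_out_of_range_latitude_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            "t.csv",
            "animal_id,timestamp,lon,lat,location_class\n"
            "w1,2019-03-01T00:00:00Z,-73.5,95.0,1\n"
            "w1,2019-03-01T01:00:00Z,-73.5,-43.5,1\n",
        )
        with pytest.raises(TrackFormatError, match="latitude"):
            read_argos_table(path)

    def test_missing_column_named_in_error(self, tmp_path):
        path = _write(tmp_path, "t.csv", "animal_id,timestamp,lon\nw1,2019-03-01,1\n")
        with pytest.raises(TrackFormatError, match="lat"):
            read_argos_table(path)

    def test_duplicate_timestamps_keep_first(self, tmp_path):
        path = _write(
            tmp_path,
            "t.csv",
            "animal_id,timestamp,lon,lat,location_class\n"
            "w1,2019-03-01T00:00:00Z,-73.50,-43.5,1\n"
            "w1,2019-03-01T01:00:00Z,-73.51,-43.5,1\n"
            "w1,2019-03-01T01:00:00Z,-99.00,-43.5,1\n",
        )
        (track,) = read_argos_table(path)
        assert track.n == 2
        assert track.relocations[1].lon == -73.51


class TestReadVesselTable:
    def test_basic(self, tmp_path):
        path = _write(
            tmp_path,
            "v.csv",
            "vessel_id,fleet,timestamp,lon,lat\n"
            "a,aquaculture,2019-03-01T00:00:00Z,-73.5,-43.5\n"
            "a,aquaculture,2019-03-01T01:00:00Z,-73.6,-43.5\n"
            "b,aquaculture,2019-03-01T00:00:00Z,-73.7,-43.6\n"
            "b,aquaculture,2019-03-01T02:00:00Z,-73.8,-43.6\n",
        )
        records = read_vessel_table(path)
        assert len(records) == 4
        assert {r.vessel_id for r in records} == {"a", "b"}

    def test_unknown_fleet_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            "v.csv",
            "vessel_id,fleet,timestamp,lon,lat\na,whaling,2019-03-01T00:00:00Z,-73.5,-43.5\n",
        )
        with pytest.raises(TrackFormatError, match="fleet"):
            read_vessel_table(path)

    def test_empty_file_warns(self, tmp_path):
        path = _write(tmp_path, "v.csv", "vessel_id,fleet,timestamp,lon,lat\n")
        with pytest.warns(UserWarning, match="empty"):
            assert read_vessel_table(path) == []


class TestImputeEllipses:
    def _reloc(self, hour, cls, ellipse=None):
        from datetime import datetime, timedelta, timezone

        e = ellipse or (None, None, None)
        return ArgosRelocation(
            timestamp=datetime(2019, 3, 1, tzinfo=timezone.utc) + timedelta(hours=hour),
            lon=-73.5,
            lat=-43.5,
            location_class=cls,
            ellipse_semi_major=e[0],
            ellipse_semi_minor=e[1],
            ellipse_orientation=e[2],
        )

    def test_per_class_mean_assigned(self):
        donor = ArgosTrack(
            "d",
            [self._reloc(0, "3", (100, 50, 10)), self._reloc(1, "3", (300, 150, 30))],
        )
        recip = ArgosTrack("r", [self._reloc(0, "3"), self._reloc(1, "3")])
        (out,) = impute_ellipses_by_class([donor], [recip])
        r = out.relocations[0]
        assert (r.ellipse_semi_major, r.ellipse_semi_minor, r.ellipse_orientation) == (
            200.0,
            100.0,
            20.0,
        )

    def test_existing_ellipse_untouched_and_order_preserved(self):
        donor = ArgosTrack(
            "d", [self._reloc(0, "3", (100, 50, 10)), self._reloc(1, "3", (300, 150, 30))]
        )
        recip = ArgosTrack(
            "r", [self._reloc(0, "3", (999, 99, 9)), self._reloc(1, "3")]
        )
        (out,) = impute_ellipses_by_class([donor], [recip])
        assert out.n == recip.n
        assert out.relocations[0].ellipse_semi_major == 999
        assert out.relocations[1].ellipse_semi_major == 200.0

    def test_unknown_class_in_recipient_errors(self):
        donor = ArgosTrack(
            "d", [self._reloc(0, "3", (100, 50, 10)), self._reloc(1, "3", (300, 150, 30))]
        )
        recip = ArgosTrack("r", [self._reloc(0, "B"), self._reloc(1, "B")])
        with pytest.raises(ValueError, match="'B'"):
            impute_ellipses_by_class([donor], [recip])


class TestSpeedFilter:
    def _track_from_lonlat(self, lonlat, dt_hours=1.0):
        lonlat = np.asarray(lonlat, dtype=float)
        return make_track(np.zeros_like(lonlat), dt_hours=dt_hours, lonlat=lonlat)

    def test_slow_pair_kept(self):
        # ~1 km apart, 1 h apart -> ~0.28 m/s
        track = self._track_from_lonlat([[-73.5, -43.5], [-73.5, -43.509]])
        assert speed_filter(track).n == 2

    def test_spike_removed(self):
        # middle point displaced ~1 degree: both adjacent legs are fast
        track = self._track_from_lonlat(
            [[-73.5, -43.5], [-73.5, -44.5], [-73.5, -43.502]]
        )
        out = speed_filter(track)
        assert out.n == 2
        assert [r.lat for r in out.relocations] == [-43.5, -43.502]

    def test_stationary_track_unchanged(self):
        track = self._track_from_lonlat([[-73.5, -43.5]] * 4)
        assert speed_filter(track).n == 4

    def test_idempotent_and_bounded_on_random_tracks(self, rng):
        from movescape.tracks import _implied_speeds_ms

        for _ in range(10):
            n = rng.integers(5, 25)
            lonlat = np.column_stack(
                [
                    -73.5 + np.cumsum(rng.normal(0, 0.05, n)),
                    -43.5 + np.cumsum(rng.normal(0, 0.05, n)),
                ]
            )
            track = self._track_from_lonlat(lonlat, dt_hours=rng.uniform(0.5, 3.0, n - 1))
            try:
                once = speed_filter(track)
            except DegenerateTrackError:
                continue
            assert (_implied_speeds_ms(once.relocations) <= 3.0 + 1e-9).all()
            twice = speed_filter(once)
            assert twice.n == once.n

    def test_unfilterable_two_point_sprint_errors(self):
        track = self._track_from_lonlat([[-73.5, -43.5], [-70.0, -43.5]])
        with pytest.raises(DegenerateTrackError):
            speed_filter(track)


class TestProjection:
    def test_centre_maps_to_origin(self):
        proj = AzimuthalEquidistant(lon0=-73.5, lat0=-43.5)
        x, y = proj.forward(-73.5, -43.5)
        assert abs(float(x)) < 1e-9 and abs(float(y)) < 1e-9

    def test_meridian_distance_matches_geodesic(self):
        # 0.1 degrees of latitude is ~11.1 km along a meridian
        proj = AzimuthalEquidistant(lon0=-73.5, lat0=-43.5)
        _, y = proj.forward(-73.5, -43.4)
        expected = great_circle_km(-73.5, -43.5, -73.5, -43.4)
        assert y == pytest.approx(float(expected), rel=1e-9)
        assert y == pytest.approx(11.1, abs=0.05)

    @given(
        dlon=st.floats(-4.0, 4.0),
        dlat=st.floats(-4.0, 4.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_round_trip_is_identity(self, dlon, dlat):
        proj = AzimuthalEquidistant(lon0=-73.5, lat0=-43.5)
        lon, lat = -73.5 + dlon, -43.5 + dlat
        x, y = proj.forward(lon, lat)
        lon2, lat2 = proj.inverse(x, y)
        assert float(lon2) == pytest.approx(lon, abs=1e-9)
        assert float(lat2) == pytest.approx(lat, abs=1e-9)

    def test_project_track_fills_xy_and_round_trips(self, rng):
        lonlat = np.column_stack(
            [-73.5 + rng.normal(0, 1, 6), -43.5 + rng.normal(0, 1, 6)]
        )
        track = make_track(np.zeros((6, 2)), lonlat=lonlat)
        out = project_track(track)
        assert out.projected_xy.shape == (6, 2)
        lon2, lat2 = out.projection.inverse(out.projected_xy[:, 0], out.projected_xy[:, 1])
        np.testing.assert_allclose(lon2, lonlat[:, 0], atol=1e-9)
        np.testing.assert_allclose(lat2, lonlat[:, 1], atol=1e-9)

    def test_round_trip_within_500km_below_1m(self, rng):
        proj = AzimuthalEquidistant(lon0=-73.5, lat0=-43.5)
        lon = -73.5 + rng.uniform(-5, 5, 200)
        lat = -43.5 + rng.uniform(-4.5, 4.5, 200)
        x, y = proj.forward(lon, lat)
        keep = np.hypot(x, y) < 500
        lon2, lat2 = proj.inverse(x[keep], y[keep])
        err_km = great_circle_km(lon[keep], lat[keep], lon2, lat2)
        assert err_km.max() < 1e-3


def test_truncate_after_drops_later_relocations():
    track = make_track(np.zeros((5, 2)), dt_hours=1.0)
    cutoff = track.timestamps()[2]
    out = truncate_after(track, cutoff)
    assert out.n == 3
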