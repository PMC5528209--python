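import io

import numpy as np
import pandas as pd
import pytest

from foragescale.telemetry import (
    EARTH_RADIUS_M,
    Track,
    load_tracks,
    project_planar,
    split_on_gaps,
    step_lengths,
    summarize_track,
    track_to_geojson,
    unproject_planar,
)

from conftest import make_track

CSV_ONE = """id,timestamp,lon,lat,species,site
b1,2020-01-01T00:00:00Z,18.0,-34.0,EG,STR
b1,2020-01-01T02:00:00Z,18.01,-34.01,EG,STR
b1,2020-01-01T04:00:00Z,18.02,-34.0,EG,STR
"""

CSV_TWO_IDS = """id,timestamp,lon,lat
b2,2020-01-01T02:00:00Z,18.01,-34.01
b1,2020-01-01T00:00:00Z,18.0,-34.0
b1,2020-01-01T04:00:00Z,18.02,-34.0
b2,2020-01-01T00:00:00Z,18.0,-34.0
"""

CSV_DUP = """id,timestamp,lon,lat
b1,2020-01-01T00:00:00Z,18.0,-34.0
b1,2020-01-01T02:00:00Z,18.01,-34.01
b1,2020-01-01T02:00:00Z,18.99,-34.99
b1,2020-01-01T04:00:00Z,18.02,-34.0
"""


class TestLoadTracks:
    def test_single_individual(self):
        (track,) = load_tracks(io.StringIO(CSV_ONE))
        assert track.n_fixes == 3
        assert track.species == "EG" and track.site == "STR"
        assert np.allclose(track.t, [0, 7200, 14400])

    def test_two_interleaved_ids_are_partitioned_and_sorted(self):
        tracks = load_tracks(io.StringIO(CSV_TWO_IDS))
        assert [t.individual_id for t in tracks] == ["b1", "b2"]
        for t in tracks:
            assert np.all(np.diff(t.t) > 0)

    def test_duplicate_timestamp_keeps_first(self):
        (track,) = load_tracks(io.StringIO(CSV_DUP))
        assert track.n_fixes == 3
        assert track.lon[1] == 18.01  # first occurrence wins

    def test_missing_column_is_schema_error(self):
        with pytest.raises(ValueError, match="missing"):
            load_tracks(io.StringIO("id,timestamp\nb1,2020-01-01\nb1,2020-01-02\n"))

    def test_unparseable_timestamp_reports_row(self):
        bad = CSV_ONE.replace("2020-01-01T02:00:00Z", "not-a-time")
        with pytest.raises(ValueError, match="row 1"):
            load_tracks(io.StringIO(bad))

    def test_singleton_id_skipped(self):
        csv = CSV_ONE + "lonely,2020-01-01T00:00:00Z,18.0,-34.0\n"
        tracks = load_tracks(io.StringIO(csv))
        assert [t.individual_id for t in tracks] == ["b1"]

    def test_planar_xy_columns_accepted(self):
        csv = "id,timestamp,x,y\nb1,2020-01-01T00:00Z,0,0\nb1,2020-01-01T02:00Z,100,100\n"
        (track,) = load_tracks(io.StringIO(csv))
        assert track.is_projected


class TestSplitOnGaps:
    def test_regular_track_unchanged(self):
        t = make_track(np.zeros((5, 2)) + np.arange(5)[:, None], dt=7200.0)
        assert split_on_gaps(t) == [t]

    def test_eight_day_gap_splits_in_two(self):
        times = np.array([0, 7200, 14400, 14400 + 8 * 86400, 14400 + 8 * 86400 + 7200])
        track = Track(
            "b1", times, pd.Timestamp("2020-01-01", tz="UTC"), x=np.arange(5.0), y=np.zeros(5)
        )
        pieces = split_on_gaps(track)
        assert [p.n_fixes for p in pieces] == [3, 2]
        assert [p.split_suffix for p in pieces] == ["", "a"]
        assert pieces[1].start_time == track.timestamps[3]

    def test_exactly_seven_day_gap_does_not_split(self):
        times = np.array([0.0, 7 * 86400, 7 * 86400 + 7200])
        track = Track(
            "b1", times, pd.Timestamp("2020-01-01", tz="UTC"), x=np.arange(3.0), y=np.zeros(3)
        )
        assert len(split_on_gaps(track)) == 1

    def test_split_is_idempotent_and_concatenation_recovers_fixes(self, rng):
        n = 40
        gaps = rng.uniform(3600, 2 * 86400, size=n - 1)
        gaps[[9, 24]] = 9 * 86400
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        xy = rng.normal(size=(n, 2))
        track = Track("b1", times, pd.Timestamp("2020-01-01", tz="UTC"), x=xy[:, 0], y=xy[:, 1])
        pieces = split_on_gaps(track)
        assert len(pieces) == 3
        for p in pieces:
            assert split_on_gaps(p) == [p]  # idempotent
        assert np.concatenate([p.x for p in pieces]).tolist() == track.x.tolist()
        stitched = np.concatenate(
            [(p.start_time - track.start_time).total_seconds() + p.t for p in pieces]
        )
        assert np.allclose(stitched, track.t)


class TestProjection:
    def test_center_maps_to_origin(self):
        track = Track(
            "b1",
            np.array([0.0, 7200.0]),
            pd.Timestamp("2020-01-01", tz="UTC"),
            lon=np.array([18.0, 18.0]),
            lat=np.array([-34.0, -34.0]),
        )
        proj = project_planar(track)
        assert np.allclose(proj.x, 0) and np.allclose(proj.y, 0)

    def test_latitude_step_matches_great_circle(self):
        # 0.01 deg of latitude = R * 0.01 * pi/180 along a meridian
        track = Track(
            "b1",
            np.array([0.0, 7200.0]),
            pd.Timestamp("2020-01-01", tz="UTC"),
            lon=np.array([18.0, 18.0]),
            lat=np.array([-34.0, -33.99]),
        )
        proj = project_planar(track)
        expected = EARTH_RADIUS_M * np.radians(0.01)
        assert step_lengths(proj)[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1111.95, abs=0.01)

    def test_round_trip(self, rng):
        lon = 18.0 + rng.uniform(-1, 1, 30)
        lat = -34.0 + rng.uniform(-1, 1, 30)
        track = Track(
            "b1", 60.0 * np.arange(30), pd.Timestamp("2020-01-01", tz="UTC"), lon=lon, lat=lat
        )
        back = unproject_planar(project_planar(track))
        assert np.allclose(back.lon, lon, atol=1e-9)
        assert np.allclose(back.lat, lat, atol=1e-9)

    def test_out_of_range_coordinates_rejected(self):
        track = Track(
            "b1",
            np.array([0.0, 60.0]),
            pd.Timestamp("2020-01-01", tz="UTC"),
            lon=np.array([181.0, 18.0]),
            lat=np.array([-34.0, -34.0]),
        )
        with pytest.raises(ValueError):
            project_planar(track)


class TestSummaries:
    def test_distance_and_rate(self):
        xy = np.array([[0, 0], [3000, 4000], [3000, 4000]])  # 5 km then rest
        track = make_track(xy, dt=43200.0)  # one-day span
        s = summarize_track(track)
        assert s.total_distance_km == pytest.approx(5.0)
        assert s.days_tracked == pytest.approx(1.0)
        assert s.km_per_day == pytest.approx(5.0)

    def test_stationary_track(self):
        s = summarize_track(make_track(np.zeros((4, 2)), dt=3600.0))
        assert s.total_distance_km == 0.0
        assert s.km_per_day == 0.0

    def test_zero_duration_rejected(self):
        # non-increasing timestamps are rejected at construction already
        with pytest.raises(ValueError):
            Track(
                "b1",
                np.array([0.0, 0.0]),
                pd.Timestamp("2020-01-01", tz="UTC"),
                x=np.zeros(2),
                y=np.zeros(2),
            )

    def test_distance_invariant_under_rotation(self, rng):
        xy = rng.normal(scale=1000, size=(50, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        d1 = summarize_track(make_track(xy)).total_distance_km
        d2 = summarize_track(make_track(xy @ rot.T)).total_distance_km
        assert d2 == pytest.approx(d1, rel=1e-6)


def test_geojson_export_round_trips_coordinates(rng):
    lon = 18.0 + rng.uniform(-0.1, 0.1, 5)
    lat = -34.0 + rng.uniform(-0.1, 0.1, 5)
    track = Track(
        "b1", 60.0 * np.arange(5), pd.Timestamp("2020-01-01", tz="UTC"), lon=lon, lat=lat
    )
    feature = track_to_geojson(project_planar(track))
    coords = np.asarray(feature["geometry"]["coordinates"])
    assert feature["geometry"]["type"] == "LineString"
    assert np.allclose(coords[:, 0], lon, atol=1e-6)
    assert np.allclose(coords[:, 1], lat, atol=1e-6)
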