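import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st

from glacierseg.trajectory import (
    Colony,
    FixParseError,
    Trip,
    TripParams,
    filter_overland,
    filter_speed,
    land_fraction,
    mann_whitney_u,
    read_fixes,
    segment_trips,
    sex_from_headbill,
    subsample_interval,
)
from conftest import fixes_frame

COLONY = Colony(id="C01", lon=12.30, lat=78.95, size=500)

# ~degrees of latitude per km at any latitude
DLAT_KM = 1.0 / 111.195


def offset_latlon(km_north):
    return 78.95 + km_north * DLAT_KM


class TestReadFixes:
    def _write(self, tmp_path, rows, header="individual_id,colony_id,timestamp_iso8601_utc,lon_wgs84,lat_wgs84"):
        p = tmp_path / "fixes.csv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_well_formed(self, tmp_path):
        p = self._write(tmp_path, [
            "B1,C01,2017-07-15T00:00:00Z,12.30,78.95",
            "B1,C01,2017-07-15T00:10:00Z,12.31,78.95",
            "B1,C01,2017-07-15T00:20:00Z,12.32,78.95",
        ])
        out = read_fixes(p)
        assert list(out) == ["B1"]
        assert len(out["B1"]) == 3

    def test_out_of_order_sorted(self, tmp_path):
        p = self._write(tmp_path, [
            "B1,C01,2017-07-15T00:20:00Z,12.32,78.95",
            "B1,C01,2017-07-15T00:00:00Z,12.30,78.95",
            "B1,C01,2017-07-15T00:10:00Z,12.31,78.95",
        ])
        out = read_fixes(p)["B1"]
        assert out["timestamp"].is_monotonic_increasing
        assert out["lon"].tolist() == [12.30, 12.31, 12.32]

    def test_out_of_bounds_latitude_rejected_with_line(self, tmp_path):
        p = self._write(tmp_path, [
            "B1,C01,2017-07-15T00:00:00Z,12.30,78.95",
            "B1,C01,2017-07-15T00:10:00Z,12.31,97.0",
        ])
        with pytest.raises(FixParseError, match="line 3"):
            read_fixes(p)

    def test_unparseable_timestamp_rejected(self, tmp_path):
        p = self._write(tmp_path, ["B1,C01,not-a-time,12.30,78.95"])
        with pytest.raises(FixParseError, match="line 2"):
            read_fixes(p)

    def test_duplicate_timestamps_collapsed(self, tmp_path):
        p = self._write(tmp_path, [
            "B1,C01,2017-07-15T00:00:00Z,12.30,78.95",
            "B1,C01,2017-07-15T00:00:00Z,12.99,78.95",
            "B1,C01,2017-07-15T00:10:00Z,12.31,78.95",
        ])
        out = read_fixes(p)["B1"]
        assert len(out) == 2
        assert out["lon"].iloc[0] == 12.30  # first occurrence kept


class TestSpeedFilter:
    def test_aberrant_second_fix_removed(self):
        # 20 km in 10 min = 120 km/h
        f = fixes_frame([0, 10], [12.3, 12.3], [78.95, offset_latlon(20)])
        out = filter_speed(f, 80.0)
        assert len(out) == 1

    def test_legal_speeds_identity(self):
        f = fixes_frame([0, 10, 20], [12.3] * 3,
                        [78.95, offset_latlon(5), offset_latlon(10)])
        assert len(filter_speed(f, 80.0)) == 3

    def test_single_aberrant_middle_fix_removed_neighbours_kept(self):
        # A at 0 km, B jumps 30 km away, C back near A: only B violates
        f = fixes_frame([0, 10, 20], [12.3] * 3,
                        [78.95, offset_latlon(30), offset_latlon(5)])
        out = filter_speed(f, 80.0)
        assert len(out) == 2
        assert out["lat"].tolist() == [78.95, offset_latlon(5)]


class TestSubsample:
    def test_2min_data_every_fifth_kept(self):
        f = fixes_frame(np.arange(0, 60, 2), [12.3] * 30, [78.95] * 30)
        out = subsample_interval(f, 10.0, 1.0)
        t = (out["timestamp"] - out["timestamp"].iloc[0]).dt.total_seconds() / 60
        assert t.tolist() == [0, 10, 20, 30, 40, 50]

    def test_native_interval_identity(self):
        f = fixes_frame(np.arange(0, 120, 10), [12.3] * 12, [78.95] * 12)
        out = subsample_interval(f, 10.0, 1.0)
        assert len(out) == 12

    def test_long_gaps_retained(self):
        f = fixes_frame([0, 10, 55, 65], [12.3] * 4, [78.95] * 4)
        out = subsample_interval(f, 10.0, 1.0)
        t = (out["timestamp"] - out["timestamp"].iloc[0]).dt.total_seconds() / 60
        assert t.tolist() == [0, 10, 55, 65]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([2.0, 3.0]), min_size=30, max_size=80),
           st.integers(0, 2**31 - 1))
    def test_irregular_mix_gap_property(self, steps, seed):
        # with 2/3-min raw data every kept gap lands in [9, 11] min
        t = np.concatenate([[0.0], np.cumsum(steps)])
        f = fixes_frame(t, [12.3] * len(t), [78.95] * len(t))
        out = subsample_interval(f, 10.0, 1.0)
        gaps = np.diff(
            (out["timestamp"] - out["timestamp"].iloc[0]).dt.total_seconds() / 60
        )
        assert np.all((gaps >= 9.0) & (gaps <= 11.0))


class TestSegmentTrips:
    def _track(self, pattern, step=10.0):
        """pattern: string of 'c' (at colony) / 'a' (1 km away) fixes."""
        lat = [78.95 if ch == "c" else offset_latlon(1.0) for ch in pattern]
        t = np.arange(len(pattern)) * step
        return fixes_frame(t, [12.3] * len(pattern), lat)

    def test_basic_complete_trip(self):
        trips = segment_trips(self._track("ccccc" + "a" * 7 + "ccc"), COLONY)
        assert len(trips) == 1
        assert trips[0].complete
        assert len(trips[0].fixes) == 7
        assert trips[0].duration_min == 60.0

    def test_short_excursion_below_minimum_discarded(self):
        # 4 fixes = 30-min span < 50 min
        trips = segment_trips(self._track("cc" + "a" * 4 + "cc"), COLONY)
        assert trips == []

    def test_record_ending_away_flagged_incomplete(self):
        trips = segment_trips(self._track("ccc" + "a" * 7), COLONY)
        assert len(trips) == 1
        assert not trips[0].complete

    def test_empty_input(self):
        assert segment_trips(self._track(""), COLONY) == []

    def test_invariant_to_colony_fix_padding(self):
        core = "cc" + "a" * 8 + "cc"
        t1 = segment_trips(self._track(core), COLONY)
        t2 = segment_trips(self._track("cccc" + core + "ccc"), COLONY)
        assert len(t1) == len(t2) == 1
        assert len(t1[0].fixes) == len(t2[0].fixes)
        np.testing.assert_allclose(t1[0].fixes["lat"], t2[0].fixes["lat"])

    def test_max_range(self):
        trips = segment_trips(self._track("cc" + "a" * 7 + "cc"), COLONY)
        assert trips[0].max_range_km(COLONY) == pytest.approx(1.0, rel=1e-3)


class TestLandFilter:
    # a land square roughly east of lon 12.5
    LAND = shapely.Polygon([(12.5, 78.5), (13.5, 78.5), (13.5, 79.5), (12.5, 79.5)])

    def _trip(self, lons):
        f = fixes_frame(np.arange(len(lons)) * 10.0, lons, [78.95] * len(lons))
        return Trip(individual_id="B1", colony_id="C01", fixes=f,
                    complete=True, trip_index=0)

    def test_all_sea_zero_retained(self):
        tr = self._trip([12.3] * 10)
        assert land_fraction(tr, self.LAND) == 0.0
        assert filter_overland([tr], self.LAND) == [tr]

    def test_six_of_ten_on_land_removed(self):
        tr = self._trip([12.6] * 6 + [12.3] * 4)
        assert land_fraction(tr, self.LAND) == pytest.approx(0.6)
        assert filter_overland([tr], self.LAND) == []

    def test_exactly_half_removed(self):
        tr = self._trip([12.6] * 5 + [12.3] * 5)
        assert land_fraction(tr, self.LAND) == pytest.approx(0.5)
        assert filter_overland([tr], self.LAND) == []

    def test_degenerate_polygon_raises(self):
        tr = self._trip([12.3] * 3)
        with pytest.raises(ValueError):
            land_fraction(tr, shapely.Polygon())


class TestSexing:
    @pytest.mark.parametrize("length,expected", [
        (88.0, "female"),
        (90.5, "female"),  # boundary inclusive to female
        (92.1, "male"),
    ])
    def test_cutoff(self, length, expected):
        assert sex_from_headbill(length) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sex_from_headbill(0.0)


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0

    def test_identical_samples_u_half(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, _ = mann_whitney_u(x, x)
        assert u == len(x) * len(x) / 2.0

    def test_all_identical_p_one(self):
        assert mann_whitney_u([5, 5, 5], [5, 5])[1] == 1.0

    def test_u_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 15, 20).astype(float)
        y = rng.integers(0, 15, 20).astype(float)
        u, p = mann_whitney_u(x, y)
        brute = sum(
            (1.0 if xi > yj else 0.5 if xi == yj else 0.0) for xi in x for yj in y
        )
        assert u == pytest.approx(brute)

    def test_p_matches_scipy_asymptotic(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.5, 1, 30)
        u, p = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


def test_pipeline_order_is_fixed():
    with pytest.raises(ValueError, match="pipeline order"):
        TripParams(pipeline_order=("speed_filter", "subsample", "segment", "land_filter"))
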