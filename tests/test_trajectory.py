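"""Fix-stream reading, burst collapse, projection, and cleaning."""

import io
from datetime import date

import numpy as np
import pandas as pd
import pytest

from roost.projection import TransverseMercator
from roost.trajectory import (
    align_to_slots,
    collapse_bursts,
    day_coverage_hours,
    project_to_metric,
    read_fix_table,
    remove_impossible_fixes,
)


def _csv(rows, header="individual-local-identifier,timestamp,location-long,location-lat"):
    return io.StringIO(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))


class TestReadFixTable:
    def test_valid_rows_in_order(self):
        fixes, rejects = read_fix_table(
            _csv(
                [
                    "B1,2019-09-01 04:00:00,34.35,-18.95",
                    "B1,2019-09-01 04:15:00,34.351,-18.951",
                    "B2,2019-09-01 04:00:00,34.36,-18.96",
                    "B2,2019-09-01 04:15:00,34.361,-18.961",
                ]
            )
        )
        assert len(fixes) == 4 and len(rejects) == 0
        assert list(fixes["individual_id"]) == ["B1", "B1", "B2", "B2"]

    def test_out_of_bounds_latitude_rejected(self):
        fixes, rejects = read_fix_table(
            _csv(
                [
                    "B1,2019-09-01 04:00:00,34.35,-18.95",
                    "B1,2019-09-01 04:15:00,34.35,91.0",
                    "B1,2019-09-01 04:30:00,34.35,-18.95",
                    "B1,2019-09-01 04:45:00,34.35,-18.95",
                ]
            )
        )
        assert len(fixes) == 3
        assert len(rejects) == 1
        assert rejects["reject_reason"].iloc[0] == "coordinate out of bounds"

    def test_bad_timestamp_rejected_not_fatal(self):
        fixes, rejects = read_fix_table(
            _csv(
                [
                    "B1,2019-09-01 04:00:00,34.35,-18.95",
                    "B1,not-a-time,34.35,-18.95",
                ]
            )
        )
        assert len(fixes) == 1 and len(rejects) == 1

    def test_header_only_yields_empty(self):
        fixes, rejects = read_fix_table(_csv([]))
        assert len(fixes) == 0 and len(rejects) == 0

    def test_missing_mapped_column_raises(self):
        with pytest.raises(ValueError, match="missing mapped column"):
            read_fix_table(_csv([], header="a,b,c"))

    def test_all_rows_rejected_raises(self):
        with pytest.raises(ValueError, match="all .* rejected"):
            read_fix_table(_csv(["B1,bad,34.35,-18.95"]))

    def test_custom_column_map(self):
        buf = io.StringIO("id,t,lg,lt\nB1,2019-09-01 04:00:00,34.35,-18.95\n")
        fixes, _ = read_fix_table(
            buf,
            column_map={"individual_id": "id", "timestamp": "t", "lon": "lg", "lat": "lt"},
        )
        assert len(fixes) == 1


def _fix_frame(rows):
    df = pd.DataFrame(
        rows, columns=["individual_id", "timestamp", "lon", "lat", "burst_id"]
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


class TestCollapseBursts:
    def test_last_fix_of_burst_retained(self):
        df = _fix_frame(
            [
                ("B1", "2019-09-01 06:00:00", 34.35, -18.95, "b1"),
                ("B1", "2019-09-01 06:00:05", 34.36, -18.95, "b1"),
                ("B1", "2019-09-01 06:00:10", 34.37, -18.95, "b1"),
            ]
        )
        out = collapse_bursts(df)
        assert len(out) == 1
        assert out["timestamp"].iloc[0] == pd.Timestamp("2019-09-01 06:00:10", tz="UTC")
        assert out["lon"].iloc[0] == 34.37

    def test_no_burst_ids_passthrough(self):
        df = _fix_frame(
            [
                ("B1", "2019-09-01 06:00:00", 34.35, -18.95, None),
                ("B1", "2019-09-01 06:15:00", 34.36, -18.95, None),
            ]
        )
        out = collapse_bursts(df)
        pd.testing.assert_frame_equal(out, df)

    def test_one_fix_per_burst(self):
        rows = [("B1", f"2019-09-01 06:00:{s:02d}", 34.35, -18.95, "b1") for s in (0, 5)]
        rows += [
            ("B1", f"2019-09-01 06:15:{s:02d}", 34.36, -18.95, "b2")
            for s in (0, 5, 10, 15, 20)
        ]
        out = collapse_bursts(_fix_frame(rows))
        assert len(out) == 2

    def test_idempotent(self):
        rows = [
            ("B1", f"2019-09-01 06:00:{s:02d}", 34.35 + s * 1e-4, -18.95, "b1")
            for s in (0, 5, 10)
        ] + [("B1", "2019-09-01 06:15:00", 34.4, -18.95, None)]
        once = collapse_bursts(_fix_frame(rows))
        twice = collapse_bursts(once)
        pd.testing.assert_frame_equal(once, twice)


class TestProjection:
    def test_known_latitude_step(self):
        # 0.001 deg of latitude near 18.9 S spans ~110.6 m (ellipsoid arc)
        df = _fix_frame(
            [
                ("B1", "2019-09-01 06:00:00", 34.35, -18.900, None),
                ("B1", "2019-09-01 06:15:00", 34.35, -18.901, None),
            ]
        )
        traj = project_to_metric(df)["B1"]
        d = np.hypot(*(traj.xy()[1] - traj.xy()[0]))
        assert d == pytest.approx(110.6, abs=0.5)

    def test_identical_points_zero_distance(self):
        df = _fix_frame(
            [
                ("B1", "2019-09-01 06:00:00", 34.35, -18.95, None),
                ("B1", "2019-09-01 06:15:00", 34.35, -18.95, None),
            ]
        )
        traj = project_to_metric(df)["B1"]
        assert np.hypot(*(traj.xy()[1] - traj.xy()[0])) == 0.0

    def test_roundtrip_error_below_microdegree(self, rng):
        lon = 34.0 + rng.uniform(0, 1, 100)
        lat = -19.5 + rng.uniform(0, 1, 100)
        proj = TransverseMercator.utm_for(lon, lat)
        lon2, lat2 = proj.inverse(*proj.forward(lon, lat))
        assert np.max(np.abs(lon2 - lon)) < 1e-6
        assert np.max(np.abs(lat2 - lat)) < 1e-6

    def test_distance_matches_geodesic_within_half_percent(self, rng):
        # independent oracle: local metres-per-degree series at the mean
        # latitude (valid for short separations)
        lat0 = -18.9
        phi = np.radians(lat0)
        m_lat = 111132.92 - 559.82 * np.cos(2 * phi) + 1.175 * np.cos(4 * phi)
        m_lon = 111412.84 * np.cos(phi) - 93.5 * np.cos(3 * phi)
        proj = TransverseMercator.utm_for(np.array([34.35]), np.array([lat0]))
        for _ in range(50):
            dlon, dlat = rng.uniform(-0.2, 0.2, 2)
            geo = np.hypot(dlon * m_lon, dlat * m_lat)
            x1, y1 = proj.forward(34.35, lat0)
            x2, y2 = proj.forward(34.35 + dlon, lat0 + dlat)
            planar = np.hypot(x2 - x1, y2 - y1)
            assert planar == pytest.approx(geo, rel=5e-3)

    def test_shared_crs_across_individuals(self):
        df = _fix_frame(
            [
                ("B1", "2019-09-01 06:00:00", 34.35, -18.95, None),
                ("B2", "2019-09-01 06:00:00", 34.36, -18.96, None),
            ]
        )
        trajs = project_to_metric(df)
        assert trajs["B1"].crs_label == trajs["B2"].crs_label == "UTM 36S (WGS84)"


class TestRemoveImpossibleFixes:
    def test_isolated_12km_jump_removed(self, make_trajectory):
        traj = make_trajectory(
            [(0, 0, 0), (15, 12_000, 0), (30, 200, 0), (45, 400, 0)]
        )
        cleaned, report = remove_impossible_fixes(traj)
        assert report.n_outliers_removed == 1
        assert report.n_retained == 3
        assert 12_000 not in cleaned.fixes["x"].values

    def test_smooth_trajectory_untouched(self, make_trajectory):
        traj = make_trajectory([(15 * i, 600 * i, 0) for i in range(10)])
        cleaned, report = remove_impossible_fixes(traj)
        assert report.n_outliers_removed == 0
        assert len(cleaned) == 10

    def test_true_relocation_kept(self, make_trajectory):
        # two consecutive 12 km displacements: the next fix agrees with
        # the new position, so nothing is an outlier
        traj = make_trajectory(
            [(0, 0, 0), (15, 12_000, 0), (30, 12_100, 0), (45, 12_200, 0)]
        )
        cleaned, report = remove_impossible_fixes(traj)
        assert report.n_outliers_removed == 0

    def test_short_trajectory_unchanged(self, make_trajectory):
        traj = make_trajectory([(0, 0, 0), (15, 50_000, 0)])
        cleaned, report = remove_impossible_fixes(traj)
        assert len(cleaned) == 2 and report.n_outliers_removed == 0

    def test_long_gap_scales_threshold(self, make_trajectory):
        # 12 km moved over 24 h is possible; same jump in 15 min is not
        traj = make_trajectory([(0, 0, 0), (24 * 60, 12_000, 0), (24 * 60 + 15, 12_000, 100)])
        _, report = remove_impossible_fixes(traj)
        assert report.n_outliers_removed == 0

    def test_matches_bruteforce_neighbour_oracle(self, rng, make_trajectory):
        # oracle: flag interior fix i iff BOTH neighbour distances exceed
        # the per-gap threshold; implementation must never remove more
        for trial in range(20):
            n = int(rng.integers(10, 120))
            xy = np.cumsum(rng.normal(0, 300, (n, 2)), axis=0)
            burst = rng.random(n) < 0.05
            xy[burst] += rng.normal(0, 30_000, (burst.sum(), 2))
            traj = make_trajectory([(15 * i, xy[i, 0], xy[i, 1]) for i in range(n)])
            cleaned, report = remove_impossible_fixes(traj)
            flagged = 0
            for i in range(1, n - 1):
                d_prev = np.hypot(*(xy[i] - xy[i - 1]))
                d_next = np.hypot(*(xy[i] - xy[i + 1]))
                if d_prev > 10_000 and d_next > 10_000:
                    flagged += 1
            assert report.n_outliers_removed == flagged


class TestDayCoverage:
    def test_full_day_span(self, make_trajectory):
        traj = make_trajectory(
            [(15 * i, 0, 0) for i in range(53)], t0="2019-09-01 05:00:00"
        )  # 05:00 to 18:00
        assert day_coverage_hours(traj, date(2019, 9, 1)) == pytest.approx(13.0)

    def test_no_fixes_zero(self, make_trajectory):
        traj = make_trajectory([(0, 0, 0)], t0="2019-09-01 05:00:00")
        assert day_coverage_hours(traj, date(2019, 9, 2)) == 0.0

    def test_short_day_below_threshold(self, make_trajectory):
        traj = make_trajectory(
            [(15 * i, 0, 0) for i in range(17)], t0="2019-09-01 05:00:00"
        )  # 05:00 to 09:00
        hours = day_coverage_hours(traj, date(2019, 9, 1))
        assert hours == pytest.approx(4.0)
        assert hours < 8.0


class TestAlignToSlots:
    def test_duplicate_slot_keeps_last(self):
        df = _fix_frame(
            [
                ("B1", "2019-09-01 06:00:40", 34.35, -18.95, None),
                ("B1", "2019-09-01 06:02:00", 34.36, -18.95, None),
                ("B1", "2019-09-01 06:14:30", 34.37, -18.95, None),
            ]
        )
        out = align_to_slots(df)
        assert len(out) == 2  # 06:00 (last of two), 06:15
        assert out["lon"].tolist() == [34.36, 34.37]
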