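"""Stop detection, GoP merging, rolling windows, and day AOI records."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from roost.aoi import (
    assign_windows,
    day_aoi_record,
    detect_stops,
    filter_daytime,
    merge_stops,
)
from roost.sleep_sites import SleepNight
from roost.trajectory import Trajectory


def _traj(points, individual_id="B1", t0="2019-09-01 04:00:00"):
    base = pd.Timestamp(t0, tz="UTC")
    rows = [
        {"timestamp": base + pd.Timedelta(minutes=m), "x": float(x), "y": float(y)}
        for m, x, y in points
    ]
    return Trajectory(individual_id=individual_id, fixes=pd.DataFrame(rows))


def _night(d, x, y, ind="B1", hour=0):
    ts = pd.Timestamp(d, tz="UTC") + pd.Timedelta(hours=hour)
    return SleepNight(
        individual_id=ind, night_date=d, x=float(x), y=float(y),
        timestamp=ts, anchor_source="T0200",
    )


class TestDetectStops:
    def test_dwell_then_move(self):
        traj = _traj([(0, 0, 0), (15, 5, 0), (30, 8, 0), (45, 58, 0)])
        stops = detect_stops(traj)
        assert len(stops) == 1
        assert len(stops[0].xy) == 3
        assert stops[0].duration >= pd.Timedelta(minutes=30)

    def test_steady_travel_no_stops(self):
        traj = _traj([(15 * i, 50 * i, 0) for i in range(10)])
        assert detect_stops(traj) == []

    def test_origin_anchored_drift(self):
        # drifting +20 m per fix: the stop holds the fixes at 0 and 20 m
        # from the origin; the fix at 40 m closes it
        traj = _traj([(0, 0, 0), (15, 20, 0), (30, 40, 0), (45, 90, 0)])
        stops = detect_stops(traj)
        assert len(stops) == 1
        assert stops[0].xy[:, 0].tolist() == [0.0, 20.0]

    def test_closing_fix_can_open_next_stop(self):
        pts = [(0, 0, 0), (15, 10, 0), (30, 40, 0), (45, 45, 0), (60, 120, 0)]
        stops = detect_stops(_traj(pts))
        assert len(stops) == 2
        assert stops[1].origin[0] == 40.0

    def test_minimum_two_fixes(self):
        traj = _traj([(0, 0, 0), (15, 100, 0), (30, 105, 0), (45, 200, 0)])
        stops = detect_stops(traj, min_fixes=2)
        assert len(stops) == 1 and stops[0].origin[0] == 100.0

    def test_overnight_gap_breaks_stop(self):
        # same place evening and next morning, but 14 h apart: two stops
        pts = [(0, 0, 0), (15, 5, 0), (14 * 60, 8, 0), (14 * 60 + 15, 3, 0)]
        stops = detect_stops(_traj(pts))
        assert len(stops) == 2

    def test_radius_audit_invariant(self, rng):
        # every retained stop satisfies the origin-radius rule exactly
        steps = rng.normal(0, 40, (300, 2))
        xy = np.cumsum(steps, axis=0)
        traj = _traj([(15 * i, xy[i, 0], xy[i, 1]) for i in range(300)])
        for s in detect_stops(traj, radius_m=30.0):
            d = np.hypot(s.xy[:, 0] - s.origin[0], s.xy[:, 1] - s.origin[1])
            assert (d <= 30.0).all()
            assert len(s.xy) >= 2


def _stops_from_clusters(centers, t0="2019-09-01 08:00:00"):
    """One 3-fix stop at each centre, consecutive half-hours."""
    pts = []
    t = 0
    for cx, cy in centers:
        pts += [(t, cx, cy), (t + 15, cx + 3, cy), (t + 30, cx, cy + 3)]
        t += 45
        pts += [(t, cx + 500, cy + 500)]  # spacer travel fix
        t += 15
    return detect_stops(_traj(pts, t0=t0))


class TestMergeStops:
    def test_within_40m_merges(self):
        stops = _stops_from_clusters([(0, 0), (35, 0)])
        aois = merge_stops(stops, 40.0)
        assert len(aois) == 1
        assert aois[0].n_visits == 2
        assert aois[0].recurrent

    def test_beyond_40m_stays_separate(self):
        stops = _stops_from_clusters([(0, 0), (60, 0)])
        aois = merge_stops(stops, 40.0)
        assert len(aois) == 2
        assert not any(a.recurrent for a in aois)

    def test_chain_merges_transitively(self):
        # A-B 35 m, B-C 35 m, A-C 70 m: one AOI of three visits
        stops = _stops_from_clusters([(0, 0), (35, 0), (70, 0)])
        aois = merge_stops(stops, 40.0)
        assert len(aois) == 1 and aois[0].n_visits == 3

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(0, 600, (40, 2))
        stops = _stops_from_clusters(centers)
        aois = merge_stops(stops, 40.0)

        # oracle: all-pairs min inter-fix distance, then reachability
        n = len(stops)
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                dmin = min(
                    np.hypot(*(p - q))
                    for p in stops[i].xy
                    for q in stops[j].xy
                )
                adj[i, j] = adj[j, i] = dmin <= 40.0
        import networkx as nx

        g = nx.from_numpy_array(adj)
        want = {frozenset(c) for c in nx.connected_components(g)}
        got = {
            frozenset(s.stop_id for s in a.stops) for a in aois
        }
        assert got == want

    def test_polygon_contains_all_member_fixes(self, rng):
        centers = rng.uniform(0, 300, (15, 2))
        aois = merge_stops(_stops_from_clusters(centers), 40.0)
        from shapely.geometry import Point

        for a in aois:
            poly = a.polygon.buffer(1e-6)
            assert all(poly.contains(Point(*p)) for p in a.all_xy)

    def test_polygon_area_nondecreasing_under_merge(self):
        stops = _stops_from_clusters([(0, 0), (35, 0)])
        merged = merge_stops(stops, 40.0)[0]
        separate = merge_stops(stops, 10.0)
        assert merged.polygon.area >= max(a.polygon.area for a in separate)


class TestAssignWindows:
    def test_trailing_window_inclusion(self):
        stops = _stops_from_clusters([(0, 0)], t0="2019-09-05 08:00:00")
        win = assign_windows(stops, [date(2019, 9, 10)], window_days=30)
        assert win[date(2019, 9, 10)] == [0]

    def test_stop_outside_window_excluded(self):
        stops = _stops_from_clusters([(0, 0)], t0="2019-09-05 08:00:00")
        win = assign_windows(stops, [date(2019, 10, 15)], window_days=30)
        assert win[date(2019, 10, 15)] == []

    def test_windows_shift_with_date(self):
        stops = _stops_from_clusters(
            [(0, 0)], t0="2019-09-01 08:00:00"
        ) + _stops_from_clusters([(500, 500)], t0="2019-09-20 08:00:00")
        d1, d2 = date(2019, 9, 30), date(2019, 10, 5)
        win = assign_windows(stops, [d1, d2], window_days=30)
        assert set(win[d1]) == {0, 1}
        assert set(win[d2]) == {1}  # the Sep 1 stop has aged out


class TestFilterDaytime:
    def test_all_day_at_anchor_empty(self):
        nights = [_night(date(2019, 9, 1), 0, 0), _night(date(2019, 9, 2), 0, 0)]
        pts = [(60 * h, 0, 0) for h in range(1, 24)]
        traj = _traj(pts, t0="2019-09-01 00:00:00")
        day_traj, log = filter_daytime(traj, nights)
        assert len(day_traj) == 0
        assert (log["status"] == "never left sleep site").any()

    def test_departure_and_entry_bounds(self):
        # out-and-back day: depart site at x=0, travel to 1000, return to
        # the same site; the retained span runs from the first fix beyond
        # 100 m in the morning to the last fix beyond 100 m in the evening
        nights = [_night(date(2019, 9, 1), 0, 0), _night(date(2019, 9, 2), 0, 0)]
        away = [min(200 * i, 200 * (10 - i)) for i in range(11)]  # 0..1000..0
        pts = (
            [(60 * h, 0, 0) for h in range(1, 6)]
            + [(360 + 30 * i, away[i], 0) for i in range(11)]
            + [(720 + 60 * h, 0, 0) for h in range(12)]
        )
        traj = _traj(pts, t0="2019-09-01 00:00:00")
        day_traj, log = filter_daytime(traj, nights, exit_radius_m=100.0)
        xs = day_traj.fixes["x"]
        assert xs.iloc[0] == 200.0 and xs.iloc[-1] == 200.0
        assert xs.max() == 1000.0
        assert (xs > 0).all()  # no at-site fixes retained
        assert (log["status"] == "ok").any()

    def test_missing_next_anchor_logged(self):
        nights = [_night(date(2019, 9, 1), 0, 0)]
        traj = _traj([(60 * h, 500, 0) for h in range(24)], t0="2019-09-01 00:00:00")
        day_traj, log = filter_daytime(traj, nights)
        assert len(day_traj) == 0
        assert log["status"].iloc[0] == "missing next-night anchor"


class TestDayAoiRecord:
    def _aois(self):
        stops = _stops_from_clusters(
            [(600, 800), (1500, 0)], t0="2019-09-01 08:00:00"
        )
        # make both recurrent by a second visit on another day
        stops2 = _stops_from_clusters(
            [(600, 800), (1500, 0)], t0="2019-09-02 08:00:00"
        )
        for i, s in enumerate(stops + stops2):
            s.stop_id = i
        return merge_stops(stops + stops2, 40.0)

    def test_single_aoi_day_first_equals_last(self):
        stops = _stops_from_clusters([(600, 800)], t0="2019-09-01 08:00:00")
        stops += _stops_from_clusters([(600, 800)], t0="2019-09-02 08:00:00")
        aois = merge_stops(stops, 40.0)
        nights = {
            date(2019, 9, 1): _night(date(2019, 9, 1), 0, 0),
            date(2019, 9, 2): _night(date(2019, 9, 2), 0, 0),
        }
        rec = day_aoi_record(date(2019, 9, 1), "B1", nights, aois)
        assert rec.first_aoi_id == rec.last_aoi_id
        assert rec.dist_sleep_to_first_m == pytest.approx(1000.0)  # 600-800-1000
        assert rec.dist_last_to_sleep_m == pytest.approx(1000.0)

    def test_first_and_last_distinct(self):
        aois = self._aois()
        nights = {
            date(2019, 9, 1): _night(date(2019, 9, 1), 0, 0),
            date(2019, 9, 2): _night(date(2019, 9, 2), 0, 0),
        }
        rec = day_aoi_record(date(2019, 9, 1), "B1", nights, aois)
        assert rec.first_aoi_id != rec.last_aoi_id
        assert rec.dist_sleep_to_first_m == pytest.approx(1000.0)
        assert rec.dist_last_to_sleep_m == pytest.approx(1500.0)

    def test_no_visits_yields_absent_fields(self):
        nights = {date(2019, 9, 5): _night(date(2019, 9, 5), 0, 0)}
        rec = day_aoi_record(date(2019, 9, 5), "B1", nights, self._aois())
        assert rec.first_aoi_id is None
        assert rec.dist_sleep_to_first_m is None

    def test_non_recurrent_aois_ignored(self):
        stops = _stops_from_clusters([(600, 800)], t0="2019-09-01 08:00:00")
        aois = merge_stops(stops, 40.0)  # single visit: not recurrent
        nights = {date(2019, 9, 1): _night(date(2019, 9, 1), 0, 0)}
        rec = day_aoi_record(date(2019, 9, 1), "B1", nights, aois)
        assert rec.first_aoi_id is None
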