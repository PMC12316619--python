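"""Areas of interest (AOIs) from stop/dwell detection.

A *stop* (group of points, GoP) is a run of consecutive fixes all within
30 m of the run's FIRST fix, lasting at least 15 min (2 fixes at the
nominal cadence).  Stops whose fixes come within 40 m of each other are
merged transitively; the merged set, hulled, is an AOI.  AOIs are built
within a trailing 30-day window per analysis date, using only daytime
fixes (after the morning departure from, and before the evening entry
into, a sleep site).  Per day, the first AOI the animal visited and
remained in after leaving the sleep site, and the last AOI before the
evening entry, are linked back to the night anchors by straight-line
distance to the first utilized fix of the triggering stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Polygon

from .sleep_sites import SleepNight
from .trajectory import Trajectory


@dataclass
class Stop:
    """One dwell: >= min_fixes consecutive fixes within radius of the origin."""

    individual_id: str
    xy: np.ndarray  # (k, 2) member fix coordinates, temporal order
    times: pd.DatetimeIndex
    stop_id: int = -1

    @property
    def origin(self) -> np.ndarray:
        return self.xy[0]

    @property
    def start(self) -> pd.Timestamp:
        return self.times[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.times[-1]

    @property
    def centroid(self) -> np.ndarray:
        return self.xy.mean(axis=0)

    @property
    def duration(self) -> pd.Timedelta:
        return self.end - self.start


@dataclass
class AOI:
    """Merged stops plus their minimum convex polygon."""

    aoi_id: int
    stops: list[Stop] = field(default_factory=list)
    recurrent: bool = False  # n_visits >= 2 within the window

    @property
    def n_visits(self) -> int:
        return len(self.stops)

    @property
    def all_xy(self) -> np.ndarray:
        return np.vstack([s.xy for s in self.stops])

    @property
    def polygon(self) -> Polygon:
        """Hull over member fixes; degenerate hulls get a 5 m buffer."""
        hull = MultiPoint([tuple(p) for p in self.all_xy]).convex_hull
        if not isinstance(hull, Polygon) or hull.area == 0.0:
            hull = hull.buffer(5.0)
        return hull


@dataclass(frozen=True)
class DayAoiRecord:
    """Per individual-day link between sleep anchors and AOI visits.

    ``dist_sleep_to_first_m`` runs from that morning's anchor (the night
    dated this day) to the entry fix of the first recurrent AOI;
    ``dist_last_to_sleep_m`` runs from the entry fix of the day's last
    recurrent AOI to the anchor of the coming night (dated day+1).
    """

    individual_id: str
    date: _date
    first_aoi_id: int | None
    last_aoi_id: int | None
    dist_sleep_to_first_m: float | None
    dist_last_to_sleep_m: float | None


def detect_stops(
    traj: Trajectory,
    radius_m: float = 30.0,
    min_fixes: int = 2,
    max_gap: pd.Timedelta = pd.Timedelta(minutes=31),
) -> list[Stop]:
    """Greedy left-to-right origin-anchored stop detection.

    A stop opens at a fix whose successor lies within ``radius_m`` of it;
    it extends while fixes stay within ``radius_m`` of the ORIGIN fix
    (not the running centroid) and closes at the first fix beyond.  The
    closing fix may immediately open the next stop.  Runs shorter than
    ``min_fixes`` are discarded.  A time gap over ``max_gap`` between
    successive fixes (missing data, or the overnight gap left by daytime
    filtering) breaks the run: member fixes must be genuinely
    consecutive at the fix cadence.
    """
    xy = traj.xy()
    times = pd.DatetimeIndex(traj.fixes["timestamp"])
    n = len(xy)
    stops: list[Stop] = []
    i = 0
    while i < n - 1:
        if (
            np.hypot(*(xy[i + 1] - xy[i])) <= radius_m
            and times[i + 1] - times[i] <= max_gap
        ):
            origin = xy[i]
            j = i + 1
            while (
                j < n
                and np.hypot(*(xy[j] - origin)) <= radius_m
                and times[j] - times[j - 1] <= max_gap
            ):
                j += 1
            if j - i >= min_fixes:
                stops.append(
                    Stop(
                        individual_id=traj.individual_id,
                        xy=xy[i:j].copy(),
                        times=times[i:j],
                    )
                )
            i = j  # the closing fix can start a new stop
        else:
            i += 1
    for k, s in enumerate(stops):
        s.stop_id = k
    return stops


def _stop_adjacency(stops: Sequence[Stop], merge_m: float) -> list[tuple[int, int]]:
    """Pairs of stop indices having any inter-fix distance <= merge_m."""
    if len(stops) < 2:
        return []
    all_xy = np.vstack([s.xy for s in stops])
    owner = np.concatenate(
        [np.full(len(s.xy), i, dtype=int) for i, s in enumerate(stops)]
    )
    tree = cKDTree(all_xy)
    pairs = tree.query_pairs(merge_m, output_type="ndarray")
    if len(pairs) == 0:
        return []
    a, b = owner[pairs[:, 0]], owner[pairs[:, 1]]
    mask = a != b
    edges = {tuple(sorted(e)) for e in zip(a[mask].tolist(), b[mask].tolist())}
    return sorted(edges)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_stops(
    stops: Sequence[Stop],
    merge_m: float = 40.0,
    edges: Sequence[tuple[int, int]] | None = None,
) -> list[AOI]:
    """Transitive closure of "some fix-pair within merge_m" over stops.

    Each connected component becomes one AOI; an AOI is flagged
    ``recurrent`` when it holds >= 2 temporally distinct stops.
    Precomputed ``edges`` (global adjacency restricted to this window)
    may be supplied to avoid rebuilding the KD-tree per window.
    """
    stops = list(stops)
    if not stops:
        return []
    if edges is None:
        edges = _stop_adjacency(stops, merge_m)
    uf = _UnionFind(len(stops))
    for i, j in edges:
        uf.union(i, j)
    comps: dict[int, list[Stop]] = {}
    for i, s in enumerate(stops):
        comps.setdefault(uf.find(i), []).append(s)
    aois = []
    for k, root in enumerate(sorted(comps)):
        members = sorted(comps[root], key=lambda s: s.start)
        aois.append(AOI(aoi_id=k, stops=members, recurrent=len(members) >= 2))
    return aois


def assign_windows(
    stops: Sequence[Stop],
    dates: Sequence[_date],
    window_days: int = 30,
) -> dict[_date, list[int]]:
    """Trailing-window grouping: date d is served by stops whose dwell
    started in [d - window_days + 1, d]."""
    starts = [s.start.date() for s in stops]
    out: dict[_date, list[int]] = {}
    for d in dates:
        lo = d - timedelta(days=window_days - 1)
        out[d] = [i for i, sd in enumerate(starts) if lo <= sd <= d]
    return out


def filter_daytime(
    traj: Trajectory,
    nights: Sequence[SleepNight],
    exit_radius_m: float = 100.0,
) -> tuple[Trajectory, pd.DataFrame]:
    """Keep fixes between morning sleep-site departure and evening entry.

    For each date with anchors on both the bounding nights (the 02:00
    anchor dated d and the one dated d+1), the day's fixes run from the
    first fix after the morning anchor farther than ``exit_radius_m``
    from it, to the last fix before the evening anchor farther than
    ``exit_radius_m`` from THAT night's anchor.  Days missing either
    anchor are dropped and listed in the returned log frame.
    """
    by_date = {n.night_date: n for n in nights}
    ts = pd.DatetimeIndex(traj.fixes["timestamp"])
    xy = traj.xy()
    keep = np.zeros(len(ts), dtype=bool)
    log_rows = []
    for d, night in sorted(by_date.items()):
        nxt = by_date.get(d + timedelta(days=1))
        if nxt is None:
            log_rows.append({"date": d, "status": "missing next-night anchor"})
            continue
        in_day = (ts > night.timestamp) & (ts < nxt.timestamp)
        idx = np.flatnonzero(in_day)
        if len(idx) == 0:
            log_rows.append({"date": d, "status": "no fixes between anchors"})
            continue
        d_morning = np.hypot(xy[idx, 0] - night.x, xy[idx, 1] - night.y)
        d_evening = np.hypot(xy[idx, 0] - nxt.x, xy[idx, 1] - nxt.y)
        away_m = np.flatnonzero(d_morning > exit_radius_m)
        away_e = np.flatnonzero(d_evening > exit_radius_m)
        if len(away_m) == 0 or len(away_e) == 0:
            log_rows.append({"date": d, "status": "never left sleep site"})
            continue
        start, stop = away_m[0], away_e[-1]
        if stop < start:
            log_rows.append({"date": d, "status": "degenerate day"})
            continue
        keep[idx[start] : idx[stop] + 1] = True
        log_rows.append({"date": d, "status": "ok"})
    day_traj = Trajectory(
        individual_id=traj.individual_id,
        fixes=traj.fixes[keep].reset_index(drop=True),
        crs_label=traj.crs_label,
        projector=traj.projector,
    )
    return day_traj, pd.DataFrame(log_rows, columns=["date", "status"])


def day_aoi_record(
    date: _date,
    individual_id: str,
    nights: dict[_date, SleepNight],
    aois: Sequence[AOI],
) -> DayAoiRecord:
    """First/last recurrent AOI of one day and the anchor distances.

    Distances are measured to the first utilized fix of the AOI's
    triggering stop on this day (not the polygon or centroid): morning
    anchor -> first AOI entry; last AOI entry -> evening anchor.
    """
    morning = nights.get(date)
    evening = nights.get(date + timedelta(days=1))

    visits = []  # (stop.start, entry_xy, aoi_id)
    for a in aois:
        if not a.recurrent:
            continue
        for s in a.stops:
            if s.start.date() == date:
                visits.append((s.start, s.origin, a.aoi_id))
    visits.sort(key=lambda v: v[0])

    first_id = last_id = None
    d_first = d_last = None
    if visits:
        _, entry_xy, first_id = visits[0]
        if morning is not None:
            d_first = float(np.hypot(entry_xy[0] - morning.x, entry_xy[1] - morning.y))
        _, exit_xy, last_id = visits[-1]
        if evening is not None:
            d_last = float(np.hypot(exit_xy[0] - evening.x, exit_xy[1] - evening.y))
    return DayAoiRecord(
        individual_id=individual_id,
        date=date,
        first_aoi_id=first_id,
        last_aoi_id=last_id,
        dist_sleep_to_first_m=d_first,
        dist_last_to_sleep_m=d_last,
    )


def build_day_records(
    traj: Trajectory,
    nights: Sequence[SleepNight],
    radius_m: float = 30.0,
    min_fixes: int = 2,
    merge_m: float = 40.0,
    window_days: int = 30,
    exit_radius_m: float = 100.0,
    min_coverage_h: float = 8.0,
) -> tuple[list[DayAoiRecord], list[Stop]]:
    """Full AOI chain for one individual: daytime filter, stops, rolling
    windows, per-day records.

    Analysis dates require the night anchor, the following-day coverage
    of at least ``min_coverage_h`` hours, and the next night's anchor for
    the evening leg.  Stop merging runs independently within each
    trailing window (global stop adjacency is precomputed once; a
    window's merge uses only edges among its member stops, which equals
    per-window closure).
    """
    from .trajectory import daily_coverage_hours

    day_traj, _ = filter_daytime(traj, nights, exit_radius_m=exit_radius_m)
    stops = detect_stops(day_traj, radius_m=radius_m, min_fixes=min_fixes)
    night_by_date = {n.night_date: n for n in nights}

    coverage = daily_coverage_hours(traj)
    dates = sorted(
        d for d in night_by_date if coverage.get(d, 0.0) >= min_coverage_h
    )
    windows = assign_windows(stops, dates, window_days=window_days)
    edges = _stop_adjacency(stops, merge_m)

    records = []
    for d in dates:
        members = windows[d]
        pos = {orig: k for k, orig in enumerate(members)}
        sub_edges = [
            (pos[i], pos[j]) for i, j in edges if i in pos and j in pos
        ]
        aois = merge_stops([stops[i] for i in members], merge_m, edges=sub_edges)
        records.append(day_aoi_record(d, traj.individual_id, night_by_date, aois))
    return records, stops


def day_records_frame(records: Sequence[DayAoiRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "date": r.date,
                "first_aoi_id": r.first_aoi_id,
                "last_aoi_id": r.last_aoi_id,
                "dist_sleep_to_first_m": r.dist_sleep_to_first_m,
                "dist_last_to_sleep_m": r.dist_last_to_sleep_m,
            }
            for r in records
        ]
    )
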