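"""Nightly sleep locations and single-linkage sleep-site clusters.

The anchor fix at 02:00 local time (02:30 if the 02:00 fix failed) marks
where an individual slept that night.  Anchors from both collared
individuals of a troop are pooled and clustered by single linkage
("friends-of-friends") with a 100 m distance factor: two nights share a
sleep site iff they are connected by a chain of pairwise distances at or
below the factor.  A site is summarised by the geographic mean of its
member anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date, timedelta
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .trajectory import Trajectory

Season = str  # "wet" | "dry"


@dataclass(frozen=True)
class SleepNight:
    """One individual-night: the 02:00 (or 02:30) anchor fix."""

    individual_id: str
    night_date: _date
    x: float
    y: float
    timestamp: pd.Timestamp
    anchor_source: str  # "T0200" | "T0230"


@dataclass
class SleepSite:
    site_id: int
    member_nights: list[SleepNight] = field(default_factory=list)

    @property
    def centroid(self) -> tuple[float, float]:
        xs = [n.x for n in self.member_nights]
        ys = [n.y for n in self.member_nights]
        return float(np.mean(xs)), float(np.mean(ys))

    @property
    def use_count(self) -> int:
        return len(self.member_nights)

    def use_count_by_individual(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for n in self.member_nights:
            out[n.individual_id] = out.get(n.individual_id, 0) + 1
        return out

    def seasons_used(self, season_fn: Callable[[_date], Season]) -> set[Season]:
        return {season_fn(n.night_date) for n in self.member_nights}


@dataclass(frozen=True)
class CohesionSummary:
    """Nightly distance between a troop's two collared individuals."""

    n_nights: int
    mean_m: float
    sd_m: float
    min_m: float
    max_m: float


def extract_sleep_nights(
    traj: Trajectory,
    local_utc_offset_hours: float = 2.0,
    anchor_time: tuple[int, int] = (2, 0),
    fallback_time: tuple[int, int] = (2, 30),
) -> list[SleepNight]:
    """Pick each night's anchor fix: 02:00 local, falling back to 02:30.

    The collars log UTC; ``local_utc_offset_hours`` (default UTC+2,
    south-east Africa) shifts to local clock time before matching.  A
    night is keyed by the local calendar date the anchor falls on.
    Nights with neither fix are absent from the output.
    """
    ts_local = traj.fixes["timestamp"] + timedelta(hours=local_utc_offset_hours)
    nights: dict[_date, SleepNight] = {}
    for want, src in ((anchor_time, "T0200"), (fallback_time, "T0230")):
        mask = (ts_local.dt.hour == want[0]) & (ts_local.dt.minute == want[1])
        for idx in np.flatnonzero(mask.to_numpy()):
            row = traj.fixes.iloc[idx]
            d = (ts_local.iloc[idx]).date()
            if d not in nights:  # 02:00 pass runs first and wins
                nights[d] = SleepNight(
                    individual_id=traj.individual_id,
                    night_date=d,
                    x=float(row["x"]),
                    y=float(row["y"]),
                    timestamp=row["timestamp"],
                    anchor_source=src,
                )
    return [nights[d] for d in sorted(nights)]


def single_linkage_clusters(
    points: np.ndarray, threshold_m: float
) -> np.ndarray:
    """Friends-of-friends partition: labels 0..k-1, chain-linked at ≤ threshold.

    Distances exactly equal to the threshold link.  Order-independent up
    to label renumbering (labels follow first appearance).
    """
    if threshold_m <= 0:
        raise ValueError("threshold_m must be positive")
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.empty(0, dtype=int)
    if len(pts) == 1:
        return np.zeros(1, dtype=int)
    z = linkage(pdist(pts), method="single")
    raw = fcluster(z, t=threshold_m, criterion="distance")
    # renumber by first appearance for deterministic, order-stable labels
    remap: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    return labels


def build_sleep_sites(
    nights: Sequence[SleepNight],
    threshold_m: float = 100.0,
) -> tuple[list[SleepSite], dict[tuple[str, _date], int]]:
    """Cluster pooled troop anchors into sleep sites.

    Returns the sites and a lookup from (individual, night_date) to
    site_id.  Every night belongs to exactly one site.
    """
    if not nights:
        return [], {}
    pts = np.array([(n.x, n.y) for n in nights])
    labels = single_linkage_clusters(pts, threshold_m)
    sites: dict[int, SleepSite] = {}
    assignment: dict[tuple[str, _date], int] = {}
    for night, lab in zip(nights, labels):
        site = sites.setdefault(int(lab), SleepSite(site_id=int(lab)))
        site.member_nights.append(night)
        assignment[(night.individual_id, night.night_date)] = int(lab)
    return [sites[k] for k in sorted(sites)], assignment


def consecutive_night_distance(
    nights: Sequence[SleepNight],
    season_fn: Callable[[_date], Season],
) -> pd.DataFrame:
    """Straight-line metres between anchors on strictly consecutive nights.

    Grouped by the season of the later night; calendar gaps are skipped.
    Returns a frame with columns season, mean_m, sd_m, n.
    """
    ordered = sorted(nights, key=lambda n: n.night_date)
    rows = []
    for a, b in zip(ordered, ordered[1:]):
        if (b.night_date - a.night_date).days == 1:
            rows.append(
                {
                    "season": season_fn(b.night_date),
                    "dist_m": float(np.hypot(b.x - a.x, b.y - a.y)),
                }
            )
    if not rows:
        return pd.DataFrame(columns=["season", "mean_m", "sd_m", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("season")["dist_m"]
        .agg(mean_m="mean", sd_m="std", n="size")
        .reset_index()
    )
    return out


def return_statistics(
    nights: Sequence[SleepNight],
    assignment: dict[tuple[str, _date], int],
    season_boundary: _date,
) -> tuple[int, int, pd.DataFrame]:
    """Cross-boundary site reuse and longest absences, for one individual.

    A site is "reused across the boundary" iff this individual used it at
    least once strictly before and at least once on/after the boundary
    date.  ``longest_absence_days`` is the maximum day-gap between an
    individual's consecutive uses of the same site, over all their sites.
    Returns (n_reused_sites, longest_absence_days, per-site frame).
    """
    by_site: dict[int, list[_date]] = {}
    for n in nights:
        sid = assignment[(n.individual_id, n.night_date)]
        by_site.setdefault(sid, []).append(n.night_date)

    rows = []
    n_reused = 0
    longest = 0
    for sid, dates in by_site.items():
        dates = sorted(dates)
        before = any(d < season_boundary for d in dates)
        after = any(d >= season_boundary for d in dates)
        reused = before and after
        n_reused += int(reused)
        gap = max(
            ((b - a).days for a, b in zip(dates, dates[1:])), default=0
        )
        longest = max(longest, gap)
        rows.append(
            {
                "site_id": sid,
                "n_uses": len(dates),
                "first_use": dates[0],
                "last_use": dates[-1],
                "max_gap_days": gap,
                "reused_across_boundary": reused,
            }
        )
    return n_reused, longest, pd.DataFrame(rows)


def cohesion_summary(
    nights_a: Sequence[SleepNight], nights_b: Sequence[SleepNight]
) -> CohesionSummary | None:
    """Nightly inter-individual anchor distance on shared nights.

    A lower bound on troop sleeping spread (only two of the troop are
    collared).  Returns None when the individuals share no nights.
    """
    by_date_b = {n.night_date: n for n in nights_b}
    dists = [
        float(np.hypot(a.x - by_date_b[a.night_date].x, a.y - by_date_b[a.night_date].y))
        for a in nights_a
        if a.night_date in by_date_b
    ]
    if not dists:
        return None
    arr = np.array(dists)
    return CohesionSummary(
        n_nights=len(arr),
        mean_m=float(arr.mean()),
        sd_m=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        min_m=float(arr.min()),
        max_m=float(arr.max()),
    )


def sleep_nights_frame(nights: Sequence[SleepNight]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual_id": n.individual_id,
                "night_date": n.night_date,
                "x": n.x,
                "y": n.y,
                "anchor_source": n.anchor_source,
            }
            for n in nights
        ]
    )


def sleep_sites_frame(
    sites: Sequence[SleepSite], season_fn: Callable[[_date], Season]
) -> pd.DataFrame:
    rows = []
    for s in sites:
        cx, cy = s.centroid
        seasons = sorted(s.seasons_used(season_fn))
        rows.append(
            {
                "site_id": s.site_id,
                "centroid_x": cx,
                "centroid_y": cy,
                "use_count": s.use_count,
                "seasons_used": "+".join(seasons),
                **{
                    f"use_count_{ind}": c
                    for ind, c in sorted(s.use_count_by_individual().items())
                },
            }
        )
    return pd.DataFrame(rows)
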