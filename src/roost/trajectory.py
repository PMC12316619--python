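"""Raw GPS fix handling: read, validate, burst-collapse, project, clean.

A fix table is a pandas DataFrame in the Movebank dialect (individual id,
ISO-8601 UTC timestamp, longitude, latitude, optional burst id).  After
projection each individual's fixes become a :class:`Trajectory` in planar
UTM metres, at most one fix per nominal 15-min slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .projection import TransverseMercator

#: Movebank-style defaults; override with ``column_map``.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "individual_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "burst_id": "burst-id",
}

NOMINAL_INTERVAL = pd.Timedelta(minutes=15)


@dataclass
class Trajectory:
    """Time-ordered planar fixes for one individual.

    ``fixes`` has columns ``timestamp`` (UTC), ``x``, ``y`` (metres).
    """

    individual_id: str
    fixes: pd.DataFrame
    crs_label: str = "unprojected"
    projector: TransverseMercator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ts = self.fixes["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            self.fixes = self.fixes.sort_values("timestamp").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fixes)

    def xy(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy(dtype=float)


@dataclass(frozen=True)
class CleaningReport:
    n_raw: int
    n_burst_collapsed: int
    n_outliers_removed: int

    @property
    def n_retained(self) -> int:
        return self.n_burst_collapsed - self.n_outliers_removed


def read_fix_table(
    path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a Movebank-style fix CSV.

    Returns ``(fixes, rejects)``: ``fixes`` holds the parseable rows with
    canonical columns (individual_id, timestamp, lon, lat, burst_id) in
    file order; ``rejects`` holds malformed rows with a ``reject_reason``.
    Raises ``ValueError`` if a mapped required column is absent, or if the
    file has data rows but every one of them rejects.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["individual_id", "timestamp", "lon", "lat"]
    for key in required:
        if cols[key] not in raw.columns:
            raise ValueError(f"missing mapped column {cols[key]!r} for {key!r}")

    out = pd.DataFrame(
        {
            "individual_id": raw[cols["individual_id"]],
            "timestamp": pd.to_datetime(
                raw[cols["timestamp"]], errors="coerce", utc=True, format="mixed"
            ),
            "lon": pd.to_numeric(raw[cols["lon"]], errors="coerce"),
            "lat": pd.to_numeric(raw[cols["lat"]], errors="coerce"),
        }
    )
    if cols.get("burst_id") in raw.columns:
        out["burst_id"] = raw[cols["burst_id"]].replace("", pd.NA)
    else:
        out["burst_id"] = pd.NA

    reason = pd.Series("", index=out.index, dtype=str)
    reason[out["timestamp"].isna()] = "unparseable timestamp"
    reason[out["lon"].isna() | out["lat"].isna()] = "non-numeric coordinate"
    bad_bounds = (
        out["lon"].lt(-180) | out["lon"].gt(180)
        | out["lat"].lt(-90) | out["lat"].gt(90)
    ).fillna(False)
    reason[bad_bounds] = "coordinate out of bounds"
    reason[out["individual_id"].str.strip() == ""] = "missing individual id"

    bad = reason != ""
    rejects = out[bad].copy()
    rejects["reject_reason"] = reason[bad]
    fixes = out[~bad].reset_index(drop=True)
    if len(raw) > 0 and len(fixes) == 0:
        raise ValueError(f"all {len(raw)} rows rejected while reading {path}")
    return fixes, rejects.reset_index(drop=True)


def canonicalize_fixes(
    fixes: pd.DataFrame, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Rename a Movebank-dialect frame to canonical columns and parse types.

    A no-op for frames already carrying canonical columns.  Unlike
    :func:`read_fix_table` this assumes well-formed values (simulator
    output or pre-validated data).
    """
    if "individual_id" in fixes.columns:
        return fixes
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    out = pd.DataFrame(
        {
            "individual_id": fixes[cols["individual_id"]].astype(str),
            "timestamp": pd.to_datetime(fixes[cols["timestamp"]], utc=True),
            "lon": pd.to_numeric(fixes[cols["lon"]]),
            "lat": pd.to_numeric(fixes[cols["lat"]]),
        }
    )
    out["burst_id"] = (
        fixes[cols["burst_id"]] if cols.get("burst_id") in fixes.columns else pd.NA
    )
    return out


def collapse_bursts(fixes: pd.DataFrame) -> pd.DataFrame:
    """Keep only the chronologically last fix of each (individual, burst).

    Later fixes in a burst allow the receiver more time to acquire
    satellites and are the most accurate; fixes with no burst id pass
    through untouched.  Idempotent.
    """
    if fixes.empty:
        return fixes.copy()
    df = fixes.sort_values(["individual_id", "timestamp"], kind="stable")
    has_burst = df["burst_id"].notna()
    keep_last = ~df[has_burst].duplicated(["individual_id", "burst_id"], keep="last")
    kept = pd.concat([df[~has_burst], df[has_burst][keep_last]])
    return kept.sort_values(["individual_id", "timestamp"], kind="stable").reset_index(
        drop=True
    )


def align_to_slots(
    fixes: pd.DataFrame, interval: pd.Timedelta = NOMINAL_INTERVAL
) -> pd.DataFrame:
    """Bin fixes to the nearest nominal slot; keep the last fix per slot.

    Guarantees the at-most-one-fix-per-slot invariant.  The original
    timestamp is replaced by the slot time so downstream clock matching
    (02:00 anchors) is exact.
    """
    if fixes.empty:
        return fixes.copy()
    df = fixes.copy()
    df["timestamp"] = df["timestamp"].dt.round(interval)
    df = df.sort_values(["individual_id", "timestamp"], kind="stable")
    df = df[~df.duplicated(["individual_id", "timestamp"], keep="last")]
    return df.reset_index(drop=True)


def project_to_metric(
    fixes: pd.DataFrame,
    projector: TransverseMercator | None = None,
) -> dict[str, Trajectory]:
    """Project WGS84 fixes to planar metres, one Trajectory per individual.

    The UTM zone is chosen from the pooled data centroid unless an
    explicit projector is given, so all individuals share one CRS.
    """
    if fixes.empty:
        return {}
    if projector is None:
        projector = TransverseMercator.utm_for(
            fixes["lon"].to_numpy(), fixes["lat"].to_numpy()
        )
    x, y = projector.forward(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    df = fixes.copy()
    df["x"] = x
    df["y"] = y
    out: dict[str, Trajectory] = {}
    for ind, grp in df.groupby("individual_id", sort=True):
        traj = grp[["timestamp", "x", "y"]].sort_values("timestamp")
        out[str(ind)] = Trajectory(
            individual_id=str(ind),
            fixes=traj.reset_index(drop=True),
            crs_label=projector.label,
            projector=projector,
        )
    return out


def remove_impossible_fixes(
    traj: Trajectory,
    max_jump_m: float = 10_000.0,
    window: pd.Timedelta = NOMINAL_INTERVAL,
) -> tuple[Trajectory, CleaningReport]:
    """Drop gross GPS outliers: fixes an impossible distance from BOTH
    temporal neighbours.

    The threshold scales with the actual elapsed time between neighbours
    (floor ``max_jump_m`` per nominal window), so a fix after a long gap
    is not penalised.  The both-neighbour condition protects genuine long
    relocations, where the next fix agrees with the new position.  Single
    pass over the original sequence.
    """
    n = len(traj)
    if n < 3:
        report = CleaningReport(n_raw=n, n_burst_collapsed=n, n_outliers_removed=0)
        return traj, report

    xy = traj.xy()
    ts = traj.fixes["timestamp"].astype("int64").to_numpy() / 1e9  # epoch seconds
    win_s = window.total_seconds()

    step = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))  # step[i] = |p[i+1]-p[i]|
    dt = np.maximum(np.diff(ts) / win_s, 1.0)
    excess = step > max_jump_m * dt  # step i is impossible at nominal speed

    keep = np.ones(n, dtype=bool)
    # interior fix i is dropped iff both adjacent steps are impossible
    keep[1:-1] = ~(excess[:-1] & excess[1:])

    cleaned = Trajectory(
        individual_id=traj.individual_id,
        fixes=traj.fixes[keep].reset_index(drop=True),
        crs_label=traj.crs_label,
        projector=traj.projector,
    )
    report = CleaningReport(
        n_raw=n, n_burst_collapsed=n, n_outliers_removed=int((~keep).sum())
    )
    return cleaned, report


def day_coverage_hours(traj: Trajectory, date: _date) -> float:
    """Hours spanned by fixes on a civil date (UTC).

    Days with under 8 h of coverage are excluded from day-level analyses;
    this returns the span so the caller applies the threshold.
    """
    ts = traj.fixes["timestamp"]
    on_day = ts[ts.dt.date == date]
    if len(on_day) < 2:
        return 0.0
    return float((on_day.max() - on_day.min()).total_seconds() / 3600.0)


def daily_coverage_hours(traj: Trajectory) -> dict[_date, float]:
    """Coverage span per civil date (UTC) for all dates at once."""
    if len(traj) == 0:
        return {}
    ts = traj.fixes["timestamp"]
    span = ts.groupby(ts.dt.date).agg(["min", "max", "size"])
    out: dict[_date, float] = {}
    for d, row in span.iterrows():
        out[d] = (
            float((row["max"] - row["min"]).total_seconds() / 3600.0)
            if row["size"] > 1
            else 0.0
        )
    return out


def clean_pipeline(
    fixes: pd.DataFrame,
    max_jump_m: float = 10_000.0,
    projector: TransverseMercator | None = None,
) -> tuple[dict[str, Trajectory], dict[str, CleaningReport]]:
    """Full cleaning chain: burst-collapse, slot-align, project, de-outlier."""
    fixes = canonicalize_fixes(fixes)
    n_raw = (
        fixes.groupby("individual_id").size().to_dict() if not fixes.empty else {}
    )
    collapsed = align_to_slots(collapse_bursts(fixes))
    trajectories = project_to_metric(collapsed, projector=projector)
    cleaned: dict[str, Trajectory] = {}
    reports: dict[str, CleaningReport] = {}
    for ind, traj in trajectories.items():
        traj2, rep = remove_impossible_fixes(traj, max_jump_m=max_jump_m)
        cleaned[ind] = traj2
        reports[ind] = CleaningReport(
            n_raw=int(n_raw.get(ind, len(traj))),
            n_burst_collapsed=rep.n_burst_collapsed,
            n_outliers_removed=rep.n_outliers_removed,
        )
    return cleaned, reports
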