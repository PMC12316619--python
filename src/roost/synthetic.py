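"""Ground-truthed GPS collar simulator.

Emulates the structure a troop's collar data must have for the pipeline
to be testable end-to-end without field data: two collared individuals
per troop sleeping at a shared site each night (with a known
inter-individual spread), a daytime itinerary of dwells at recurrent
stop locations connected by travel legs, a wet-season range displacement
for floodplain-like troops, burst-structured 15-min fixes with GPS
jitter, missing fixes, and rare gross outliers.

Every random draw flows from the scenario seed, so a scenario is a
reproducible study condition; the emitted table is Movebank-dialect CSV
and the :class:`GroundTruth` sidecar records the planted truth (site per
night, itinerary per day, pool locations) for recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date as _date, datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .stats import season_of

# metres per degree at the reference latitude (standard series expansion)
def _metres_per_degree(lat_deg: float) -> tuple[float, float]:
    phi = np.radians(lat_deg)
    m_lat = 111132.92 - 559.82 * np.cos(2 * phi) + 1.175 * np.cos(4 * phi)
    m_lon = 111412.84 * np.cos(phi) - 93.5 * np.cos(3 * phi)
    return m_lon, m_lat


@dataclass
class TroopScenario:
    """Study conditions for one simulated troop.

    Defaults mirror the collared study system: two individuals, ~300
    nights, 15-min UTC fix cadence, ~5 m GPS jitter, ~1% missing fixes,
    rare >10 km outliers, wet season Nov 1 - Mar 31.
    """

    troop_id: str = "T"
    n_individuals: int = 2
    start_date: _date = _date(2019, 8, 15)
    n_days: int = 300
    center_lon: float = 34.35
    center_lat: float = -18.95
    range_scale_m: float = 2000.0
    n_sites: int = 10
    n_aois: int = 15
    min_site_sep_m: float = 350.0
    min_aoi_sep_m: float = 200.0
    site_weights: tuple[float, ...] | None = None
    top_site_share: float | None = None
    reuse_edge_slope: float = 0.0  # per metre of distance-to-range-edge
    seasonal_shift_m: tuple[float, float] = (0.0, 0.0)  # active in wet season
    post_return_site_fraction: float | None = None
    morning_vs_evening_shift_m: float = 0.0
    night_spread_m: float = 30.0
    fix_interval_min: int = 15
    jitter_sd_m: tuple[float, ...] = (5.0, 5.0)  # per individual
    miss_prob: tuple[float, ...] = (0.01, 0.01)
    outlier_prob: float = 0.001
    speed_ms: tuple[float, float] = (0.4, 0.9)
    aois_per_day: tuple[int, int] = (3, 5)
    dwell_min_min: float = 45.0
    depart_hour: float = 6.0
    return_hour: float = 17.5
    local_utc_offset_hours: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.outlier_prob <= 1:
            raise ValueError("outlier_prob must be a probability")
        for p in self.miss_prob:
            if not 0 <= p <= 1:
                raise ValueError("miss_prob entries must be probabilities")
        if self.n_sites < 1 or self.n_aois < 1:
            raise ValueError("site and AOI pools must be non-empty")


@dataclass
class GroundTruth:
    """Planted truth: pool locations (lon/lat), per-night site key,
    per-day itinerary with entry/exit times and first/last AOI keys."""

    sites: dict[str, tuple[float, float]]
    aois: dict[str, tuple[float, float]]
    nights: dict[str, dict[str, str]]  # individual -> date iso -> site key
    days: dict[str, dict[str, dict]]  # individual -> date iso -> itinerary
    sites_xy: dict[str, tuple[float, float]] = field(default_factory=dict)
    aois_xy: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _poisson_disc(
    rng: np.random.Generator,
    n: int,
    radius: float,
    min_sep: float,
    avoid: np.ndarray | None = None,
    avoid_sep: float = 0.0,
    shift: np.ndarray | None = None,
) -> np.ndarray:
    """n points in a disc with pairwise separation >= min_sep (rejection).

    Points also keep ``avoid_sep`` clear of the ``avoid`` set (AOIs must
    not overlap sleep sites, or their dwells would be clipped by the
    sleep-site exit filter).  When a seasonal ``shift`` is active, the
    separation holds across modes too: every point keeps ``min_sep``
    from every other point's displaced copy, so shifted and unshifted
    pools stay resolvable as distinct planted locations.
    """

    def _far(p: np.ndarray, others: np.ndarray, sep: float) -> bool:
        if len(others) == 0:
            return True
        return float(np.hypot(others[:, 0] - p[0], others[:, 1] - p[1]).min()) >= sep

    pts: list[np.ndarray] = []
    for _ in range(200_000):
        r = radius * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        p = np.array([r * np.cos(th), r * np.sin(th)])
        arr = np.array(pts) if pts else np.empty((0, 2))
        ok = _far(p, arr, min_sep)
        if ok and shift is not None:
            ok = _far(p, arr + shift, min_sep) and _far(p, arr - shift, min_sep)
        if ok and avoid is not None and len(avoid):
            ok = _far(p, avoid, avoid_sep)
        if ok:
            pts.append(p)
            if len(pts) == n:
                return np.array(pts)
    raise RuntimeError("could not place pool points; lower min separation")


def _site_probabilities(scenario: TroopScenario, edge_dist: np.ndarray) -> np.ndarray:
    n = scenario.n_sites
    if scenario.site_weights is not None:
        w = np.asarray(scenario.site_weights, dtype=float)
    elif scenario.reuse_edge_slope != 0.0:
        w = np.exp(scenario.reuse_edge_slope * edge_dist)
    elif scenario.top_site_share is not None:
        s = scenario.top_site_share
        if abs(s - 1.0 / n) < 1e-9:
            w = np.ones(n)
        elif s < 1.0 / n:
            raise ValueError("top_site_share below uniform share")
        else:
            from scipy.optimize import brentq

            q = brentq(
                lambda q_: (1 - q_) / (1 - q_**n) - s, 1e-9, 1 - 1e-12
            )
            decay = q ** np.arange(n)
            # most central site is the most used
            w = np.empty(n)
            w[np.argsort(-edge_dist, kind="stable")] = decay
    else:
        w = np.ones(n)
    return w / w.sum()


def simulate_troop(
    scenario: TroopScenario,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one troop's fix stream.

    Returns a Movebank-dialect DataFrame (individual-local-identifier,
    timestamp, location-long, location-lat, burst-id) pooled over the
    troop's individuals, plus the GroundTruth sidecar.  Raises
    ``ValueError`` naming the day if an itinerary is unreachable at the
    scenario's travel speed.
    """
    rng = np.random.default_rng(scenario.seed)
    m_lon, m_lat = _metres_per_degree(scenario.center_lat)

    shift_vec = np.asarray(scenario.seasonal_shift_m, dtype=float)
    mode_shift = shift_vec if np.any(shift_vec != 0) else None
    sites = _poisson_disc(
        rng,
        scenario.n_sites,
        scenario.range_scale_m * 0.8,
        scenario.min_site_sep_m,
        shift=mode_shift,
    )
    avoid_sites = (
        np.vstack([sites, sites + shift_vec]) if mode_shift is not None else sites
    )
    aois = _poisson_disc(
        rng,
        scenario.n_aois,
        scenario.range_scale_m,
        scenario.min_aoi_sep_m,
        avoid=avoid_sites,
        avoid_sep=250.0,
        shift=mode_shift,
    )
    edge_dist = scenario.range_scale_m - np.hypot(sites[:, 0], sites[:, 1])
    p_site = _site_probabilities(scenario, edge_dist)

    shift = np.asarray(scenario.seasonal_shift_m)
    shifted = bool(np.any(shift != 0))

    def to_lonlat(xy: np.ndarray) -> tuple[float, float]:
        return (
            scenario.center_lon + float(xy[0]) / m_lon,
            scenario.center_lat + float(xy[1]) / m_lat,
        )

    site_keys = [f"S{i}" for i in range(scenario.n_sites)]
    aoi_keys = [f"A{i}" for i in range(scenario.n_aois)]
    truth_sites = {k: to_lonlat(sites[i]) for i, k in enumerate(site_keys)}
    truth_aois = {k: to_lonlat(aois[i]) for i, k in enumerate(aoi_keys)}
    truth_sites_xy = {k: tuple(map(float, sites[i])) for i, k in enumerate(site_keys)}
    truth_aois_xy = {k: tuple(map(float, aois[i])) for i, k in enumerate(aoi_keys)}
    if shifted:
        for i, k in enumerate(site_keys):
            truth_sites[k + "w"] = to_lonlat(sites[i] + shift)
            truth_sites_xy[k + "w"] = tuple(map(float, sites[i] + shift))
        for i, k in enumerate(aoi_keys):
            truth_aois[k + "w"] = to_lonlat(aois[i] + shift)
            truth_aois_xy[k + "w"] = tuple(map(float, aois[i] + shift))

    dates = [scenario.start_date + timedelta(days=i) for i in range(scenario.n_days + 1)]
    wet = {d: season_of(d) == "wet" for d in dates}
    # the wet-season displacement splits the study into before/after; the
    # post-return pool may be restricted to emulate partial site loss
    first_wet = next((d for d in dates if wet[d]), None)
    post_pool = np.arange(scenario.n_sites)
    if scenario.post_return_site_fraction is not None:
        k = int(np.ceil(scenario.post_return_site_fraction * scenario.n_sites))
        post_pool = np.arange(k)

    # one shared site per troop-night (troop cohesion); lead individual
    # sleeps at the site, others at a per-night Gaussian offset
    night_site_idx: dict[_date, int] = {}
    for d in dates:
        if scenario.post_return_site_fraction is not None and first_wet and d >= first_wet and not wet[d]:
            pool = post_pool
            p = p_site[pool] / p_site[pool].sum()
        else:
            pool = np.arange(scenario.n_sites)
            p = p_site
        night_site_idx[d] = int(rng.choice(pool, p=p))

    def site_key_for(d: _date) -> str:
        k = site_keys[night_site_idx[d]]
        return k + "w" if (shifted and wet[d]) else k

    def site_xy_for(d: _date) -> np.ndarray:
        xy = sites[night_site_idx[d]]
        return xy + shift if (shifted and wet[d]) else xy

    def aoi_xy(i: int, d: _date) -> np.ndarray:
        xy = aois[i]
        return xy + shift if (shifted and wet[d]) else xy

    def aoi_key(i: int, d: _date) -> str:
        k = aoi_keys[i]
        return k + "w" if (shifted and wet[d]) else k

    interval = scenario.fix_interval_min
    slots_per_day = 24 * 60 // interval
    utc_off = timedelta(hours=scenario.local_utc_offset_hours)

    rows: dict[str, list] = {
        "individual-local-identifier": [],
        "timestamp": [],
        "location-long": [],
        "location-lat": [],
        "burst-id": [],
    }
    truth_nights: dict[str, dict[str, str]] = {}
    truth_days: dict[str, dict[str, dict]] = {}

    for ind in range(scenario.n_individuals):
        ind_id = f"{scenario.troop_id}{ind + 1}"
        jit = scenario.jitter_sd_m[ind % len(scenario.jitter_sd_m)]
        miss = scenario.miss_prob[ind % len(scenario.miss_prob)]
        truth_nights[ind_id] = {}
        truth_days[ind_id] = {}

        # nightly offset of this individual from the troop's site
        night_off: dict[_date, np.ndarray] = {
            d: (
                np.zeros(2)
                if ind == 0
                else rng.normal(0.0, scenario.night_spread_m, 2)
            )
            for d in dates
        }
        for d in dates:
            truth_nights[ind_id][d.isoformat()] = site_key_for(d)

        for d in dates[:-1]:
            d_next = d + timedelta(days=1)
            here = site_xy_for(d) + night_off[d]
            there = site_xy_for(d_next) + night_off[d_next]

            # --- itinerary -------------------------------------------------
            k = int(rng.integers(scenario.aois_per_day[0], scenario.aois_per_day[1] + 1))
            k = min(k, scenario.n_aois)
            chosen = list(rng.choice(scenario.n_aois, size=k, replace=False))
            if scenario.morning_vs_evening_shift_m > 0 and k >= 2:
                # evening-last AOI is the nearest to tonight's site, so the
                # morning leg is stochastically longer than the evening leg
                d_to_site = [
                    float(np.hypot(*(aoi_xy(i, d) - there))) for i in chosen
                ]
                last_pos = int(np.argmin(d_to_site))
                chosen.append(chosen.pop(last_pos))
                middle = chosen[:-1]
                rng.shuffle(middle)
                chosen = middle + chosen[-1:]
            else:
                rng.shuffle(chosen)

            depart_min = (scenario.depart_hour + rng.normal(0, 0.2)) * 60.0
            return_min = (scenario.return_hour + rng.normal(0, 0.2)) * 60.0
            waypoints = [here] + [aoi_xy(i, d) for i in chosen] + [there]
            legs = [
                float(np.hypot(*(b - a)))
                for a, b in zip(waypoints, waypoints[1:])
            ]
            speed = rng.uniform(*scenario.speed_ms)
            travel_min = [L / speed / 60.0 for L in legs]
            budget = return_min - depart_min - sum(travel_min)
            while budget < scenario.dwell_min_min * len(chosen) and len(chosen) > 1:
                # drop a middle AOI to make the day feasible
                drop = len(chosen) // 2
                chosen.pop(drop)
                waypoints = [here] + [aoi_xy(i, d) for i in chosen] + [there]
                legs = [
                    float(np.hypot(*(b - a)))
                    for a, b in zip(waypoints, waypoints[1:])
                ]
                travel_min = [L / speed / 60.0 for L in legs]
                budget = return_min - depart_min - sum(travel_min)
            if budget < scenario.dwell_min_min * max(1, len(chosen)):
                raise ValueError(
                    f"{ind_id} {d.isoformat()}: itinerary unreachable at "
                    f"{speed:.2f} m/s"
                )
            extra = rng.dirichlet(np.ones(len(chosen))) * (
                budget - scenario.dwell_min_min * len(chosen)
            )
            dwell_min = scenario.dwell_min_min + extra

            # --- schedule segments (minutes from local midnight) -----------
            segments: list[tuple[float, float, str, object]] = []
            segments.append((0.0, depart_min, "site", here))
            t = depart_min
            itinerary = []
            for leg_i, aoi_i in enumerate(chosen):
                t2 = t + travel_min[leg_i]
                segments.append((t, t2, "leg", (waypoints[leg_i], waypoints[leg_i + 1])))
                t3 = t2 + dwell_min[leg_i]
                segments.append((t2, t3, "dwell", aoi_xy(aoi_i, d)))
                itinerary.append(
                    {
                        "aoi": aoi_key(aoi_i, d),
                        "entry_min": round(t2, 2),
                        "exit_min": round(t3, 2),
                    }
                )
                t = t3
            t_arr = t + travel_min[-1]
            segments.append((t, t_arr, "leg", (waypoints[-2], waypoints[-1])))
            segments.append((t_arr, 24 * 60.0, "site", there))

            truth_days[ind_id][d.isoformat()] = {
                "itinerary": itinerary,
                "first_aoi": itinerary[0]["aoi"] if itinerary else None,
                "last_aoi": itinerary[-1]["aoi"] if itinerary else None,
                "depart_min": round(depart_min, 2),
                "arrive_min": round(t_arr, 2),
            }

            # --- emit fixes ------------------------------------------------
            for s in range(slots_per_day):
                t_min = s * interval
                if rng.uniform() < miss:
                    continue
                seg = next(
                    (sg for sg in segments if sg[0] <= t_min < sg[1]), segments[-1]
                )
                kind, payload = seg[2], seg[3]
                if kind == "site" or kind == "dwell":
                    base = np.asarray(payload, dtype=float)
                else:
                    a, b = payload
                    frac = (t_min - seg[0]) / max(seg[1] - seg[0], 1e-9)
                    base = a + (np.asarray(b) - np.asarray(a)) * frac + rng.normal(
                        0.0, 25.0, 2
                    )
                pos = base + rng.normal(0.0, jit, 2)
                if rng.uniform() < scenario.outlier_prob:
                    th = rng.uniform(0, 2 * np.pi)
                    pos = pos + rng.uniform(12_000, 25_000) * np.array(
                        [np.cos(th), np.sin(th)]
                    )

                t_local = datetime.combine(d, datetime.min.time()) + timedelta(
                    minutes=t_min
                )
                t_utc = (t_local - utc_off).replace(tzinfo=timezone.utc)
                burst_id = f"{ind_id}:{t_utc.isoformat()}"
                n_burst = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
                for b in range(n_burst):
                    if b < n_burst - 1:  # earlier burst fixes are noisier
                        p2 = pos + rng.normal(0.0, 4.0 * jit, 2)
                        t_fix = t_utc + timedelta(seconds=20 * (b - n_burst + 1) + 40)
                    else:
                        p2, t_fix = pos, t_utc + timedelta(seconds=40)
                    lon, lat = to_lonlat(p2)
                    rows["individual-local-identifier"].append(ind_id)
                    rows["timestamp"].append(
                        t_fix.strftime("%Y-%m-%d %H:%M:%S")
                    )
                    rows["location-long"].append(round(lon, 7))
                    rows["location-lat"].append(round(lat, 7))
                    rows["burst-id"].append(burst_id)

    df = pd.DataFrame(rows)
    truth = GroundTruth(
        sites=truth_sites,
        aois=truth_aois,
        nights=truth_nights,
        days=truth_days,
        sites_xy=truth_sites_xy,
        aois_xy=truth_aois_xy,
    )
    return df, truth


def scenario_presets() -> dict[str, TroopScenario]:
    """The two study-condition presets.

    ``floodplain_like`` displaces its whole range in the wet season
    (Nov-Mar inundation) and its most-used site accounts for ~10% of
    nights; ``woodland_like`` keeps one range year-round with evenly
    distributed site reuse and one noisier collar (10 m jitter, 4%
    missing fixes).
    """
    return {
        "floodplain_like": TroopScenario(
            troop_id="FT",
            n_days=300,
            n_sites=10,
            n_aois=15,
            jitter_sd_m=(5.0, 5.0),
            miss_prob=(0.04, 0.04),
            seasonal_shift_m=(2500.0, 1200.0),
            top_site_share=0.10,
            morning_vs_evening_shift_m=200.0,
            seed=11,
        ),
        "woodland_like": TroopScenario(
            troop_id="WT",
            n_days=300,
            n_sites=10,
            n_aois=15,
            jitter_sd_m=(5.0, 10.0),
            miss_prob=(0.01, 0.04),
            seasonal_shift_m=(0.0, 0.0),
            morning_vs_evening_shift_m=200.0,
            seed=12,
        ),
    }
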