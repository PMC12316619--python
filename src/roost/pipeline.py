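"""End-to-end orchestration: fixes -> sleep sites -> AOIs -> home ranges
-> night-level statistics.

All tunables live in :class:`PipelineConfig` with the study defaults
(100 m sleep-site linkage, 30 m / 15 min stops, 40 m merging, 30-day
windows, 10 km outlier jumps, 8 h day coverage, 95% ranges, wet season
Nov 1 - Mar 31).  ``run`` executes every stage per troop, writes CSV /
GeoJSON / text outputs, and embeds a config hash in the manifest so a
rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aoi as aoi_mod
from . import home_range as hr_mod
from . import sleep_sites as ss_mod
from . import stats as stats_mod
from . import trajectory as traj_mod


@dataclass
class PipelineConfig:
    """Every numeric rule of the analysis, with study defaults."""

    input_csv: str | None = None
    out_dir: str = "roost_out"
    column_map: dict[str, str] = field(default_factory=dict)
    troops: dict[str, list[str]] = field(default_factory=dict)  # troop -> individuals
    local_utc_offset_hours: float = 2.0
    sleep_cluster_threshold_m: float = 100.0
    stop_radius_m: float = 30.0
    stop_min_fixes: int = 2
    merge_distance_m: float = 40.0
    window_days: int = 30
    outlier_jump_m: float = 10_000.0
    day_coverage_min_h: float = 8.0
    exit_radius_m: float = 100.0
    home_range_level: float = 0.95
    kde_grid_res_m: float = 50.0
    home_range_methods: tuple[str, ...] = ("MCP", "KDE")
    wilcoxon_zero_method: str = "drop"  # or "pratt"
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "sleep_cluster_threshold_m",
            "stop_radius_m",
            "merge_distance_m",
            "outlier_jump_m",
            "exit_radius_m",
            "kde_grid_res_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.home_range_level < 1.0:
            raise ValueError("home_range_level must be in (0, 1)")
        if self.stop_min_fixes < 2:
            raise ValueError("stop_min_fixes must be >= 2")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.wilcoxon_zero_method not in ("drop", "pratt"):
            raise ValueError("wilcoxon_zero_method must be 'drop' or 'pratt'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "home_range_methods" in raw:
            raw["home_range_methods"] = tuple(raw["home_range_methods"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class TroopResult:
    troop_id: str
    nights: list
    sites: list
    assignment: dict
    day_records: list
    night_records: dict[str, list]  # method -> records
    home_ranges: dict[tuple[str, str], hr_mod.HomeRange]  # (method, season)
    lmm: dict[str, "stats_mod.LmmResult"]
    wilcoxon: "stats_mod.WilcoxonResult | None"
    cohesion: "ss_mod.CohesionSummary | None"


@dataclass
class RunResult:
    config: PipelineConfig
    troops: dict[str, TroopResult]
    cleaning: dict[str, traj_mod.CleaningReport]
    trajectories: dict[str, traj_mod.Trajectory]


def _polygons_geojson(ranges: dict, path: Path) -> None:
    feats = []
    for (method, season), hr in sorted(ranges.items()):
        for poly in hr.polygons:
            feats.append(
                {
                    "type": "Feature",
                    "properties": {
                        "troop": hr.troop_id,
                        "season": season,
                        "method": method,
                        "level": hr.level,
                        "area_m2": round(hr.area_m2, 1),
                    },
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [[round(x, 2), round(y, 2)] for x, y in poly.exterior.coords]
                        ],
                    },
                }
            )
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}, indent=1)
    )


def analyze_troop(
    troop_id: str,
    trajectories: dict[str, traj_mod.Trajectory],
    config: PipelineConfig,
    fit_models: bool = True,
) -> TroopResult:
    """All analysis stages for one troop (individuals pooled where the
    method pools them: site clustering, home ranges)."""
    nights_by_ind = {
        ind: ss_mod.extract_sleep_nights(
            traj, local_utc_offset_hours=config.local_utc_offset_hours
        )
        for ind, traj in trajectories.items()
    }
    pooled_nights = [n for seq in nights_by_ind.values() for n in seq]
    sites, assignment = ss_mod.build_sleep_sites(
        pooled_nights, threshold_m=config.sleep_cluster_threshold_m
    )

    day_records: list[aoi_mod.DayAoiRecord] = []
    for ind, traj in trajectories.items():
        recs, _ = aoi_mod.build_day_records(
            traj,
            nights_by_ind[ind],
            radius_m=config.stop_radius_m,
            min_fixes=config.stop_min_fixes,
            merge_m=config.merge_distance_m,
            window_days=config.window_days,
            exit_radius_m=config.exit_radius_m,
            min_coverage_h=config.day_coverage_min_h,
        )
        day_records.extend(recs)

    # seasonal home ranges pool the troop's individuals
    pts_by_season: dict[str, np.ndarray] = {}
    for season in ("wet", "dry"):
        pts = []
        for traj in trajectories.values():
            months = (
                traj.fixes["timestamp"]
                + pd.Timedelta(hours=config.local_utc_offset_hours)
            ).dt.month.to_numpy()
            is_wet = np.isin(months, (11, 12, 1, 2, 3))
            pts.append(traj.xy()[is_wet if season == "wet" else ~is_wet])
        nonempty = [p for p in pts if len(p)]
        if nonempty:
            allpts = np.vstack(nonempty)
            if len(allpts) >= 30:
                pts_by_season[season] = allpts

    home_ranges: dict[tuple[str, str], hr_mod.HomeRange] = {}
    for season, pts in pts_by_season.items():
        if "MCP" in config.home_range_methods:
            home_ranges[("MCP", season)] = hr_mod.mcp_home_range(
                pts, level=config.home_range_level, troop_id=troop_id, season=season
            )
        if "KDE" in config.home_range_methods:
            home_ranges[("KDE", season)] = hr_mod.kde_home_range(
                pts,
                level=config.home_range_level,
                grid_res_m=config.kde_grid_res_m,
                troop_id=troop_id,
                season=season,
            )

    night_records: dict[str, list] = {}
    lmm: dict[str, stats_mod.LmmResult] = {}
    wilcoxon = None
    for method in config.home_range_methods:
        hr_by_season = {
            season: hr
            for (m, season), hr in home_ranges.items()
            if m == method
        }
        records = stats_mod.build_night_records(
            pooled_nights, assignment, sites, day_records, hr_by_season, method=method
        )
        night_records[method] = records
        if fit_models and len(records) >= 10:
            try:
                lmm[method] = stats_mod.fit_reuse_lmm(records)
            except ValueError:
                pass
    base_method = config.home_range_methods[0]
    if fit_models and len(night_records.get(base_method, [])) >= 6:
        try:
            wilcoxon = stats_mod.wilcoxon_from_records(
                night_records[base_method],
                zero_method=config.wilcoxon_zero_method,
            )
        except ValueError:
            wilcoxon = None

    inds = sorted(nights_by_ind)
    cohesion = (
        ss_mod.cohesion_summary(nights_by_ind[inds[0]], nights_by_ind[inds[1]])
        if len(inds) >= 2
        else None
    )

    return TroopResult(
        troop_id=troop_id,
        nights=pooled_nights,
        sites=sites,
        assignment=assignment,
        day_records=day_records,
        night_records=night_records,
        home_ranges=home_ranges,
        lmm=lmm,
        wilcoxon=wilcoxon,
        cohesion=cohesion,
    )


def run(config: PipelineConfig, fixes: pd.DataFrame | None = None) -> RunResult:
    """Execute every stage and write the result bundle to ``out_dir``.

    ``fixes`` may be given directly (e.g. from the simulator); otherwise
    ``config.input_csv`` is read.  Individuals are grouped into troops
    by ``config.troops``; unlisted individuals form one troop per id
    prefix (all but the last character).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if fixes is None:
        if config.input_csv is None:
            raise ValueError("no input: provide fixes or config.input_csv")
        fixes, rejects = traj_mod.read_fix_table(
            config.input_csv, column_map=config.column_map or None
        )
        if len(rejects):
            rejects.to_csv(out / "rejected_rows.csv", index=False)
    else:
        fixes = traj_mod.canonicalize_fixes(
            fixes, column_map=config.column_map or None
        )

    trajectories, cleaning = traj_mod.clean_pipeline(
        fixes, max_jump_m=config.outlier_jump_m
    )

    troops = dict(config.troops)
    if not troops:
        by_prefix: dict[str, list[str]] = {}
        for ind in trajectories:
            by_prefix.setdefault(ind[:-1] if len(ind) > 1 else ind, []).append(ind)
        troops = {k: sorted(v) for k, v in sorted(by_prefix.items())}

    results: dict[str, TroopResult] = {}
    for troop_id, members in troops.items():
        sub = {i: trajectories[i] for i in members if i in trajectories}
        if not sub:
            continue
        results[troop_id] = analyze_troop(troop_id, sub, config)

    _write_bundle(config, results, cleaning, trajectories, out)
    return RunResult(
        config=config, troops=results, cleaning=cleaning, trajectories=trajectories
    )


def _write_bundle(config, results, cleaning, trajectories, out: Path) -> None:
    # cleaned trajectories
    frames = []
    for ind, traj in sorted(trajectories.items()):
        df = traj.fixes.copy()
        df.insert(0, "individual_id", ind)
        frames.append(df)
    if frames:
        pd.concat(frames).to_csv(out / "trajectories_clean.csv", index=False)

    rows = []
    for troop_id, res in sorted(results.items()):
        ss_mod.sleep_nights_frame(res.nights).to_csv(
            out / f"sleep_nights_{troop_id}.csv", index=False
        )
        ss_mod.sleep_sites_frame(res.sites, stats_mod.season_of).to_csv(
            out / f"sleep_sites_{troop_id}.csv", index=False
        )
        aoi_mod.day_records_frame(res.day_records).to_csv(
            out / f"day_records_{troop_id}.csv", index=False
        )
        for method, recs in res.night_records.items():
            stats_mod.night_records_frame(recs).to_csv(
                out / f"night_records_{troop_id}_{method}.csv", index=False
            )
        _polygons_geojson(res.home_ranges, out / f"home_ranges_{troop_id}.geojson")

        for method, fit in sorted(res.lmm.items()):
            tbl = pd.DataFrame(
                {
                    "estimate": fit.params,
                    "ci_lower": fit.conf_int["lower"],
                    "ci_upper": fit.conf_int["upper"],
                }
            )
            tbl.to_csv(out / f"lmm_{troop_id}_{method}.csv")
            txt = [
                f"Troop {troop_id} — reuse_count ~ distances ({method} home range)",
                tbl.to_string(float_format=lambda v: f"{v:.4g}"),
                f"Observations      {fit.n_obs}",
                f"Log likelihood    {fit.loglik:.3f}",
                f"AIC               {fit.aic:.3f}",
                f"BIC               {fit.bic:.3f}",
                f"RE variance       {fit.re_variance}",
                f"OLS fallback      {fit.fell_back_to_ols}",
            ]
            (out / f"lmm_{troop_id}_{method}.txt").write_text("\n".join(txt) + "\n")

        if res.wilcoxon is not None:
            w = res.wilcoxon
            rows.append(
                {
                    "troop": troop_id,
                    "V": w.v,
                    "p": w.p_value,
                    "effect_size": w.effect_size_r,
                    "n": w.n_pairs,
                }
            )
    if rows:
        pd.DataFrame(rows).to_csv(out / "wilcoxon.csv", index=False)

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "crs": next(iter(trajectories.values())).crs_label if trajectories else None,
        "stage_counts": {
            "individuals": len(trajectories),
            "fixes_retained": {k: v.n_retained for k, v in sorted(cleaning.items())},
            "outliers_removed": {
                k: v.n_outliers_removed for k, v in sorted(cleaning.items())
            },
            "sleep_nights": {t: len(r.nights) for t, r in sorted(results.items())},
            "sleep_sites": {t: len(r.sites) for t, r in sorted(results.items())},
            "day_records": {t: len(r.day_records) for t, r in sorted(results.items())},
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
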