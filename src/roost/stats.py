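"""Night-level records and the inferential layer.

Each analyzable night yields one row: the individual, date, season, the
sleep site used, how many times that site was used over the whole study
(the response), the unsigned distance from the night's anchor to the
seasonal home-range edge, and the distances linking the site to the last
AOI of the previous evening and the first AOI of the following morning.

Two pre-planned analyses mirror the field's standard toolkit:

* a linear mixed-effects model of reuse count on the three distances,
  with crossed random intercepts for season and individual identity
  (fit via variance components; run once per troop per home-range
  method);
* a paired Wilcoxon signed-rank test of morning-first vs evening-last
  AOI distance per night, with effect size r = |z| / sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date, timedelta
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import norm, rankdata

from .aoi import DayAoiRecord
from .home_range import HomeRange, distance_to_edge
from .sleep_sites import SleepNight, SleepSite

WET_MONTHS = {11, 12, 1, 2, 3}


def season_of(date: _date) -> str:
    """Wet season Nov 1 - Mar 31; dry season Apr 1 - Oct 31."""
    return "wet" if date.month in WET_MONTHS else "dry"


@dataclass(frozen=True)
class NightRecord:
    individual_id: str
    date: _date
    season: str
    site_id: int
    reuse_count: int
    dist_edge_m: float
    dist_last_aoi_m: float
    dist_first_aoi_m: float


@dataclass
class LmmResult:
    params: pd.Series  # fixed-effect estimates incl. intercept
    conf_int: pd.DataFrame  # 95% CI, columns [lower, upper]
    n_obs: int
    loglik: float
    aic: float
    bic: float
    re_variance: dict[str, float]
    residual_normality_p: float
    fell_back_to_ols: bool = False


@dataclass(frozen=True)
class WilcoxonResult:
    v: float  # sum of positive-difference ranks
    p_value: float
    effect_size_r: float
    n_pairs: int  # nonzero differences used


def build_night_records(
    nights: Sequence[SleepNight],
    assignment: dict[tuple[str, _date], int],
    sites: Sequence[SleepSite],
    day_records: Sequence[DayAoiRecord],
    home_ranges: dict[str, HomeRange],
    method: str = "MCP",
) -> list[NightRecord]:
    """Join sleep nights, site reuse, AOI distances, and edge distances.

    ``home_ranges`` maps season -> HomeRange for the chosen method.  The
    night dated d pairs with d's morning first-AOI distance and with day
    (d-1)'s evening last-AOI distance (both legs touch the same sleep
    site).  Rows missing any of the three distances, or whose season has
    no fitted home range, are dropped.
    """
    use_count = {s.site_id: s.use_count for s in sites}
    first_by = {(r.individual_id, r.date): r.dist_sleep_to_first_m for r in day_records}
    last_by = {(r.individual_id, r.date): r.dist_last_to_sleep_m for r in day_records}

    out: list[NightRecord] = []
    for n in nights:
        key = (n.individual_id, n.night_date)
        if key not in assignment:
            continue
        hr = home_ranges.get(season_of(n.night_date))
        if hr is None or hr.method != method:
            continue
        d_first = first_by.get(key)
        d_last = last_by.get((n.individual_id, n.night_date - timedelta(days=1)))
        if d_first is None or d_last is None:
            continue
        sid = assignment[key]
        out.append(
            NightRecord(
                individual_id=n.individual_id,
                date=n.night_date,
                season=season_of(n.night_date),
                site_id=sid,
                reuse_count=use_count[sid],
                dist_edge_m=distance_to_edge((n.x, n.y), hr),
                dist_last_aoi_m=float(d_last),
                dist_first_aoi_m=float(d_first),
            )
        )
    return out


def night_records_frame(records: Sequence[NightRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "date": r.date,
                "season": r.season,
                "site_id": r.site_id,
                "reuse_count": r.reuse_count,
                "dist_edge_m": r.dist_edge_m,
                "dist_last_aoi_m": r.dist_last_aoi_m,
                "dist_first_aoi_m": r.dist_first_aoi_m,
            }
            for r in records
        ]
    )


_FIXED = ["dist_edge_m", "dist_last_aoi_m", "dist_first_aoi_m"]


def fit_reuse_lmm(
    records: Sequence[NightRecord] | pd.DataFrame,
    singular_vc_tol: float = 1e-3,
) -> LmmResult:
    """Mixed model: reuse_count ~ the three distances, random intercepts
    for season and individual (crossed, fit as variance components).

    When every variance component collapses to (near) zero — below
    ``singular_vc_tol`` times the residual variance, the usual
    boundary-singularity situation — the random structure carries no
    information and the model is refit as OLS, flagged on the result;
    fixed effects then equal the least-squares estimates exactly.
    Zero-variance predictors raise ``ValueError``.
    """
    df = (
        records.copy()
        if isinstance(records, pd.DataFrame)
        else night_records_frame(records)
    )
    if df.empty:
        raise ValueError("no night records to fit")
    for col in _FIXED:
        if np.ptp(df[col].to_numpy(dtype=float)) == 0.0:
            raise ValueError(f"predictor {col} has no variance")

    formula = "reuse_count ~ " + " + ".join(_FIXED)
    vc = {
        "individual": "0 + C(individual_id)",
        "season": "0 + C(season)",
    }
    df["_one"] = 1
    fell_back = False
    try:
        import warnings

        with warnings.catch_warnings():
            # boundary fits (vc -> 0) are expected and handled below
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups="_one", vc_formula=vc)
            fit = model.fit(reml=False, method=["lbfgs", "powell"])
        vcomp = dict(zip(model.exog_vc.names, np.asarray(fit.vcomp, dtype=float)))
        singular = all(
            v < singular_vc_tol * float(fit.scale) for v in vcomp.values()
        )
    except Exception:
        vcomp = {}
        singular = True
    if singular:
        fell_back = True
        ols = smf.ols(formula, df).fit()
        ci = ols.conf_int(alpha=0.05)
        ci.columns = ["lower", "upper"]
        resid = ols.resid
        return LmmResult(
            params=ols.params,
            conf_int=ci,
            n_obs=int(ols.nobs),
            loglik=float(ols.llf),
            aic=float(ols.aic),
            bic=float(ols.bic),
            re_variance={k: 0.0 for k in ("individual", "season")},
            residual_normality_p=_shapiro_p(resid),
            fell_back_to_ols=True,
        )

    ci = fit.conf_int(alpha=0.05).loc[fit.fe_params.index]
    ci.columns = ["lower", "upper"]
    return LmmResult(
        params=fit.fe_params,
        conf_int=ci,
        n_obs=int(fit.nobs),
        loglik=float(fit.llf),
        aic=float(fit.aic),
        bic=float(fit.bic),
        re_variance=vcomp,
        residual_normality_p=_shapiro_p(np.asarray(fit.resid)),
        fell_back_to_ols=fell_back,
    )


def _shapiro_p(resid) -> float:
    from scipy.stats import shapiro

    r = np.asarray(resid, dtype=float)
    if len(r) < 3:
        return float("nan")
    if len(r) > 5000:  # shapiro's validity limit
        rng = np.random.default_rng(0)
        r = rng.choice(r, 5000, replace=False)
    return float(shapiro(r).pvalue)


def paired_wilcoxon(
    first: Sequence[float],
    last: Sequence[float],
    exact_max_n: int = 25,
    zero_method: str = "drop",
) -> WilcoxonResult:
    """Paired signed-rank test of morning-first vs evening-last distance.

    Differences first - last; ties mid-ranked.  Zero differences are
    dropped by default (the classical statistic); ``zero_method="pratt"``
    instead ranks them with the rest and discards only their signs, so
    frequent zero nights still widen the null.  V is the sum of ranks of
    positive differences.  The two-sided p is exact (equivalent to
    enumerating all 2^n sign assignments, valid under ties) for
    n <= ``exact_max_n``, else the normal approximation with continuity
    correction (Var V = sum r_i^2 / 4, which embeds the tie correction).
    Effect size r = |z|/sqrt(n).
    """
    diff = np.asarray(first, dtype=float) - np.asarray(last, dtype=float)
    if zero_method == "drop":
        diff = diff[diff != 0.0]
        ranks_all = rankdata(np.abs(diff))
        nonzero = np.ones(len(diff), dtype=bool)
    elif zero_method == "pratt":
        ranks_all = rankdata(np.abs(diff))
        nonzero = diff != 0.0
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n = int(nonzero.sum())
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = ranks_all[nonzero]
    v = float(ranks[diff[nonzero] > 0].sum())

    # normal approximation quantities (used for r in all cases)
    mu = ranks.sum() / 2.0
    sigma = sqrt(float((ranks**2).sum()) / 4.0)
    if sigma == 0:
        raise ValueError("degenerate rank distribution")
    z = (v - mu - 0.5 * np.sign(v - mu)) / sigma if v != mu else 0.0

    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, v)
    else:
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(
        v=v, p_value=p, effect_size_r=min(1.0, abs(z) / sqrt(n)), n_pairs=n
    )


def _exact_signed_rank_p(ranks: np.ndarray, v: float) -> float:
    """Exact two-sided p over all 2^n sign assignments, counted by
    dynamic programming on the rank sum.

    p = P(|V - mu| >= |v - mu|) under the null that each difference is
    positive or negative with probability 1/2; valid with mid-ranks
    (ranks are half-integers, so sums are tracked doubled).
    """
    r2 = np.round(2.0 * ranks).astype(int)  # doubled ranks are integers
    total2 = int(r2.sum())
    counts = np.zeros(total2 + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total2 + 1 - r]
        counts = counts + shifted
    mu2 = total2 / 2.0
    sums2 = np.arange(total2 + 1)
    extreme = np.abs(sums2 - mu2) >= abs(2.0 * v - mu2) - 1e-9
    return float(counts[extreme].sum() / 2.0 ** len(r2))


def wilcoxon_from_records(
    records: Sequence[NightRecord] | pd.DataFrame,
    zero_method: str = "drop",
) -> WilcoxonResult:
    """Run the paired test on night records (first vs last AOI distance)."""
    df = (
        records
        if isinstance(records, pd.DataFrame)
        else night_records_frame(records)
    )
    first = df["dist_first_aoi_m"].to_numpy(dtype=float)
    last = df["dist_last_aoi_m"].to_numpy(dtype=float)
    return paired_wilcoxon(first, last, zero_method=zero_method)
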