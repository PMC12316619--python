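# Methods

This note documents the models and procedures `roost` implements, the
choices made where the analysis rules left room, and what the synthetic
test bed does and does not establish.

## Coordinate handling

Raw fixes arrive as WGS84 longitude/latitude. All analysis distances
are straight-line metres, so fixes are projected into the UTM zone
containing the pooled data centroid (transverse Mercator, k₀ = 0.9996).
The projection is implemented in `roost.projection` from the classical
series expansion; within a zone it is accurate to well under a
millimetre and round-trips coordinates to < 1e-9°, which the test suite
verifies against an independent metres-per-degree series. Scale
distortion at the central meridian (≤ 4 × 10⁻⁴) is negligible against
GPS jitter.

## Trajectory cleaning

1. **Burst collapse** — collars fire a burst of fixes per 15-min slot;
   only the chronologically last fix of each burst is kept, as later
   fixes have had the longest satellite-acquisition time. Idempotent.
2. **Slot alignment** — fixes are binned to the nearest 15-min slot
   (last fix wins within a slot), establishing the one-fix-per-slot
   invariant downstream code assumes.
3. **Outlier removal** — a fix is an impossible jump when it lies more
   than `max_jump_m` (default 10 km per nominal 15-min interval, scaled
   linearly with the actual gap) from **both** temporal neighbours.
   The both-neighbour rule protects genuine long relocations, where the
   following fix agrees with the new position. Single pass.
4. **Day coverage** — day-level analyses require ≥ 8 h of fixes on the
   civil date.

Clock convention: collars log UTC; the 02:00 sleep anchor is matched in
local time (default UTC+2, configurable), since 02:00 local is the
biologically meaningful mid-night. A night belongs to the local
calendar date its anchor falls on; "the following day" is that same
date.

## Sleep sites

Nightly anchors from both collared individuals of a troop are pooled
and clustered by single linkage with a 100 m distance factor: two
nights share a site iff a chain of pairwise distances ≤ 100 m connects
them (distances exactly at the factor link; the partition is
order-independent). A site is summarised by the arithmetic mean of its
member anchors. Implementation uses `scipy.cluster.hierarchy`
single-linkage; tests verify exact agreement with a brute-force
union-find oracle on 500 random instances. Per-individual views
(unique sites per season, consecutive-night distances grouped by the
season of the later night, cross-season reuse, longest absence before
a return) are derived from the pooled clustering restricted to the
individual; individual-only clustering is available by passing one
individual's nights.

Cohesion (nightly distance between the troop's two collared
individuals) is a lower bound on sleeping group spread — only two
members carry collars.

## Areas of interest

Stops follow the origin-anchored rule: a stop opens at a fix whose
successor lies within 30 m of it, extends while fixes remain within
30 m of the stop's **first** fix (not its running centroid), and closes
at the first fix beyond. Runs of fewer than 2 fixes (15 min) are
dropped, and a temporal gap above twice the fix cadence breaks a run,
so member fixes are genuinely consecutive — without this, the overnight
gap left by daytime filtering could chain an evening dwell to the next
morning's visit to the same place.

Only daytime fixes participate: per day, from the first fix farther
than 100 m (the sleep-site cluster scale; configurable) from the
morning anchor to the last fix farther than 100 m from the coming
night's anchor.

Stops whose fixes come within 40 m of another stop's fixes merge
transitively; the merged set, hulled (degenerate hulls get a 5 m
buffer so every AOI has positive area), is an AOI. AOIs are built
independently within each trailing 30-day window ending on the
analysis date — trailing, not centred, so the set of "known" AOIs on a
given evening is causally available. An AOI counts as recurrent when
it holds ≥ 2 temporally distinct stops within its window; single-visit
AOIs are retained but flagged, and only recurrent AOIs enter day
records. Stops are merged per individual (the procedure is defined per
animal); merging across a troop would need a shared-resource
assumption the data cannot check.

Per day, the first AOI is the first recurrent AOI the animal entered
and completed a stop in after leaving the sleep site; the last AOI is
the final one before the evening entry. Distances run from the night's
anchor fix to the first utilized fix of the AOI's triggering stop —
the anchor (not the site centroid) is the conservative pairing, since
the anchor is the observed position; a centroid variant is a one-line
change in `day_aoi_record` callers.

## Home ranges

Per troop × season (wet: Nov 1 – Mar 31), both individuals pooled:

- **MCP** — points ranked by distance to their geographic mean
  ("most central" needs a definition; distance-to-mean is the simplest
  that makes the concentric profile monotone). The concentric profile
  (hull area at 5%, 10%, …, 100%) is emitted so the outlier knee that
  motivates the 95% cut is reproducible rather than visual; the cut
  level is a fixed config value (default 0.95).
- **KDE** — utilization distribution with an isotropic Gaussian kernel
  at the reference bandwidth h = σ·n^(−1/6), σ the mean of the
  coordinate standard deviations (the pooled-σ reading of the
  reference-bandwidth convention). Density is estimated by binning on
  a regular grid (resolution min(50 m, h/3), padded 3h beyond the data
  extent so boundary contours close) and convolving with the kernel;
  the home range is the smallest-density superlevel set holding ≥ 95%
  of the grid-integrated mass, its boundary extracted as contour
  polygons (disjoint modes yield multiple polygons; rings nested in
  another ring are treated as interior structure and dropped).

Edge distance is the unsigned minimum from a point to any boundary
segment, inside or out.

Tests verify the KDE 95% area against the closed-form Gaussian ellipse
π·χ²₀.₉₅(2)·σ² at n = 5000 (the kernel inflates the area by
(1 + h²/σ²) ≈ 6%, well inside the 15% test band) and edge distances
against a brute-force segment oracle.

## Night-level inference

A night enters the model when its site assignment, seasonal home range,
evening-last and morning-first AOI distances all exist. The response is
the site's use count over the full study (the night-level row
convention: every night at a site carries that site's total count).
Fixed effects are the three distances; random intercepts for season and
individual are crossed, fit as variance components by maximum
likelihood (`statsmodels` MixedLM). When every variance component
collapses below 10⁻³ of the residual variance the random structure is
singular and the model is refit as OLS, flagged on the result — this
also realises the invariant that the mixed model reduces to least
squares when the random effects carry no variance. The model runs once
per troop per home-range method (MCP and KDE). No multiple-testing
correction is applied: the two analyses are pre-planned. Residual
normality (Shapiro) is reported with each fit.

The paired Wilcoxon signed-rank test compares, per night, the distance
to the next morning's first AOI against the distance from the previous
evening's last AOI (both legs touch the same sleep site). Zero
differences are dropped (the classical statistic; nights where the
same AOI closes one day and opens the next contribute a zero), ties
are mid-ranked, V is the sum of positive-difference ranks. The
two-sided p is exact for n ≤ 25 — computed by dynamic programming over
the rank-sum distribution, equivalent to enumerating all 2ⁿ sign
assignments and valid under mid-ranks — and the tie-corrected normal
approximation with continuity correction otherwise. Effect size is
r = |z|/√n. Tests verify the exact p against brute-force enumeration
on 1000 random small samples and against `scipy.stats.wilcoxon` in the
tie-free regime.

## Synthetic troops

`roost.synthetic` generates the study conditions: two troops of two
collared individuals, 300 days at 15-min cadence, ~5 m GPS jitter
(10 m for one noisier collar), 1–4% missing fixes, rare > 10 km
outliers injected, bursts of 1–3 fixes per slot with noisier non-final
fixes. Each night the troop sleeps at one pooled site (the second
individual offset by a ~30 m Gaussian spread); each day an itinerary
of 3–5 AOI dwells (≥ 45 min each) is scheduled between a ~06:00
departure and ~17:30 return, connected by straight travel legs at
0.3–1.0 m/s with lateral scatter. Straight legs with scatter (rather
than a free random walk) keep arrival times exactly schedulable while
respecting the fix cadence and dwell rules — the only properties the
pipeline consumes; an infeasible itinerary raises an error naming the
day. The floodplain-like preset displaces its entire range by a fixed
vector during the wet season and its most-used site accounts for ~10%
of nights; the woodland-like preset keeps one range year-round with
even reuse.

Planted pools are generated with structural separations the analysis
assumes: sites ≥ 350 m apart (> 3 × the 100 m linkage factor, also
across the shifted/unshifted modes), AOIs ≥ 200 m apart and ≥ 250 m
from any site — an AOI inside the 100 m sleep-site exit radius would
have its dwells clipped by the daytime filter by construction.

Two generating handles create the effects the inference layer must
recover: `reuse_edge_slope` weights nightly site choice by
exp(slope × distance-to-range-edge), so interior sites are reused
more; `morning_vs_evening_shift_m` makes the evening-last AOI the one
nearest the coming night's site, so the morning leg stochastically
dominates the evening leg.

What the simulator does **not** emulate: terrain and habitat structure,
social dynamics, predator encounters, GPS error correlated with canopy,
collar duty-cycle drift, and any feedback of past choices on future
ones. Passing the recovery tests therefore shows the pipeline
faithfully implements its own rules at realistic noise levels — not
that those rules capture everything in real collar data.

## Problem sizes used in the checks

The oracle-equivalence checks run 500 clustering instances (≤ 200
points) and 100 scripted trajectories; planted-structure recovery runs
the full 300-day floodplain-like preset; the estimator-recovery check
fits 200 replicates of 450 nights at a generating edge slope of
+0.007 per m (the observed effect magnitude); the directional check
runs 50 independent 60-day troops; determinism re-runs a 30-day bundle
twice. These sizes make the whole suite complete in a couple of
minutes while keeping every probabilistic bound comfortably powered.

## Known limitations

- The 02:00-anchor convention assumes the troop is stationary at the
  sleep site at that hour; a troop moving at night would corrupt
  anchors silently.
- Reuse counts are study-total, so the response of the mixed model is
  constant within a site; the night-level rows weight sites by use, a
  site-level aggregation mode is the natural robustness check.
- The KDE boundary depends on the grid resolution near the isopleth;
  resolution is capped at h/3, but extremely clumped data (h → 0)
  would make the grid large.
- Wilcoxon zero-handling (drop vs mid-rank) is a config-visible choice;
  with ~20% same-AOI nights the dropped-zero n is noticeably smaller
  than the night count.
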