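# roost

Sleep-site selection analysis for GPS-collared primate troops.

Where a troop sleeps is one of the most consequential daily decisions a
primate makes: sleep trees offer safety from nocturnal predators, but the
chosen site also constrains the evening commute and the next morning's
start. `roost` turns raw collar fix streams (Movebank-style CSV, 15-min
burst cadence) into the quantities that analysis needs:

- **Sleep sites** — the nightly 02:00 anchor fix (02:30 when the 02:00
  acquisition failed), clustered by single linkage ("friends-of-friends")
  with a 100 m distance factor and summarised by the geographic mean;
  reuse counts, seasonal usage, cross-season returns, and nightly
  cohesion between the two collared troop members.
- **Areas of interest (AOIs)** — recurrent daytime stops: runs of ≥ 2
  consecutive fixes (> 15 min) within 30 m of the run's first fix, merged
  transitively at 40 m, hulled, and tracked per trailing 30-day window;
  per day, the first AOI entered after leaving the sleep site and the
  last before entering the evening site.
- **Seasonal home ranges** — the 95% minimum convex polygon over the
  most-central points (with the concentric 5%-step centrality profile
  that exposes outliers), and the 95% isopleth of a Gaussian-kernel
  utilization distribution with the reference bandwidth
  h = σ·n^(−1/6), σ = (sd_x + sd_y)/2.
- **Night-level inference** — one row per analysable night (site reuse
  count, unsigned distance to the seasonal range edge, distances to the
  evening-last and morning-first AOI), fit with

  reuse ~ dist_edge + dist_last_AOI + dist_first_AOI + (1 | season) + (1 | individual)

  and a paired Wilcoxon signed-rank test of morning-first vs
  evening-last AOI distance with effect size r = |z|/√n.

Because collar datasets of this kind are rarely deposited, the package
ships a ground-truthed simulator (`roost.synthetic`) that generates
troops with the full structure the analysis assumes — nightly site
fidelity, scripted daytime itineraries, a wet-season (Nov 1–Mar 31)
range displacement, burst fixes, jitter, missing fixes and gross
outliers — so every stage is testable end to end against planted truth.

## Worked example

`examples/05_night_models.py` simulates a 200-day troop whose site
choice favours interior sites and whose evening-last AOI is planted
nearer the sleep site, then runs the full pipeline:

```
MCP model (n=394): reuse ~ edge distance slope 0.1213 per m
    (95% CI 0.1125, 0.1302); RE variance {'individual': 0.0, 'season': 0.0}
paired Wilcoxon (first morning vs last evening AOI distance):
    V=71439, p=6.7e-47, r=0.72, n=394
```

The positive edge-distance slope with a CI excluding zero recovers the
planted preference for central sleep sites (reuse grows with distance
from the range edge); the large V with tiny p recovers the planted
asymmetry that mornings begin with the longer AOI leg. The other
examples (`examples/01`–`04`) walk the individual stages: cleaning,
sleep-site clustering, AOI detection, home ranges.

There is also a thin CLI:

```bash
roost simulate --preset floodplain_like --seed 1 --out fixes.csv --truth-out truth.json
roost run-all --input fixes.csv --out-dir out/
```

`run-all` writes per-troop CSV tables (sleep nights, sleep sites, day
records, night records), home-range GeoJSON, model summaries, and a
manifest embedding the config hash; reruns with the same inputs are
byte-identical.

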