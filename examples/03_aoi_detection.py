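"""Detect recurrent daytime areas of interest (AOIs).

Filters one individual's fixes to daytime (after leaving / before
entering the sleep site), finds origin-anchored stops (>= 2 consecutive
fixes within 30 m of the first), merges stops within 40 m into AOIs per
trailing 30-day window, and prints the first/last AOI distances that
feed the night-level analyses.
"""

from datetime import date

from roost.aoi import build_day_records, day_records_frame
from roost.sleep_sites import extract_sleep_nights
from roost.synthetic import TroopScenario, simulate_troop
from roost.trajectory import clean_pipeline

scenario = TroopScenario(
    troop_id="EX", n_days=60, n_sites=5, n_aois=8,
    morning_vs_evening_shift_m=200.0, start_date=date(2019, 9, 1), seed=3,
)
fixes, truth = simulate_troop(scenario)
trajectories, _ = clean_pipeline(fixes)

ind, traj = sorted(trajectories.items())[0]
nights = extract_sleep_nights(traj)
records, stops = build_day_records(traj, nights)
print(f"{ind}: {len(stops)} stops detected over {len(records)} analysable days")

df = day_records_frame(records).dropna()
print(df.head(8).to_string(index=False))
print(
    f"mean distance sleep site -> first morning AOI: "
    f"{df['dist_sleep_to_first_m'].mean():.0f} m"
)
print(
    f"mean distance last evening AOI -> sleep site:  "
    f"{df['dist_last_to_sleep_m'].mean():.0f} m"
)
# With the evening-last AOI planted nearer the sleep site, the morning
# leg is systematically the longer of the two.
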