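import numpy as np
import pandas as pd
import pytest

from roost.trajectory import Trajectory


@pytest.fixture
def make_trajectory():
    """Build a Trajectory from (minutes, x, y) triples."""

    def _make(points, individual_id="B1", t0="2019-09-01 04:00:00"):
        base = pd.Timestamp(t0, tz="UTC")
        rows = [
            {
                "timestamp": base + pd.Timedelta(minutes=m),
                "x": float(x),
                "y": float(y),
            }
            for m, x, y in points
        ]
        return Trajectory(
            individual_id=individual_id,
            fixes=pd.DataFrame(rows),
            crs_label="test-metric",
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_run():
    """One small troop simulated and analyzed end-to-end (shared)."""
    from roost.pipeline import PipelineConfig, analyze_troop
    from roost.synthetic import TroopScenario, simulate_troop
    from roost.trajectory import clean_pipeline

    scenario = TroopScenario(
        troop_id="ST",
        n_days=70,
        n_sites=6,
        n_aois=8,
        range_scale_m=1500.0,
        morning_vs_evening_shift_m=150.0,
        start_date=pd.Timestamp("2019-09-01").date(),
        seed=7,
    )
    fixes, truth = simulate_troop(scenario)
    trajs, reports = clean_pipeline(fixes)
    config = PipelineConfig()
    result = analyze_troop("ST", trajs, config, fit_models=False)
    return {
        "scenario": scenario,
        "fixes": fixes,
        "truth": truth,
        "trajectories": trajs,
        "reports": reports,
        "result": result,
    }
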