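import numpy as np
import pytest

from enantiopore import (
    PopulationSpec,
    SimConfig,
    simulate_trace,
    estimate_baseline,
    detect_events,
    extract_features,
    filter_events,
)

DETECTION = {"k": 7.0, "min_dwell_us": 200.0, "min_sigma_pa": 1.0, "min_norm_blockade": 0.2}


def run_chain(config: SimConfig, detection: dict = DETECTION):
    """simulate -> baseline -> detect -> featurize -> filter."""
    trace = simulate_trace(config)
    baseline = estimate_baseline(trace, k=detection["k"])
    featurized = extract_features(trace, detect_events(trace, baseline))
    filtered = filter_events(
        featurized,
        min_dwell_us=detection["min_dwell_us"],
        min_sigma_pa=detection["min_sigma_pa"],
        min_norm_blockade=detection["min_norm_blockade"],
    )
    return trace, featurized, filtered


@pytest.fixture(scope="session")
def typeii_chain():
    """A single Type IIa-like population at an elevated rate: a compact
    recording with ~1800 events for detection/feature/fit validation."""
    config = SimConfig(
        duration_s=30.0,
        populations=[PopulationSpec("TypeIIa", 0.43, 0.015, 820.0, 60.0)],
        seed=20240901,
    )
    return run_chain(config)


@pytest.fixture(scope="session")
def mixture_table():
    """Two overlapping blockade populations (70% at 0.39, 30% at 0.43)."""
    rng = np.random.default_rng(55)
    import pandas as pd

    from enantiopore import BaselineStats, EventTable

    n = 4000
    which = rng.random(n) < 0.7
    vals = np.where(
        which, rng.normal(0.39, 0.015, n), rng.normal(0.43, 0.015, n)
    )
    df = pd.DataFrame(
        {
            "start_index": np.arange(n) * 1000,
            "end_index": np.arange(n) * 1000 + 100,
            "t_t_us": rng.exponential(800.0, n) + 200.0,
            "norm_di_b": vals,
            "i_bs_pA": np.full(n, 3.0),
        }
    )
    return EventTable(df, BaselineStats(250.0, 2.0), 250_000.0)
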