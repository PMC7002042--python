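import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import vasculome as v

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_config() -> v.TruthConfig:
    """Baseline-only (homeostasis) study design without batch effects."""
    return v.TruthConfig(timepoints_h=(0.0,), batch_shift_log2=0.0, seed=11)


@pytest.fixture(scope="session")
def baseline_truth(baseline_config) -> v.SyntheticTruth:
    return v.build_truth(baseline_config)


@pytest.fixture(scope="session")
def baseline_bulk(baseline_truth, baseline_config) -> v.ExpressionMatrix:
    return v.simulate_bulk(baseline_truth, baseline_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def small_matrix(rng) -> v.ExpressionMatrix:
    """Random 60-gene x 9-sample count matrix with 3 tissues."""
    genes = pd.Index([f"g{i:03d}" for i in range(60)], name="gene")
    samples = pd.Index([f"s{i}" for i in range(9)], name="sample_id")
    values = pd.DataFrame(rng.poisson(50, (60, 9)), index=genes, columns=samples)
    meta = pd.DataFrame(
        {
            "tissue": ["brain"] * 3 + ["lung"] * 3 + ["heart"] * 3,
            "compartment": "EC",
            "timepoint_h": 0.0,
            "batch": ["b0", "b1"] * 4 + ["b0"],
            "platform": "bulk",
            "replicate": [1, 2, 3] * 3,
        },
        index=samples,
    )
    return v.ExpressionMatrix(values=values, samples=meta, scale="counts")
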