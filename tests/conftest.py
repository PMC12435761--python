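import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from cfdna2ta import Cohort, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def synthetic_cohort(default_config) -> Cohort:
    """One default-size synthetic cohort, shared across tests."""
    return generate_cohort(default_config, seed=12345)


@pytest.fixture()
def tiny_cohort() -> Cohort:
    """Three patients, mixed sample counts, one AR sample."""
    rows = []
    specs = [
        ("A", [(0.71, 58.0, "2R", "0"), (0.05, 3.0, "0", "0")]),
        ("B", [(0.04, 2.0, "0", "0")]),
        ("C", [(0.10, 6.0, "1R", "0"), (0.02, 1.0, "0", "0"), (0.30, 20.0, "0", "1H+")]),
    ]
    for pid, samples in specs:
        for k, (frac, dqs, acr, pamr) in enumerate(samples, 1):
            rows.append(
                {
                    "patient_id": pid,
                    "sample_id": f"{pid}-{k}",
                    "days_post_tx": 100 + 10 * k,
                    "dd_cfdna_pct": frac,
                    "dqs_cpml": dqs,
                    "total_cfdna_cpml": 100.0 * dqs / frac,
                    "acr_grade": acr,
                    "pamr_grade": pamr,
                    "indication": "surveillance",
                }
            )
    return Cohort(pd.DataFrame(rows))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
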