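import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gutresponse.synthetic import CohortConfig, generate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_patients=40,
        group_proportions={"PR": 0.3, "SD": 0.3, "PD": 0.3, "FD": 0.1},
        n_mgs=60,
        n_ko=90,
        n_pathways=12,
        pathway_size_range=(4, 10),
        n_differential_mgs=8,
        n_differential_pathways=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_meta(n_patients=10, atb_patients=(), responses=None, seed=0):
    """Minimal per-sample metadata table for IO/validation tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        resp = responses[i] if responses is not None else ["PR", "SD", "PD"][i % 3]
        rows.append(
            {
                "sample_id": f"{pid}_M0",
                "patient_id": pid,
                "timepoint": "M0",
                "week": 0,
                "response": resp,
                "atb": pid in atb_patients,
                "bmi": float(rng.normal(23, 2)),
                "tmb": float(rng.lognormal(1.5, 0.5)),
                "hla_e": "low",
                "pfs_months": float(rng.exponential(4) + 0.1),
                "pfs_event": True,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
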