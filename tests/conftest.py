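import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from prescreen import default_config, simulate_warehouse

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def calibrated_warehouse():
    """A mid-size warehouse drawn from the calibrated reference model."""
    cfg = default_config(n_patients=20_000, seed=11)
    return cfg, simulate_warehouse(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(202)


@pytest.fixture()
def two_tissue_zscores(rng):
    """120 samples in two tissues with known Z values for recount tests."""
    z_a = rng.normal(0.8, 1.0, size=60)
    z_b = rng.normal(-0.5, 0.7, size=60)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(120)],
            "tissue_type": ["alpha"] * 60 + ["beta"] * 60,
            "z": np.concatenate([z_a, z_b]),
        }
    )
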