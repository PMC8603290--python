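import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from melpipe import SimulationConfig, simulate_depth_profile, simulate_variant_calls

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def depth_profile(default_config):
    """Full-size depth simulation shared across CNV tests."""
    return simulate_depth_profile(default_config)


@pytest.fixture(scope="session")
def variant_calls(default_config):
    return simulate_variant_calls(default_config)


@pytest.fixture()
def toy_variant():
    """A single clean variant that passes every discard rule."""
    return pd.DataFrame(
        [
            {
                "chrom": "chr1",
                "pos": 1000,
                "ref": "A",
                "alt": "T",
                "callers": "caller_A,caller_B",
                "t_depth": 100,
                "t_alt": 30,
                "t_alt_fwd": 14,
                "t_alt_rev": 16,
                "n_alt": 0,
                "in_population_db": False,
                "in_blacklist_db": False,
                "consequence": "non_synonymous",
            }
        ]
    )


def perturb(toy, **kwargs):
    row = toy.iloc[0].to_dict()
    row.update(kwargs)
    return pd.DataFrame([row])
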