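import numpy as np
import pytest
from hypothesis import settings

import alesim

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_genotype_pop():
    """Ancestor (mu=0.2) and competitor (mu=0.3), 100 cells each."""
    return alesim.Population.from_arrays(
        np.array([100.0, 100.0]), np.array([0.2, 0.3]))


def make_config(**overrides):
    """Default 42-day tree with nested overrides merged in."""
    base = {}

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict):
                dst[k] = merge(dst.get(k, {}), v)
            else:
                dst[k] = v
        return dst

    merge(base, overrides)
    return alesim.validate_config(base)


@pytest.fixture
def quiet_deterministic_config():
    """Noise-free deterministic single-genotype run: the closed-form rig."""
    return make_config(
        run={"mode": "deterministic", "seed": 1},
        culture={"growth_rate": np.log(2),
                 "mutation": {"rate_per_division": 0.0}},
        biofilm={"enabled": False},
        sensor={"noise_sd": 0.0, "fouling_coeff": 0.0},
        controller={"run_duration_h": 24.0, "t_sampling_h": 0.01},
    )
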