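import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bnctkit.radiobiology import analyze_clonogenic
from bnctkit.synthetic import default_config, gen_clonogenic

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def gen_config():
    """The paper-anchored study design used by every generator test."""
    return default_config(seed=1)


@pytest.fixture(scope="session")
def noiseless_clonogenic(gen_config):
    """Zero-noise clonogenic table: counts equal their expectations."""
    cfg = dataclasses.replace(gen_config.clonogenic, noise=False)
    return gen_clonogenic(cfg, np.random.default_rng(0))


@pytest.fixture(scope="session")
def noiseless_effectiveness(noiseless_clonogenic):
    return analyze_clonogenic(noiseless_clonogenic)
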