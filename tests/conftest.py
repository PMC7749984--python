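import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cladetrace as ct

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset():
    return ct.build_scenario_preset("fig1_fig3")


@pytest.fixture(scope="session")
def mtdna_tree(preset):
    return ct.derive_locus_tree(preset, "mtDNA")


@pytest.fixture(scope="session")
def mtdna_alignment(preset, mtdna_tree):
    """One 16.5 kb replicate of the preset scenario (seed 1)."""
    return ct.simulate_alignment(mtdna_tree, preset, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
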