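import numpy as np
import pytest

from plumewake import synthetic as psynth


@pytest.fixture(scope="session")
def small_scenario():
    """A compact seeded scenario shared by read-only tests."""
    cfg = psynth.ScenarioConfig(
        domain_bounds=(0.0, 0.0, 1.5, 1.5),
        n_facilities=40,
        n_days=8,
        tract_nx=8,
        tract_ny=8,
        seed=7,
    )
    return psynth.generate_scenario(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
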