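import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pbrtqc import datagen, presets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cea_spec():
    return presets.get_preset("CEA")


@pytest.fixture(scope="session")
def cea_stream(cea_spec):
    """Medium CEA stream with covariate signal, shared across tests."""
    cfg = datagen.GeneratorConfig(n=20000, seed=3, covariate_effect_fraction=0.5)
    return datagen.generate_stream(cea_spec, cfg)


@pytest.fixture(scope="session")
def cea_splits(cea_stream):
    return datagen.split_chronological(cea_stream)


@pytest.fixture(scope="session")
def cea_panel(cea_spec):
    """Companion panel with two well-separated latent groups."""
    comps = [presets.get_preset(c) for c in presets.load_companions()["CEA"]]
    cfg = datagen.GeneratorConfig(n=20000, seed=2)
    return datagen.generate_panel(cea_spec, comps, cfg)


@pytest.fixture(scope="session")
def cea_panel_splits(cea_panel):
    return datagen.split_chronological(cea_panel)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(12345)
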