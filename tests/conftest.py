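import pytest
from hypothesis import HealthCheck, settings

import twinproj as tp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params_small():
    return tp.SynthParams(n_countries=3, mothers_per_country=3000, seed=42)


@pytest.fixture(scope="session")
def histories_small(params_small):
    return tp.generate_birth_histories(params_small)


@pytest.fixture(scope="session")
def deliveries_small(histories_small):
    return tp.collapse_to_deliveries(tp.apply_recall_window(histories_small, 10))


@pytest.fixture(scope="session")
def params_large():
    # ~250k deliveries across three countries spanning the observed
    # low-to-high baseline range, with the +0.01 late-30s age effect
    return tp.SynthParams(n_countries=3, mothers_per_country=30000, seed=42)


@pytest.fixture(scope="session")
def deliveries_large(params_large):
    hist = tp.generate_birth_histories(params_large)
    return tp.collapse_to_deliveries(tp.apply_recall_window(hist, 10))


@pytest.fixture(scope="session")
def lpm_large(deliveries_large):
    return tp.fit_lpm(deliveries_large)
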