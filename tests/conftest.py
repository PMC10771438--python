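import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def null10():
    from propscreen.rankcorr import exact_null

    return exact_null(10)


@pytest.fixture(scope="session")
def small_panel():
    """One deterministic small synthetic panel shared across tests."""
    from propscreen.synthetic import PanelConfig, simulate_panel

    cfg = PanelConfig(seed=42, n_probes=200)
    return cfg, simulate_panel(cfg)
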