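import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hera

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_panel() -> hera.ResourcePanel:
    """13-city x 3-region x 5-year synthetic panel under default conditions."""
    return hera.generate_panel(hera.PanelGenConfig(seed=0))


@pytest.fixture(scope="session")
def panel_csv(default_panel, tmp_path_factory):
    path = tmp_path_factory.mktemp("panels") / "panel.csv"
    hera.write_panel(default_panel, path)
    return path


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
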