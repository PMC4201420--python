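import numpy as np
import pytest

from panelpower import load_fixture_panel
from panelpower.synthpop import build_species_pair


@pytest.fixture(scope="session")
def panel_fixture():
    return load_fixture_panel()


@pytest.fixture(scope="session")
def panel(panel_fixture):
    return panel_fixture[0]


@pytest.fixture(scope="session")
def summary(panel_fixture):
    return panel_fixture[1]


@pytest.fixture(scope="session")
def species_model(panel, summary):
    """Frequency profiles matched per locus to the published (Na, He)."""
    return build_species_pair(summary, panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
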