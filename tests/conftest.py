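import pytest

from adscreen.qsar import load_shipped_models
from adscreen.synthetic_data import make_molecule_fixtures


@pytest.fixture(scope="session")
def fixture_molecules():
    """The deterministic synthetic molecule panel (seed 0)."""
    return make_molecule_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_panel(fixture_molecules):
    """A 20-molecule slice for descriptor-heavy tests."""
    return fixture_molecules[:12] + fixture_molecules[-8:]


@pytest.fixture(scope="session")
def shipped_models():
    return load_shipped_models()
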