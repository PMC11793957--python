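import pytest

from desperation.panel import GeneratorConfig, generate_panel
from desperation.preprocess import preprocess_panel


@pytest.fixture(scope="session")
def default_panel():
    """One default-configuration panel, shared across tests."""
    return generate_panel(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def processed_panel(default_panel):
    return preprocess_panel(default_panel)


@pytest.fixture(scope="session")
def small_processed_panel():
    """A quick 120-participant panel for fit-speed-sensitive tests."""
    raw = generate_panel(GeneratorConfig(seed=7, n_participants=120, n_waves=5))
    return preprocess_panel(raw)
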