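import pytest
from hypothesis import settings

from zoometry.simulate import build_default_config, simulate_herd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return build_default_config()


@pytest.fixture(scope="session")
def small_herd(default_config):
    """The 95-animal reference-sized herd at a fixed seed."""
    return simulate_herd(default_config, seed=42)
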