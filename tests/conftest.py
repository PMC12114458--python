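import pytest

from cytocide import GatingConfig, SyntheticConfig


@pytest.fixture
def cfg() -> SyntheticConfig:
    """Small, fast synthetic assay used across tests."""
    return SyntheticConfig(seed=11, n0_events=300.0, growth_factor=20.0)


@pytest.fixture
def gating_cfg() -> GatingConfig:
    return GatingConfig()
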