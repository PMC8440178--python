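import pytest

from neuroconcord.simulate import default_panel_scenario, gen_effect_panel


@pytest.fixture(scope="session")
def default_panel():
    """One seeded draw of the default 7-disorder scenario (75/74/41 masks)."""
    return gen_effect_panel(default_panel_scenario(seed=12345))


@pytest.fixture(scope="session")
def default_scenario():
    return default_panel_scenario(seed=12345)
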