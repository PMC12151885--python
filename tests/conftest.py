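import pytest

from omicage import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """Six-block cohort at reduced feature counts, shared across tests."""
    cfg = syn.default_config(seed=11, scale=0.15)
    return syn.simulate_cohort(cfg)
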