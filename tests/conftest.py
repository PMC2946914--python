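import pytest

from emrqtl.filters import default_lexicon, default_registry
from emrqtl.simulate import CausalEffect, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed fixture: 150 patients, 60 markers, one planted QTL."""
    cfg = SimConfig(
        n_patients=150,
        m_snps=60,
        seed=11,
        causal_spec=[CausalEffect(7, "HGB", 0.05)],
    )
    return simulate_dataset(cfg)
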