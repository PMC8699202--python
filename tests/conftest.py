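import numpy as np
import pytest

from pepccs import GeneratorConfig, default_chemistry, generate_peptides


@pytest.fixture(scope="session")
def chem():
    return default_chemistry()


@pytest.fixture(scope="session")
def random_peptides():
    """200 reproducible tryptic-like peptides covering both modifications."""
    cfg = GeneratorConfig(
        n_peptides=200, met_ox_prob=0.3, acetyl_prob=0.2, seed=1234
    )
    return generate_peptides(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
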