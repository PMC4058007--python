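import numpy as np
import pytest

from venomexome.synthetic_data import (
    SyntheticConfig,
    generate_bundle,
    generate_peptide_ids,
)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def bundle(default_config):
    return generate_bundle(default_config)


@pytest.fixture(scope="session")
def full_detection_bundle():
    """Bundle where every eligible tryptic fragment is detected."""
    cfg = SyntheticConfig(seed=1, detect_prob=1.0)
    return generate_bundle(cfg), generate_peptide_ids(
        generate_bundle(cfg).truth, cfg
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def random_protein(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
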