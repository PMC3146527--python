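import numpy as np
import pytest

from cksaap_ubsite import (
    FixtureConfig,
    Fragment,
    encode_dataset,
    generate_fixture,
)
from cksaap_ubsite.sequence_io import AMINO_ACIDS


def random_fragment(rng, length=None, label="unknown", pid="P", window=27):
    """A random window-27 fragment of the given (or random 2..27) length,
    truncated consistently: at most 13 residues on either side of the K."""
    n = (window - 1) // 2
    if length is None:
        length = int(rng.integers(2, window + 1))
    left = int(rng.integers(max(0, length - 1 - n), min(n, length - 1) + 1))
    residues = list(rng.choice(list(AMINO_ACIDS), size=length))
    residues[left] = "K"
    return Fragment(pid, left + 1, "".join(residues), left, label)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20110729)


@pytest.fixture(scope="session")
def signal_dataset():
    """Small synthetic dataset with strong implanted pair signals."""
    config = FixtureConfig(
        n_pos=80,
        n_neg=240,
        implants=[("ExE", 0.8), ("EQ", 0.8), ("KxxK", 0.8)],
        seed=42,
    )
    return generate_fixture(config)


@pytest.fixture(scope="session")
def signal_Xy(signal_dataset):
    X = encode_dataset(signal_dataset)
    y = np.array(
        [1 if f.label == "positive" else 0 for f in signal_dataset.fragments]
    )
    return X, y
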