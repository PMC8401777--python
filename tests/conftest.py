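import numpy as np
import pytest

from mmpcliff.fingerprints import XOR, AND, abstract_fingerprint
from mmpcliff.fixtures import PlantedCliffSpec, generate_cliff_dataset
from mmpcliff.fragmentation import generate_mmps, group_into_mms


def random_abstract_fp(rng, max_bits=10):
    """Random abstract MMP fingerprint with non-empty segments."""
    n_core = rng.integers(1, max_bits + 1)
    n_sub = rng.integers(1, max_bits + 1)
    core = rng.choice(2 * max_bits, size=n_core, replace=False)
    sub_ids = rng.choice(2 * max_bits, size=n_sub, replace=False)
    channels = rng.choice([XOR, AND], size=n_sub)
    return abstract_fingerprint(
        core=[int(c) for c in core],
        sub=[(str(ch), int(s)) for ch, s in zip(channels, sub_ids)],
    )


@pytest.fixture(scope="session")
def small_cliff_mmps():
    """MMPs from a 3-series planted-cliff dataset (fast, deterministic)."""
    spec = PlantedCliffSpec(n_series=3, series_size=4, seed=11)
    compounds = generate_cliff_dataset(spec)
    return generate_mmps(compounds)


@pytest.fixture(scope="session")
def small_cliff_mms(small_cliff_mmps):
    return group_into_mms(small_cliff_mmps)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
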