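import numpy as np
import pytest
from hypothesis import settings

import morfhmm as m

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_dataset():
    """12 synthetic sequences with a strong planted MoRF signal."""
    return m.generate_dataset(
        m.SimConfig(n_sequences=12, signal_strength=0.9, seed=11)
    )


@pytest.fixture(scope="session")
def labelled(small_dataset):
    """(profile, region labels) pairs aligned by sequence."""
    return [
        (p, m.annotate_regions(s))
        for p, s in zip(small_dataset.profiles, small_dataset.sequences)
    ]


@pytest.fixture(scope="session")
def small_ensemble(labelled):
    """Default nine-model ensemble trained on the small dataset."""
    return m.train_ensemble(labelled, master_seed=11)


@pytest.fixture()
def flat_profile():
    """A 6-residue profile with uniform 0.05 emission everywhere."""
    probs = np.full((6, 20), 0.05)
    from morfhmm.profile_io import profile_from_probs

    return profile_from_probs("flat", "ACDEFG", probs)
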