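import numpy as np
import pytest

from speccons import SimConfig, Spectrum, make_dataset


def spectrum(spectrum_id, peaks, **kwargs):
    """Shorthand for building a spectrum from (mz, intensity) pairs."""
    arr = np.asarray(peaks, dtype=float).reshape(-1, 2)
    return Spectrum(spectrum_id, arr[:, 0], arr[:, 1], **kwargs)


@pytest.fixture
def small_dataset():
    """Ten pure 4-member clusters at simulator defaults."""
    return make_dataset(SimConfig(n_clusters=10, members_per_cluster=4, seed=42))


@pytest.fixture
def mixed_dataset():
    """Ten 4-member clusters, half with one contaminant member."""
    return make_dataset(
        SimConfig(n_clusters=10, members_per_cluster=4, seed=7, contamination_fraction=0.5)
    )
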