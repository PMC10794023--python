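import numpy as np
import pytest

from comsv.formats.maps import LabelMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_ref():
    """A 200 kb reference map with labels every ~10 kb."""
    positions = np.arange(10_000.0, 200_000.0, 10_000.0)
    return LabelMap("ref1", 200_000.0, positions)


def random_label_maps(rng, n, max_labels=30, length=300_000.0):
    maps = []
    for i in range(n):
        k = int(rng.integers(0, max_labels))
        pos = np.sort(rng.uniform(1.0, length, k))
        pos = pos[np.concatenate([[True], np.diff(pos) > 1.0])] if k else pos
        maps.append(LabelMap(f"m{i}", length, pos))
    return maps
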