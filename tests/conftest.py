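import numpy as np
import pytest

from htsqc import Assay, PlateGrid, assay_from_array


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_plate(rng):
    """Random 8x12 plate, all wells valid."""
    return PlateGrid(rng.standard_normal((8, 12)))


@pytest.fixture
def masked_plate(rng):
    """8x12 plate with control columns 1 and 12 masked out."""
    mask = np.ones((8, 12), dtype=bool)
    mask[:, 0] = mask[:, -1] = False
    return PlateGrid(rng.standard_normal((8, 12)), mask)


@pytest.fixture
def small_assay(rng):
    """Five-plate 8x12 assay."""
    return assay_from_array(rng.standard_normal((5, 8, 12)))


def make_replicated(rng, n_pairs=3, shape=(4, 6)) -> Assay:
    """Random assay of n_pairs replicate pairs (plates 2k-1, 2k paired)."""
    values = rng.standard_normal((2 * n_pairs, *shape))
    pairing = {}
    for k in range(n_pairs):
        a, b = 2 * k + 1, 2 * k + 2
        pairing[a] = b
        pairing[b] = a
    return assay_from_array(values, replicate_of=pairing)
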