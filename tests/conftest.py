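import numpy as np
import pytest

import sweeppower as sp


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_model():
    """Small constant population for fast engine tests."""
    return sp.make_constant(1000, label="constant-1000")


@pytest.fixture(scope="session")
def toy_sample():
    """Hand-written 6-chromosome sample with 5 segregating sites.

    Columns (derived-allele counts): 1, 3, 1, 5, 2.
    """
    matrix = np.array(
        [
            [1, 1, 0, 1, 0],
            [0, 1, 0, 1, 0],
            [0, 1, 1, 1, 1],
            [0, 0, 0, 1, 1],
            [0, 0, 0, 1, 0],
            [0, 0, 0, 0, 0],
        ],
        dtype=np.uint8,
    )
    positions = np.array([100.0, 250.0, 400.0, 550.0, 800.0])
    return sp.HaplotypeSample(matrix=matrix, positions=positions, L=1000.0)
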