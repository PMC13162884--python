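import numpy as np
import pytest

from stea import (
    ExpressionMatrix,
    ReferenceParams,
    SpotCoordinates,
    generate_dataset,
    generate_reference,
)


@pytest.fixture(scope="session")
def small_reference():
    """Synthetic single-cell reference, 6 types, kept small for speed."""
    params = ReferenceParams(n_genes=300, cells_per_type=50)
    return generate_reference(params, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_reference):
    """One pseudo-spot dataset of 200 spots with ground truth."""
    return generate_dataset(small_reference, n_spots=200, seed=12)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def tiny_matrix():
    values = np.array(
        [
            [5.0, 0.0, 1.0, 2.0],
            [0.0, 3.0, 1.0, 0.0],
            [2.0, 2.0, 2.0, 2.0],
        ]
    )
    return ExpressionMatrix(values, ["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"])


@pytest.fixture()
def corner_coords():
    """Four spots at the corners of the unit square."""
    return SpotCoordinates(
        ["s1", "s2", "s3", "s4"],
        np.array([0.0, 1.0, 0.0, 1.0]),
        np.array([0.0, 0.0, 1.0, 1.0]),
    )


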