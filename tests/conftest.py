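import numpy as np
import pytest

from metboxscan import published_matrix
from metboxscan.synthetic import consensus_planting_matrix

# Printed final counts table: rows A, C, G, T; half-site positions 1-4.
PRINTED_COUNTS = np.array(
    [
        [634, 156, 721, 37],
        [6, 25, 84, 573],
        [135, 560, 27, 4],
        [57, 91, 0, 218],
    ]
)

# Printed bit weights of the same table, two decimals.
PRINTED_BITS = np.array(
    [
        [1.61, -0.42, 1.79, -2.49],
        [-5.12, -3.06, -1.31, 1.46],
        [-0.62, 1.43, -2.95, -5.70],
        [-1.87, -1.19, -7.70, 0.07],
    ]
)

POOL_SIZE = 832


@pytest.fixture(scope="session")
def final_matrix():
    """The shipped published-counts matrix (mu=2, pseudocount 1)."""
    return published_matrix()


@pytest.fixture(scope="session")
def planting_matrix():
    """Sharp consensus-peaked matrix used by recovery benchmarks."""
    return consensus_planting_matrix()
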