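import numpy as np
import pytest

from bibackbone.core import BipartiteMatrix

# worked example: agent and artifact degree sequences [1, 1, 2];
# one of the five fixed-margin matrices realizing those margins
TABLE1_MARGINS = ([1, 1, 2], [1, 1, 2])
TABLE1_EXACT = np.array(
    [[0.2, 0.2, 0.6], [0.2, 0.2, 0.6], [0.6, 0.6, 0.8]]
)
TABLE1_BICM = np.array(
    [[0.216, 0.216, 0.568], [0.216, 0.216, 0.568], [0.568, 0.568, 0.863]]
)


@pytest.fixture
def table1_matrix() -> BipartiteMatrix:
    return BipartiteMatrix(
        np.array([[1, 0, 0], [0, 0, 1], [0, 1, 1]]),
        ["F1", "F2", "F3"],
        ["I1", "I2", "I3"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20211214)
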