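import numpy as np
import pytest

from glasstree.matrix_io import CharacterMatrix, read_tree


@pytest.fixture
def quartet_tree():
    return read_tree("((A,B),(C,D));")


@pytest.fixture
def quartet_matrix():
    cells = np.array(
        [
            ["0", "0", "1"],
            ["0", "1", "1"],
            ["1", "0", "0"],
            ["1", "1", "0"],
        ]
    )
    return CharacterMatrix(["A", "B", "C", "D"], cells)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
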