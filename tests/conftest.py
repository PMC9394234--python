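import numpy as np
import pytest

from clonefish import CellProfile, SubcloneCode


@pytest.fixture
def diploid_male_cell():
    return CellProfile("c1", "s1", (1, 2, 2, 2, 2, 2, 2, 2))


def make_cell(cell_id, counts, sample_id="s1"):
    return CellProfile(cell_id, sample_id, tuple(counts))


def codes(*strings):
    return [SubcloneCode.from_string(s) for s in strings]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
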