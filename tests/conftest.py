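import logging

import numpy as np
import pytest

from mgrselect.measures import DiscreteMatrix
from mgrselect.simulate import Module2Model, gen_module2

logging.getLogger("mgrselect").setLevel(logging.ERROR)


@pytest.fixture
def module2_matrix():
    """A single module-2 draw at the default study conditions (n=200, p=10)."""
    return gen_module2(Module2Model(seed=42))


@pytest.fixture
def eight_sample_matrix():
    """One binary variable splitting 8 samples 4/4, with pi1 = 0.75.

    Cell (0,) holds 2 cases of 4; cell (1,) holds 4 of 4 — the worked
    partition used across the measure examples.
    """
    x = np.array([[0], [0], [0], [0], [1], [1], [1], [1]])
    y = np.array([1, 1, 0, 0, 1, 1, 1, 1])
    return DiscreteMatrix(x, ("X1",), y)


def planted_triple_matrix(n, p, seed, kind="majority", noise=0.15):
    """Binary design with a planted 3-variable signal on columns 0..2."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=(n, p), dtype=np.int64)
    if kind == "xor":
        sig = (x[:, 0] + x[:, 1] + x[:, 2]) % 2
    else:
        sig = (x[:, 0] + x[:, 1] + x[:, 2] >= 2).astype(int)
    flip = rng.random(n) < noise
    y = np.where(flip, rng.integers(0, 2, size=n), sig)
    return DiscreteMatrix(x, tuple(f"V{i}" for i in range(p)), y)
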