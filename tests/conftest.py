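import numpy as np
import pytest

from exprecover import (
    ExpressionMatrix,
    ObservationMask,
    SyntheticSpec,
    generate_low_rank,
    sample_mask,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix():
    """3x2 fully observed raw-scale matrix with ids."""
    vals = np.array([[1.0, 2.5], [0.0, 7.0], [3.25, 4.5]])
    return ExpressionMatrix(vals, ["gA", "gB", "gC"], ["s1", "s2"], scale="raw")


@pytest.fixture
def lowrank_80x60():
    """Rank-2 Gaussian-factor matrix with a 60%-observability mask."""
    x = generate_low_rank(SyntheticSpec(80, 60, 2, seed=7))
    mask = sample_mask(80, 60, 0.6, seed=8)
    return x, mask


@pytest.fixture
def full_mask_3x2():
    return ObservationMask.full(3, 2)
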