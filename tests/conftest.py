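import numpy as np
import pytest

from dcim import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_block_matrix():
    """4 genes x 3 samples with two well-separated gene blocks."""
    rng = np.random.default_rng(7)
    vals = np.vstack([rng.normal(0, 0.5, (2, 3)), rng.normal(1.5, 0.5, (2, 3))])
    return ExpressionMatrix(vals, list("abcd"), ["s1", "s2", "s3"])


@pytest.fixture
def small_matrix():
    """8 genes x 4 samples, unstructured noise."""
    rng = np.random.default_rng(11)
    vals = rng.normal(size=(8, 4))
    return ExpressionMatrix(
        vals, [f"g{i}" for i in range(8)], [f"s{j}" for j in range(4)]
    )
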