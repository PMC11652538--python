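import numpy as np
import pytest

from rankwarn import ExpressionMatrix, compute_baseline


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 samples with one baseline-mean tie."""
    return ExpressionMatrix([[1, 3], [2, 2], [5, 1]],
                            gene_ids=["a", "b", "c"],
                            sample_ids=["s1", "s2"])


@pytest.fixture
def ladder_baseline():
    """Baseline with expression [1, 2, 3] (ranks [1, 2, 3])."""
    m = ExpressionMatrix([[1.0], [2.0], [3.0]],
                         gene_ids=["a", "b", "c"], sample_ids=["n1"])
    return compute_baseline(m)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
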