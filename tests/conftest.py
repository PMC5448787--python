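import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(np.ravel(a), np.ravel(b))[0, 1])


def mean_bimf_correlation(stack_a, stack_b) -> float:
    """Mean per-level Pearson correlation, skipping degenerate all-zero levels."""
    corrs = []
    for s1, s2 in zip(stack_a, stack_b):
        if not np.any(s1) or not np.any(s2):
            continue
        corrs.append(pearson(s1, s2))
    return float(np.mean(corrs))
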