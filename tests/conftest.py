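import numpy as np
import pytest


@pytest.fixture
def rng():
    """Deterministic generator for test-local randomness."""
    return np.random.default_rng(20220708)


def random_table(rng, max_margin=30):
    """Random non-degenerate 2x2 table with margins up to max_margin."""
    n = int(rng.integers(1, max_margin))
    m = int(rng.integers(1, max_margin))
    a = int(rng.integers(0, n + 1))
    c = int(rng.integers(0, m + 1))
    return a, n - a, c, m - c
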