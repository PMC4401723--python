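import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(seed, n=None, lo=0, hi=10):
    """Random integer QAP instance (A, B) for oracle comparisons."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(3, 8))
    A = rng.integers(lo, hi, (n, n)).astype(float)
    B = rng.integers(lo, hi, (n, n)).astype(float)
    return A, B


def kb_double_loop(A, B, pi):
    """Independent element-wise oracle for the trace objective."""
    n = len(pi)
    total = 0.0
    for u in range(n):
        for v in range(n):
            total += A[u, v] * B[pi[u], pi[v]]
    return total
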