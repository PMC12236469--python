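import numpy as np
import pandas as pd
import pytest

from opscreen.simulate import make_barcode_lookup


@pytest.fixture(scope="session")
def small_lookup():
    """100 length-12 codes at pairwise edit distance >= 3."""
    return make_barcode_lookup(100, 12, 3, seed=7)


@pytest.fixture(scope="session")
def dual_lookup():
    return make_barcode_lookup(20, 8, 3, seed=7, dual=True)


def brute_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance (test oracle)."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[m]


@pytest.fixture(scope="session")
def levenshtein_oracle():
    return brute_levenshtein
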