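import numpy as np
import pytest

import ecrfpop as ep


@pytest.fixture(scope="session")
def term():
    return ep.build_fixture_terminology()


@pytest.fixture(scope="session")
def chd_form():
    return ep.build_fixture_form("chd_like")


@pytest.fixture(scope="session")
def pneumonia_form():
    return ep.build_fixture_form("pneumonia_like")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_lcs(a, b):
    """Independent LCS oracle: enumerate all subsequences of the shorter
    string and keep the longest that is also a subsequence of the other."""
    if len(a) > len(b):
        a, b = b, a

    def is_subseq(s, t):
        it = iter(t)
        return all(ch in it for ch in s)

    best = 0
    n = len(a)
    for mask in range(1 << n):
        sub = [a[i] for i in range(n) if mask >> i & 1]
        if len(sub) > best and is_subseq(sub, b):
            best = len(sub)
    return best


@pytest.fixture(scope="session")
def lcs_oracle():
    return brute_force_lcs
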