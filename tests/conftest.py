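import numpy as np
import pytest
from hypothesis import settings

import mortcomp as mc

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def lc1_truth():
    """Ground-truth LC1 parameters on the 50x20 recovery grid."""
    return mc.make_params(50, 20, "LC1", seed=3)


@pytest.fixture(scope="session")
def lc1_surface(lc1_truth):
    """High-exposure (1e6/cell) binomial surface drawn from the LC1 truth."""
    return mc.simulate_deaths(lc1_truth, 1e6, seed=7)


@pytest.fixture(scope="session")
def lc1_fit(lc1_surface):
    return mc.fit_lc(lc1_surface, r=1)


@pytest.fixture(scope="session")
def small_table():
    """Two-age hand-checkable life table: q = [0.5, 1.0], radix 1000."""
    return mc.build_period_table([0.5, 1.0], radix=1000)


def brute_force_table(q, radix=100_000.0):
    """Independent direct-sum life-table oracle (explicit loops, no recursion
    shared with the implementation)."""
    q = list(q)
    q[-1] = 1.0
    l = [radix]
    for qi in q[:-1]:
        l.append(l[-1] * (1 - qi))
    d = [li * qi for li, qi in zip(l, q)]
    L = [li - 0.5 * di for li, di in zip(l, d)]
    T = [sum(L[x:]) for x in range(len(q))]
    return l, d, L, T
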