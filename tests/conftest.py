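import numpy as np
import pytest
from hypothesis import settings

import alignkt as ak

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A small, cheap parameter set with interactions and noise."""
    return ak.make_params(N=40, M=0.5, Gamma=-0.3, Dr=0.2, n=2, dt=0.01)


def brute_force_pairs(positions, L, R):
    """O(N^2) minimum-image neighbor enumeration (independent oracle)."""
    N = len(positions)
    out = []
    for i in range(N):
        for j in range(i + 1, N):
            d = positions[j] - positions[i]
            d -= L * np.round(d / L)
            if d @ d <= R * R:
                out.append((i, j))
    return sorted(out)
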