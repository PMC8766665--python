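import numpy as np
import pytest

from matrixstim import generate_slice, mea_8x8
from matrixstim.slice_sim import copy_slice


@pytest.fixture(scope="session")
def array8():
    return mea_8x8()


@pytest.fixture(scope="session")
def _base_slice():
    return generate_slice(seed=1)


@pytest.fixture
def slice1(_base_slice):
    """Default virtual slice (seed 1), fresh plasticity state per test."""
    return copy_slice(_base_slice)


def match_events(truth_times, det_times, tol_ms=3.0):
    """Greedy one-to-one matching of detected to ground-truth event times."""
    truth_times = np.asarray(truth_times, dtype=float)
    det_times = np.asarray(det_times, dtype=float)
    used = np.zeros(len(det_times), dtype=bool)
    pairs = []
    for i, t in enumerate(truth_times):
        if det_times.size == 0:
            break
        d = np.abs(det_times - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_ms:
            used[j] = True
            pairs.append((i, j))
    return pairs, used
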