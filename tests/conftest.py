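import numpy as np
import pytest

from ibsurprise.fitting import IBCache
from ibsurprise.sequence import OddballSequence, generate_sequence

# study-regime grids shared by the recovery and significance tests
N_GRID = np.arange(2, 21)
BETA_GRID = np.geomspace(0.5, 100.0, 20)


@pytest.fixture(scope="session")
def ib_cache():
    """One IB-solution cache for the whole session (solutions are data-free)."""
    return IBCache()


@pytest.fixture(scope="session")
def study_cache(ib_cache):
    """Cache pre-populated on the study-regime grid."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ib_cache.populate(N_GRID, BETA_GRID)
    return ib_cache


@pytest.fixture
def protocol_sequence():
    """A session drawn under the experimental protocol conditions."""
    return generate_sequence([0.1, 0.2, 0.3, 0.4, 0.5], 240, seed=7)


def brute_force_counts(tones, block_id, N):
    """O(T*N) reference: oddballs among the N preceding same-block trials."""
    T = len(tones)
    values, valid = np.zeros(T), np.zeros(T, dtype=bool)
    for t in range(T):
        window = [
            i for i in range(max(t - N, 0), t) if block_id[i] == block_id[t]
        ]
        if t - N >= 0 and len(window) == N:
            valid[t] = True
            values[t] = sum(tones[i] for i in window)
    return values, valid


def make_sequence(tones, probs=None):
    tones = np.asarray(tones, dtype=np.int8)
    return OddballSequence(
        tones=tones,
        block_id=np.zeros(tones.size, dtype=int),
        block_probs=[0.5] if probs is None else probs,
    )
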