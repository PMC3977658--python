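import numpy as np
import pytest

import snpfoldscan as sfs


@pytest.fixture(scope="session", autouse=True)
def warm_kernels():
    """Trigger numba compilation once so individual tests time honestly."""
    seq = sfs.RnaSequence("warm", "GGGAAAACCC")
    sfs.global_pair_probabilities(seq)
    sfs.mfe_structure(seq)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def random_matrix_pair(n, rng, scale=0.1):
    """Two random upper-triangular 'probability' matrices of size n."""
    a = np.triu(rng.random((n, n)) * scale, k=1)
    b = np.triu(rng.random((n, n)) * scale, k=1)
    return sfs.PairProbMatrix(n, a), sfs.PairProbMatrix(n, b)


@pytest.fixture(scope="session")
def small_tables():
    """Small background tables (length 60, GC 0.5) shared across mode tests."""
    params = sfs.ModeParams(min_len=20, fixed_len=40)
    t1 = sfs.build_background_table(
        sfs.mode1_score_fn(params), sfs.DISTANCE, "mode1", 40, 11, [60], [0.5]
    )
    t2 = sfs.build_background_table(
        sfs.mode2_score_fn(params), sfs.DISTANCE, "mode2", 40, 12, [60], [0.5]
    )
    return params, {"mode1": t1, "mode2": t2}
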