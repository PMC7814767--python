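import numpy as np
import pytest

import envconn as ec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy6():
    """6-node, 2-band desk parcellation (alpha, low beta)."""
    return ec.toy_connectome(6, 2)


@pytest.fixture(scope="session")
def toy10():
    return ec.toy_connectome(10, 2)


@pytest.fixture(scope="session")
def planted_cohort(toy6):
    """Small cohort with one planted envelope correlation (r = 0.6)."""
    E = toy6.n_entries
    M = np.eye(E)
    p, q = toy6.flat_index(0, 0), toy6.flat_index(1, 0)
    M[p, q] = M[q, p] = 0.6
    spec = ec.CohortSpec(conn=toy6, n_group_a=3, n_group_b=3, duration=120.0,
                         target_corr=M, seed=42)
    signals, table, truth = ec.generate_cohort(spec)
    return dict(spec=spec, signals=signals, table=table, truth=truth,
                planted=(p, q, 0.6))
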