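import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    from musasi import default_model as _dm
    return _dm()


@pytest.fixture(scope="session")
def rod():
    from musasi import RodModel
    return RodModel()


@pytest.fixture(scope="session")
def symmetric_rod():
    from musasi import RodModel
    return RodModel(k_pos=2.0, k_neg=2.0, kBT=4.28)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_record(delta, x_a, s_off, lam_a, k_a, lam_T=1.0, lam_dot=0.0,
                n=None, N_F=16, N_M=38, B=1, dt=0.005, state=None):
    """Hand-built interval record for tension/stiffness unit tests.

    All per-entry arrays have shape (n, B*N_F*N_M); ``lam_T``/``lam_dot``
    are broadcast to (B,).
    """
    from musasi.montecarlo_engine import McIntervalRecord
    from musasi._kernels import NEDGE
    delta = np.asarray(delta, dtype=np.uint8)
    n = delta.shape[0] if n is None else n
    nt = delta.shape[1]
    assert nt == B * N_F * N_M
    z32 = lambda a: np.asarray(a, dtype=np.float32)
    if state is None:
        state = np.where(delta > 0, 4, 0).astype(np.int8)
    batch_of_mol = np.repeat(np.arange(B), N_F * N_M)
    return McIntervalRecord(
        n=n, dt=dt, t0=0.0,
        lam_T=np.broadcast_to(np.asarray(lam_T, float), (B,)).copy(),
        lam_dot=np.broadcast_to(np.asarray(lam_dot, float), (B,)).copy(),
        delta=delta, state=np.asarray(state, dtype=np.int8),
        x_a=z32(x_a), s_off=z32(s_off), lam_a=z32(lam_a),
        k_a=np.asarray(k_a, dtype=np.int32),
        edge_counts=np.zeros((B, NEDGE), dtype=np.int64),
        batch_of_mol=batch_of_mol, B=B, N_F=N_F, N_M=N_M,
        hsl0=950.0, max_rate_dt=0.0)


@pytest.fixture(scope="session")
def record_factory():
    return make_record
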