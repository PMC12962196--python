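import numpy as np
import pytest

from cordmap.protocols import DwiProtocol, QmtProtocol, ZspecProtocol


@pytest.fixture(scope="session")
def dwi_protocol():
    return DwiProtocol.default()


@pytest.fixture(scope="session")
def qmt_protocol():
    return QmtProtocol()


@pytest.fixture(scope="session")
def zspec_protocol():
    return ZspecProtocol()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_pd_tensor(rng, scale=1.0):
    """Random positive-definite 3x3 tensor with diffusivity-like eigenvalues."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    lam = rng.uniform(0.2, 2.0, 3) * scale
    return q @ np.diag(lam) @ q.T
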