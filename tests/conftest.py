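import numpy as np
import pytest

from morphoflow import make_cell_mesh
from morphoflow.model import ModelParams, MyosinSchedule


@pytest.fixture(scope="session")
def hex_mesh():
    """Regular hexagonal lattice: isotropic reference tissue."""
    return make_cell_mesh(100, 0.0, seed=1)


@pytest.fixture(scope="session")
def disordered_mesh():
    return make_cell_mesh(150, 0.3, seed=7)


@pytest.fixture(scope="session")
def schedule():
    return MyosinSchedule()  # t0=4, t1=5, t2=6 h APF


@pytest.fixture(scope="session")
def paper_regime_params():
    """Parameters in the physiological regime used throughout."""
    return ModelParams(tau_s=0.5, zeta_over_2K=-0.10, lam=0.10)


def q_oracle(corners):
    """Independent eigendecomposition oracle for the triangle tensor.

    Builds the map M from the unit-area equilateral reference and takes
    0.5*log of the unimodular left Cauchy-Green tensor through an
    explicit symmetric eigendecomposition.
    """
    a = (4.0 / np.sqrt(3.0)) ** 0.5
    R = np.array([[a, a / 2.0], [0.0, a * np.sqrt(3.0) / 2.0]])
    c = np.asarray(corners, dtype=float)
    e1, e2 = c[1] - c[0], c[2] - c[0]
    if e1[0] * e2[1] - e1[1] * e2[0] < 0:
        e1, e2 = e2, e1
    M = np.column_stack([e1, e2]) @ np.linalg.inv(R)
    B = M @ M.T / np.linalg.det(M)
    w, V = np.linalg.eigh(B)
    logB = V @ np.diag(np.log(w)) @ V.T
    Q = 0.5 * logB
    return Q[0, 0], Q[0, 1]
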