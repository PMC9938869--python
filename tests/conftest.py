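import numpy as np
import pytest

from oligoring import synthgen
from oligoring.structmodel import Structure


@pytest.fixture(scope="session")
def hexamer_closed():
    """Toy gate-covering hexamer template (narrow cytoplasmic gate)."""
    return synthgen.toy_hexamer_template("closed")


@pytest.fixture(scope="session")
def hexamer_open():
    """Toy pore-lining hexamer template (wide gate, identical anchor region)."""
    return synthgen.toy_hexamer_template("open")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def random_chain_structure(rng, n_res: int = 40, chain: str = "A") -> Structure:
    """Single-chain CA-trace with random-walk coordinates."""
    coords = np.cumsum(rng.normal(scale=2.0, size=(n_res, 3)), axis=0)
    aa = ["ALA", "GLY", "SER", "LEU", "VAL"]
    return Structure(
        serial=np.arange(1, n_res + 1),
        atom_name=np.array(["CA"] * n_res, dtype=object),
        element=np.array(["C"] * n_res, dtype=object),
        res_name=np.array([aa[i % 5] for i in range(n_res)], dtype=object),
        res_id=np.arange(1, n_res + 1),
        chain_id=np.array([chain] * n_res, dtype=object),
        coords=coords,
    )
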