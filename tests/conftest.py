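import numpy as np
import pytest

from collagen_roa.peptides import build_helix, parse_triplet_notation
from collagen_roa.synthetic import make_chiral_tensors, make_spring_system


@pytest.fixture(scope="session")
def small_helix():
    """Single-strand idealized PPII helix of (PHG)2P (7 residues)."""
    return build_helix("(PHG)2P", phi=-75.0, psi=150.0, n_chains=1)


@pytest.fixture(scope="session")
def spring_network():
    """Generic rigid 8-atom 3-D spring network with analytic Hessian."""
    return make_spring_system(8, k=1.0, seed=3, kind="network")


@pytest.fixture(scope="session")
def helix_tensors(small_helix):
    """Seeded chiral tensor set on the small helix."""
    return make_chiral_tensors(small_helix, roa_scale=1.0e-3, seed=5)


def random_rotation(rng):
    """Haar-ish random proper rotation from a random matrix QR."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
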