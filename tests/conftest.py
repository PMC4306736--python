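import numpy as np
import pytest
import scipy.sparse as sp

from multirank.chem_io import Molecule
from multirank.profile_encoding import build_scheme


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def table1_scheme():
    return build_scheme(3, [0])


@pytest.fixture
def table2_scheme():
    return build_scheme(3, [0, 1])


def permute_molecule(mol: Molecule, perm) -> Molecule:
    """Relabel atoms by a permutation (perm[i] = new index of old atom i)."""
    inv = [0] * len(perm)
    for old, new in enumerate(perm):
        inv[new] = old
    atoms = tuple(mol.atoms[inv[new]] for new in range(len(perm)))
    bonds = tuple((perm[i], perm[j], order) for i, j, order in mol.bonds)
    return Molecule(mol.id, atoms, bonds, mol.provenance, mol.props)


def random_rank_instance(rng, l=40, dim=8, R=3, density=0.5):
    """A random sparse dataset with at least one instance per score level."""
    X = sp.random(l, dim, density=density, random_state=np.random.RandomState(
        int(rng.integers(2**31))), format="csr")
    scores = rng.integers(0, R, size=l)
    scores[:R] = np.arange(R)  # every level present
    return X, scores


@pytest.fixture
def rank_instance(rng):
    return random_rank_instance(rng)
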