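import numpy as np
import pytest

from eimsim.chem_data import Molecule
from eimsim.fixtures import make_cascade_chain, make_weak_bond_dimer
from eimsim.providers import PairMorse, SurrogatePESParams, SurrogateProvider


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def weak_dimer():
    return make_weak_bond_dimer()


@pytest.fixture
def chain3():
    return make_cascade_chain(3)


@pytest.fixture
def hf_diatomic():
    """A bound H–F diatomic at its Morse minimum (covalent-radius sum)."""
    mol = Molecule(
        ["H", "F"],
        np.array([[0.0, 0.0, 0.0], [0.88, 0.0, 0.0]]),
        np.zeros((2, 3)),
    )
    params = SurrogatePESParams(
        pair_overrides={frozenset(("H", "F")): PairMorse(4.0, 2.0)},
        charge_softening=0.0,
    )
    return mol, SurrogateProvider(mol, params)


def random_molecule(rng, n_atoms=5, symbols=("C", "H", "O", "N")):
    """Random well-separated geometry for I/O and invariance tests."""
    syms = [symbols[i] for i in rng.integers(0, len(symbols), n_atoms)]
    coords = rng.uniform(-4.0, 4.0, (n_atoms, 3))
    # push apart any overlapping pair
    for _ in range(50):
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] > 0.5:
            break
        coords[i] += rng.normal(0, 1.0, 3)
    vel = rng.normal(0.0, 5e-3, (n_atoms, 3))
    return Molecule(syms, coords, vel)
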