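import numpy as np
import pytest

from molray.fixtures import (
    make_toy_pdb_text,
    single_atom_system,
    water_system,
)
from molray.model import Atom, MoleculeSystem, assign_radii


@pytest.fixture
def water():
    return water_system()


@pytest.fixture
def carbon():
    return single_atom_system("C")


@pytest.fixture
def minimal_pdb_text():
    return make_toy_pdb_text("minimal")


@pytest.fixture
def two_chain_system():
    """5 atoms on chain A, 3 on chain B."""
    atoms = []
    for k in range(5):
        atoms.append(
            Atom(index=k, name="CA", element="C", position=np.array([k * 3.8, 0.0, 0.0]),
                 chain_id="A", residue_seq=k + 1)
        )
    for k in range(3):
        atoms.append(
            Atom(index=5 + k, name="O", element="O", position=np.array([k * 3.8, 10.0, 0.0]),
                 chain_id="B", residue_seq=k + 1)
        )
    return assign_radii(MoleculeSystem(atoms=atoms))


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
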