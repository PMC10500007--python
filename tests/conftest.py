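import numpy as np
import pytest

from graftkit._build import build_backbone
from graftkit.fixtures import coords_to_structure
from graftkit.structio import AtomRecord, Residue, Structure


def make_residue(chain_id, number, name, atom_positions, icode=""):
    """Residue from a {atom name: position} mapping; element = first letter."""
    atoms = [
        AtomRecord(an, an[0], np.asarray(pos, float)) for an, pos in atom_positions.items()
    ]
    return Residue(chain_id, number, icode, name, atoms)


@pytest.fixture
def helix_structure() -> Structure:
    """A 12-residue ideal alpha helix (phi -57, psi -47)."""
    coords = build_backbone(np.full(12, -57.0), np.full(12, -47.0))
    return coords_to_structure(coords, structure_id="helix")


@pytest.fixture
def strand_structure() -> Structure:
    """A 20-residue ideal beta strand (phi -120, psi 130)."""
    coords = build_backbone(np.full(20, -120.0), np.full(20, 130.0))
    return coords_to_structure(coords, structure_id="strand")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
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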