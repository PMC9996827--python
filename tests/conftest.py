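import numpy as np
import pytest

from rborient.scattering import load_residue_table
from rborient.structure import ProteinModel
from rborient.synthetic import SyntheticSpec, make_bead_protein


@pytest.fixture(scope="session")
def residue_table():
    return load_residue_table()


def model_from_positions(positions, table, code="ALA", name="toy"):
    positions = np.asarray(positions, dtype=float)
    return ProteinModel(kinds=[table[code]] * len(positions),
                        positions=positions, name=name)


@pytest.fixture(scope="session")
def tiny_model(residue_table):
    """Eight beads at slightly perturbed cube corners."""
    rng = np.random.default_rng(11)
    corners = np.array([[x, y, z] for x in (-8.0, 8.0) for y in (-12.0, 12.0)
                        for z in (-5.0, 5.0)])
    return model_from_positions(corners + rng.normal(0, 0.3, corners.shape),
                                residue_table)


@pytest.fixture(scope="session")
def ellipsoid_model():
    return make_bead_protein(SyntheticSpec(
        shape="ellipsoid", n_beads=200, extents=(90.0, 60.0, 40.0), seed=4))


@pytest.fixture(scope="session")
def sphere_model():
    return make_bead_protein(SyntheticSpec(
        shape="sphere", n_beads=200, extents=(60.0, 60.0, 60.0), seed=5))


@pytest.fixture(scope="session")
def mirror_model(residue_table):
    """A cloud symmetric under every coordinate sign flip.

    All beads share one residue kind, so every rotated z-distribution is
    exactly invariant under the 180-degree orientation pair map.
    """
    rng = np.random.default_rng(21)
    octant = rng.uniform([2, 3, 1], [30, 40, 15], size=(40, 3))
    images = [octant * np.array(s) for s in
              [(sx, sy, sz) for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]]
    return model_from_positions(np.vstack(images), residue_table)


@pytest.fixture(scope="session")
def y_model():
    return make_bead_protein(SyntheticSpec(
        shape="y", n_beads=300, extents=(90.0, 60.0, 40.0), seed=7))
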