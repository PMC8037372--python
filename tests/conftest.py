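import numpy as np
import pytest

from hbshare.constants import ANGSTROM_TO_BOHR
from hbshare.qtaim import GridField, promolecular_field
from hbshare.synthetic_data import build_toy_active_site, write_promolecular_cube
from hbshare.trajectory_io import AtomRecord, Frame, Trajectory


def make_trajectory(coord_list, elements=None, box=None, dt=10.0, residues=None):
    """Small helper: build a Trajectory from a list of (N,3) coordinate arrays."""
    coord_list = [np.asarray(c, dtype=float) for c in coord_list]
    n = coord_list[0].shape[0]
    elements = elements or ["C"] * n
    atoms = []
    for i in range(n):
        rname, rid = (residues[i] if residues else ("MOL", 1))
        atoms.append(AtomRecord(i, elements[i], elements[i], rname, rid))
    frames = [
        Frame(k, k * dt, c, box=None if box is None else np.asarray(box, dtype=float))
        for k, c in enumerate(coord_list)
    ]
    return Trajectory(atoms=atoms, frames=frames)


@pytest.fixture(scope="session")
def toy_site():
    return build_toy_active_site()


@pytest.fixture(scope="session")
def oh_fields(tmp_path_factory):
    """Analytic promolecular O-H field and its 0.05-bohr grid counterpart."""
    field = promolecular_field([("O", (0.0, 0.0, 0.0)), ("H", (0.96, 0.0, 0.0))])
    path = tmp_path_factory.mktemp("cube") / "oh.cube"
    grid = write_promolecular_cube(field, spacing=0.05, padding=2.0, path=path)
    return field, GridField(grid), path


@pytest.fixture
def oh_midpoint_seed():
    return np.array([0.48, 0.0, 0.0]) * ANGSTROM_TO_BOHR
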