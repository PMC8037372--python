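"""File-format round trips, parse errors, and the selection grammar."""

import numpy as np
import pytest

from hbshare.constants import ANGSTROM_TO_BOHR
from hbshare.errors import ParseError, QueryError, StructureError
from hbshare.trajectory_io import (
    DensityGrid,
    read_cube,
    read_pdb_models,
    read_xyz_trajectory,
    select,
    write_cube,
    write_pdb_models,
    write_xyz_trajectory,
)

from conftest import make_trajectory


XYZ_TWO_FRAMES = """3
frame=0 time=0.0
O 0.0 0.0 0.0
H 0.96 0.0 0.0
H -0.24 0.93 0.0
3
frame=1 time=10.0
O 0.0 0.0 0.1
H 0.97 0.0 0.0
H -0.24 0.93 0.05
"""


class TestXyz:
    def test_roundtrip(self, tmp_path):
        src = tmp_path / "a.xyz"
        src.write_text(XYZ_TWO_FRAMES)
        traj = read_xyz_trajectory(src)
        assert traj.n_frames == 2 and traj.n_atoms == 3
        dst = tmp_path / "b.xyz"
        write_xyz_trajectory(traj, dst)
        back = read_xyz_trajectory(dst)
        assert np.allclose(back.coordinate_array(), traj.coordinate_array(), atol=1e-6)
        assert [a.element for a in back.atoms] == [a.element for a in traj.atoms]
        assert np.allclose(back.times, traj.times)

    def test_time_token(self, tmp_path):
        src = tmp_path / "a.xyz"
        src.write_text("1\nfirst\nO 0 0 0\n1\ntime=10.0\nO 1 0 0\n")
        traj = read_xyz_trajectory(src, default_dt=2.0)
        assert traj.frames[0].time == 0.0  # frame_index * default_dt
        assert traj.frames[1].time == 10.0

    def test_short_block_is_parse_error(self, tmp_path):
        src = tmp_path / "bad.xyz"
        src.write_text("4\ncomment\nO 0 0 0\nH 1 0 0\nH 0 1 0\n")
        with pytest.raises(ParseError, match="declares 4 atoms"):
            read_xyz_trajectory(src)

    def test_bad_count_line_names_line_number(self, tmp_path):
        src = tmp_path / "bad.xyz"
        src.write_text("zzz\ncomment\nO 0 0 0\n")
        with pytest.raises(ParseError, match="line 1"):
            read_xyz_trajectory(src)

    def test_inconsistent_atom_count_across_blocks(self, tmp_path):
        src = tmp_path / "bad.xyz"
        src.write_text("1\nc\nO 0 0 0\n2\nc\nO 0 0 0\nH 1 0 0\n")
        with pytest.raises(StructureError):
            read_xyz_trajectory(src)


PDB_SINGLE = """\
ATOM      1  OE2 GLU A  46       2.560   0.000   0.000  1.00  0.00           O
ATOM      2  HE2 GLU A  46       1.361   0.160   0.000  1.00  0.00           H
HETATM    3  O4' PCA A  69       0.000   0.000   0.000  1.00  0.00           O
ATOM      4  HH  TYR A  42      -0.980   1.328   0.000  1.00  0.00           H
ATOM      5  OH  TYR A  42      -1.065   2.284   0.000  1.00  0.00           O
END
"""


class TestPdb:
    def test_single_model(self, tmp_path):
        src = tmp_path / "a.pdb"
        src.write_text(PDB_SINGLE)
        traj = read_pdb_models(src)
        assert traj.n_frames == 1 and traj.n_atoms == 5
        assert [a.index for a in traj.atoms] == list(range(5))
        assert traj.atoms[0].residue_name == "GLU"
        assert traj.atoms[0].residue_id == 46
        assert traj.atoms[2].element == "O"

    def test_hetatm_residue_selectable(self, tmp_path):
        src = tmp_path / "a.pdb"
        src.write_text(PDB_SINGLE)
        traj = read_pdb_models(src)
        assert select(traj, "residue_name PCA") == [2]

    def test_multi_model_shares_atom_table(self, tmp_path):
        blocks = []
        for k in range(3):
            body = PDB_SINGLE.replace("END\n", "").replace(
                "2.560", f"{2.56 + 0.01 * k:.3f}"
            )
            blocks.append(f"MODEL     {k + 1}\n{body}ENDMDL\n")
        src = tmp_path / "m.pdb"
        src.write_text("".join(blocks) + "END\n")
        traj = read_pdb_models(src)
        assert traj.n_frames == 3 and traj.n_atoms == 5
        assert traj.frames[2].coordinates[0, 0] == pytest.approx(2.58, abs=1e-3)

    def test_roundtrip_fixed_width_precision(self, tmp_path, toy_site):
        dst = tmp_path / "site.pdb"
        write_pdb_models(toy_site, dst)
        back = read_pdb_models(dst)
        assert np.allclose(
            back.coordinate_array(), toy_site.coordinate_array(), atol=1e-3
        )
        assert [a.residue_id for a in back.atoms] == [
            a.residue_id for a in toy_site.atoms
        ]

    def test_no_atoms_is_structure_error(self, tmp_path):
        src = tmp_path / "empty.pdb"
        src.write_text("REMARK nothing here\nEND\n")
        with pytest.raises((StructureError, ParseError)):
            read_pdb_models(src)


def _constant_grid(value=1.0, n=2, spacing=1.0):
    return DensityGrid(
        origin=np.zeros(3),
        axes=np.diag([spacing] * 3),
        counts=[n, n, n],
        values=np.full((n, n, n), value),
        atom_numbers=np.array([8]),
        atom_charges=np.array([8.0]),
        atom_positions=np.zeros((1, 3)),
    )


class TestCube:
    def test_constant_cube_trilinear_center(self, tmp_path):
        path = tmp_path / "c.cube"
        write_cube(_constant_grid(), path)
        grid = read_cube(path)
        assert grid.interpolate([0.5, 0.5, 0.5]) == pytest.approx(1.0)

    def test_roundtrip_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = _constant_grid()
        grid.values = rng.uniform(0.0, 2.0, size=(2, 2, 2))
        p1, p2 = tmp_path / "a.cube", tmp_path / "b.cube"
        write_cube(grid, p1)
        g1 = read_cube(p1)
        write_cube(g1, p2)
        g2 = read_cube(p2)
        assert np.allclose(g1.values, g2.values, atol=1e-12, rtol=0)
        assert np.allclose(g1.origin, g2.origin, atol=1e-12)
        assert np.allclose(g1.axes, g2.axes, atol=1e-12)

    def test_angstrom_convention_converted(self, tmp_path):
        # negative voxel counts mark Å axes; 0.52917721 Å steps must read back
        # as exactly 1 bohr
        path = tmp_path / "ang.cube"
        step = 0.52917721
        lines = [
            "comment", "comment",
            "    1  0.0  0.0  0.0",
            f"   -2  {step}  0.0  0.0",
            f"   -2  0.0  {step}  0.0",
            f"   -2  0.0  0.0  {step}",
            "    8  8.0  0.0  0.0  0.0",
        ]
        vals = " ".join(["1.0"] * 8)
        path.write_text("\n".join(lines) + "\n" + vals + "\n")
        grid = read_cube(path)
        assert np.allclose(np.diag(grid.axes), 1.0, atol=1e-9)

    def test_truncated_values_reports_counts(self, tmp_path):
        path = tmp_path / "t.cube"
        write_cube(_constant_grid(), path)
        text = path.read_text().splitlines()
        path.write_text("\n".join(text[:-1]) + "\n")
        with pytest.raises(ParseError, match="expected 8 values"):
            read_cube(path)


@pytest.fixture
def within_fixture():
    # chromophore atom at origin plus atoms at 4.9, 5.0 and 5.1 Å
    coords = [[0, 0, 0], [4.9, 0, 0], [5.0, 0, 0], [5.1, 0, 0]]
    return make_trajectory(
        [np.array(coords)],
        elements=["O", "N", "N", "N"],
        residues=[("PCA", 69), ("ALA", 1), ("ALA", 2), ("ALA", 3)],
    )


class TestSelect:
    def test_element(self, toy_site):
        got = select(toy_site, "element O")
        assert got == [i for i, a in enumerate(toy_site.atoms) if a.element == "O"]

    def test_within_inclusive_boundary(self, within_fixture):
        got = select(within_fixture, "within 5.0 of residue_name PCA")
        # the 4.9 Å and exactly-5.0 Å atoms are kept (d <= R), 5.1 Å is not
        assert got == [0, 1, 2]

    def test_within_matches_brute_force(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(-6, 6, size=(30, 3))
        elements = ["O"] * 5 + ["C"] * 25
        traj = make_trajectory([coords], elements=elements)
        got = select(traj, "within 3.0 of element O")
        dmat = np.linalg.norm(coords[:, None] - coords[None, :5], axis=-1)
        expected = sorted(int(i) for i in np.nonzero(dmat.min(axis=1) <= 3.0)[0])
        assert got == expected

    def test_within_min_image(self):
        coords = np.array([[0.5, 0.5, 0.5], [9.5, 0.5, 0.5]])
        traj = make_trajectory([coords], elements=["O", "N"], box=[10, 10, 10])
        assert select(traj, "within 1.5 of element O") == [0, 1]

    def test_boolean_combinators(self, toy_site):
        got = select(toy_site, "residue_name TYR and element O")
        assert got == [4]
        got = select(toy_site, "element H or residue_name PCA")
        assert got == [1, 2, 3]
        got = select(toy_site, "not element H")
        assert got == [0, 2, 4]

    def test_empty_result_is_empty_list(self, toy_site):
        assert select(toy_site, "element S") == []

    def test_idempotent_and_sorted(self, toy_site):
        q = "element O or element O"
        once = select(toy_site, q)
        assert once == sorted(set(once))
        assert once == select(toy_site, "element O")

    @pytest.mark.parametrize("bad", ["chain A", "within x of element O", "element"])
    def test_bad_query(self, toy_site, bad):
        with pytest.raises(QueryError):
            select(toy_site, bad)
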