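"""Trajectory and volumetric-density I/O, atom selections, unit handling.

Containers
----------
:class:`AtomRecord`, :class:`Frame`, :class:`Trajectory` hold multi-frame
coordinate data in Å/fs with one shared atom table.  :class:`DensityGrid`
holds a scalar electron density on a regular grid in atomic units
(bohr, electrons/bohr³) regardless of the convention of the file it came from.

Formats
-------
* multi-frame XYZ (``N`` / comment / ``N`` element-x-y-z lines); an optional
  ``time=<fs>`` token in the comment carries the frame time,
* PDB (ATOM/HETATM with optional MODEL/ENDMDL), via biotite,
* Gaussian cube, both sign conventions (negative counts / negative atom
  count signal the Å + extra-field dialect).

Selections
----------
:func:`select` evaluates a small query grammar (``element``, ``name``,
``residue_name``, ``residue_id``, ``water``, ``within R of <expr>``, with
``and``/``or``/``not`` and parentheses).  ``within`` uses the minimum
atom-atom distance with an inclusive boundary (d <= R) and the minimum-image
convention when the frame has a box.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .constants import ANGSTROM_TO_BOHR, DEFAULT_FRAME_DT_FS
from .errors import GeometryError, GridSizeError, ParseError, QueryError, StructureError

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "DensityGrid",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_pdb_models",
    "write_pdb_models",
    "read_cube",
    "write_cube",
    "select",
    "minimum_image_displacement",
]

_WATER_RESIDUES = frozenset({"WAT", "HOH", "TIP3", "SOL", "SPC", "TIP"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared atom table (0-based contiguous index)."""

    index: int
    name: str
    element: str
    residue_name: str = "MOL"
    residue_id: int = 1

    def __post_init__(self):
        if not self.element:
            raise StructureError(f"atom {self.index}: empty element")


@dataclass
class Frame:
    """A single snapshot: N×3 coordinates in Å, time in fs, optional box."""

    frame_index: int
    time: float
    coordinates: np.ndarray
    box: Optional[np.ndarray] = None  # 3 orthorhombic edge lengths, Å

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError(
                f"frame {self.frame_index}: coordinates must be N×3, "
                f"got {self.coordinates.shape}"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise StructureError(
                    f"frame {self.frame_index}: box must be 3 positive edge lengths"
                )

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """An ordered list of frames sharing one atom table."""

    atoms: list[AtomRecord]
    frames: list[Frame]

    def __post_init__(self):
        if not self.frames:
            raise StructureError("trajectory must contain at least one frame")
        n = len(self.atoms)
        for fr in self.frames:
            if fr.n_atoms != n:
                raise StructureError(
                    f"frame {fr.frame_index} has {fr.n_atoms} atoms, "
                    f"atom table has {n}"
                )
        indices = [a.index for a in self.atoms]
        if indices != list(range(n)):
            raise StructureError("atom indices must be contiguous from 0")
        times = [fr.time for fr in self.frames]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise StructureError("frame times must be non-decreasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def coordinate_array(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_atoms, 3) in Å."""
        return np.stack([fr.coordinates for fr in self.frames])


@dataclass
class DensityGrid:
    """Scalar field on a regular grid, all quantities in atomic units."""

    origin: np.ndarray          # (3,) bohr
    axes: np.ndarray            # (3,3) step vectors, bohr (rows)
    counts: np.ndarray          # (3,) ints, >= 2
    values: np.ndarray          # (nx, ny, nz) electrons/bohr^3
    atom_numbers: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    atom_charges: np.ndarray = field(default_factory=lambda: np.zeros(0))
    atom_positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))  # bohr

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.counts < 2):
            raise StructureError("density grid needs at least 2 points per axis")
        if tuple(self.counts) != self.values.shape:
            raise StructureError(
                f"value array shape {self.values.shape} does not match counts "
                f"{tuple(self.counts)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise StructureError("density grid contains non-finite values")

    def grid_vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis coordinate arrays (bohr); requires axis-aligned steps."""
        if not np.allclose(self.axes, np.diag(np.diag(self.axes)), atol=1e-12):
            raise StructureError("grid axes must be axis-aligned (orthogonal grid)")
        steps = np.diag(self.axes)
        return tuple(
            self.origin[i] + steps[i] * np.arange(self.counts[i]) for i in range(3)
        )

    def interpolate(self, point: np.ndarray) -> float:
        """Trilinear interpolation of the density at ``point`` (bohr)."""
        xs, ys, zs = self.grid_vectors()
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator((xs, ys, zs), self.values, method="linear")
        return float(interp(np.asarray(point, dtype=float))[0])


# --------------------------------------------------------------------------
# minimum image
# --------------------------------------------------------------------------

def minimum_image_displacement(delta: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    """Wrap displacement vectors into the central orthorhombic image."""
    delta = np.asarray(delta, dtype=float)
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


# --------------------------------------------------------------------------
# XYZ
# --------------------------------------------------------------------------

_TIME_RE = re.compile(r"time\s*=\s*([-+0-9.eEdD]+)")


def read_xyz_trajectory(path, default_dt: float = DEFAULT_FRAME_DT_FS) -> Trajectory:
    """Read a multi-frame XYZ file.

    Each block is ``N`` / comment / ``N`` element-x-y-z lines.  A ``time=<fs>``
    token in the comment sets the frame time; otherwise
    ``frame_index * default_dt`` is assigned.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    elements_ref: Optional[list[str]] = None
    lineno = 0
    frame_index = 0
    while lineno < len(lines):
        if not lines[lineno].strip():  # tolerate trailing blank lines
            lineno += 1
            continue
        try:
            natoms = int(lines[lineno].split()[0])
        except (ValueError, IndexError):
            raise ParseError(
                f"{path}: line {lineno + 1}: expected atom count, got "
                f"{lines[lineno]!r}"
            ) from None
        if lineno + 1 >= len(lines):
            raise ParseError(f"{path}: line {lineno + 2}: missing comment line")
        comment = lines[lineno + 1]
        m = _TIME_RE.search(comment)
        time = float(m.group(1).replace("D", "E").replace("d", "e")) if m else (
            frame_index * default_dt
        )
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            ln = lineno + 2 + k
            if ln >= len(lines) or not lines[ln].strip() or _looks_like_count(lines[ln]):
                raise ParseError(
                    f"{path}: line {lineno + 1}: block declares {natoms} atoms "
                    f"but only {k} coordinate lines found"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {ln + 1}: expected 'element x y z', got "
                    f"{lines[ln]!r}"
                )
            elements.append(parts[0])
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(
                    f"{path}: line {ln + 1}: unparsable coordinates in "
                    f"{lines[ln]!r}"
                ) from None
        if elements_ref is None:
            elements_ref = elements
        elif elements != elements_ref or natoms != len(elements_ref):
            raise StructureError(
                f"{path}: frame {frame_index} atom list differs from frame 0"
            )
        frames.append(Frame(frame_index, time, coords))
        frame_index += 1
        lineno += 2 + natoms
    if not frames:
        raise StructureError(f"{path}: no frames found")
    atoms = [
        AtomRecord(index=i, name=el, element=el) for i, el in enumerate(elements_ref)
    ]
    return Trajectory(atoms=atoms, frames=frames)


def _looks_like_count(line: str) -> bool:
    parts = line.split()
    return len(parts) == 1 and parts[0].lstrip("+-").isdigit()


def write_xyz_trajectory(traj: Trajectory, path) -> None:
    """Write a multi-frame XYZ file with ``time=<fs>`` comment tokens."""
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame={fr.frame_index} time={fr.time:.6f}\n")
            for atom, xyz in zip(traj.atoms, fr.coordinates):
                fh.write(
                    f"{atom.element:<4s} {xyz[0]:18.10f} {xyz[1]:18.10f} "
                    f"{xyz[2]:18.10f}\n"
                )


# --------------------------------------------------------------------------
# PDB (via biotite)
# --------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def read_pdb_models(path) -> Trajectory:
    """Read a single- or multi-model PDB file into a Trajectory.

    One frame per MODEL (a single frame if the file has none); residue
    names/ids are preserved and serial numbers remapped to 0-based contiguous
    indices.  Elements come from the PDB element columns, falling back to the
    first alphabetic character of the atom name.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises plain ValueError/InvalidFileError
        raise ParseError(f"{path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    if stack.array_length() == 0:
        raise StructureError(f"{path}: no ATOM/HETATM records")
    atoms = []
    for i in range(stack.array_length()):
        element = str(stack.element[i]).strip().capitalize()
        if not element:
            element = _element_from_name(str(stack.atom_name[i]))
        if not element:
            raise ParseError(
                f"{path}: atom {i}: cannot deduce element from name "
                f"{stack.atom_name[i]!r}"
            )
        atoms.append(
            AtomRecord(
                index=i,
                name=str(stack.atom_name[i]),
                element=element,
                residue_name=str(stack.res_name[i]),
                residue_id=int(stack.res_id[i]),
            )
        )
    box = None
    if stack.box is not None:
        diag = np.diagonal(stack.box[0])
        if np.all(diag > 0):
            box = np.array(diag, dtype=float)
    frames = [
        Frame(k, k * DEFAULT_FRAME_DT_FS, np.array(stack.coord[k], dtype=float), box=box)
        for k in range(stack.stack_depth())
    ]
    return Trajectory(atoms=atoms, frames=frames)


_HET_RESIDUES = frozenset({"PCA", "HOH", "WAT", "TIP3", "SOL"})


def write_pdb_models(traj: Trajectory, path) -> None:
    """Write a Trajectory as a (multi-)MODEL PDB file via biotite."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n, m = traj.n_atoms, traj.n_frames
    stack = struc.AtomArrayStack(m, n)
    stack.coord[:] = traj.coordinate_array()
    stack.atom_name = np.array([a.name for a in traj.atoms])
    stack.element = np.array([a.element.upper() for a in traj.atoms])
    stack.res_name = np.array([a.residue_name for a in traj.atoms])
    stack.res_id = np.array([a.residue_id for a in traj.atoms])
    stack.chain_id = np.array(["A"] * n)
    stack.hetero = np.array([a.residue_name in _HET_RESIDUES for a in traj.atoms])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# --------------------------------------------------------------------------
# Gaussian cube
# --------------------------------------------------------------------------

def read_cube(path) -> DensityGrid:
    """Read a Gaussian cube file into atomic units.

    Handles both sign conventions: a negative voxel count marks an axis
    written in Å, and a negative atom count marks the dialect with an extra
    data-set id line after the atom block (also treated as Å).  Output is
    always bohr / electrons-per-bohr³.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path}: cube header truncated ({len(lines)} lines)")
    try:
        head = lines[2].split()
        natoms_raw = int(head[0])
        origin = np.array([float(x) for x in head[1:4]])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: line 3: bad atom-count/origin line") from None
    angstrom_mode = natoms_raw < 0
    natoms = abs(natoms_raw)
    counts = np.empty(3, dtype=int)
    axes = np.empty((3, 3))
    axis_angstrom = np.zeros(3, dtype=bool)
    for i in range(3):
        parts = lines[3 + i].split()
        try:
            c = int(parts[0])
            axes[i] = [float(x) for x in parts[1:4]]
        except (ValueError, IndexError):
            raise ParseError(f"{path}: line {4 + i}: bad axis line") from None
        axis_angstrom[i] = c < 0
        counts[i] = abs(c)
    numbers = np.empty(natoms, dtype=int)
    charges = np.empty(natoms)
    positions = np.empty((natoms, 3))
    for k in range(natoms):
        parts = lines[6 + k].split()
        try:
            numbers[k] = int(float(parts[0]))
            charges[k] = float(parts[1])
            positions[k] = [float(x) for x in parts[2:5]]
        except (ValueError, IndexError):
            raise ParseError(f"{path}: line {7 + k}: bad atom line") from None
    data_start = 6 + natoms
    if natoms_raw < 0:
        data_start += 1  # DSET_IDS line of the orbital-cube dialect
    vals: list[float] = []
    for ln in lines[data_start:]:
        vals.extend(float(t) for t in ln.split())
    expected = int(np.prod(counts))
    if len(vals) != expected:
        raise ParseError(
            f"{path}: value section: expected {expected} values, found {len(vals)}"
        )
    values = np.array(vals).reshape(tuple(counts))
    # unit normalization: any Å marker converts lengths to bohr
    to_bohr = np.where(axis_angstrom | angstrom_mode, ANGSTROM_TO_BOHR, 1.0)
    axes = axes * to_bohr[:, None]
    if angstrom_mode or axis_angstrom.any():
        origin = origin * ANGSTROM_TO_BOHR
        positions = positions * ANGSTROM_TO_BOHR
    return DensityGrid(
        origin=origin,
        axes=axes,
        counts=counts,
        values=values,
        atom_numbers=numbers,
        atom_charges=charges,
        atom_positions=positions,
    )


def write_cube(grid: DensityGrid, path, comment: str = "density") -> None:
    """Write a cube file in the canonical bohr / positive-count convention."""
    if np.prod(grid.counts) > 1e8:
        raise GridSizeError("refusing to write a cube with more than 1e8 points")
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("written by hbshare\n")
        o = grid.origin
        fh.write(f"{len(grid.atom_numbers):5d} {o[0]:17.10e} {o[1]:17.10e} {o[2]:17.10e}\n")
        for i in range(3):
            a = grid.axes[i]
            fh.write(
                f"{grid.counts[i]:5d} {a[0]:17.10e} {a[1]:17.10e} {a[2]:17.10e}\n"
            )
        for z, q, pos in zip(grid.atom_numbers, grid.atom_charges, grid.atom_positions):
            fh.write(
                f"{z:5d} {q:17.10e} {pos[0]:17.10e} {pos[1]:17.10e} {pos[2]:17.10e}\n"
            )
        flat = grid.values.reshape(-1)
        for start in range(0, flat.size, 6):
            fh.write(" ".join(f"{v:20.13e}" for v in flat[start:start + 6]) + "\n")


# --------------------------------------------------------------------------
# selections
# --------------------------------------------------------------------------

_FIELD_ALIASES = {
    "element": "element",
    "name": "name",
    "residue_name": "residue_name",
    "resname": "residue_name",
    "residue_id": "residue_id",
    "resid": "residue_id",
}


class _SelectionParser:
    """Recursive-descent parser for the selection mini-grammar."""

    def __init__(self, tokens: list[str], traj: Trajectory, frame: int):
        self.tokens = tokens
        self.pos = 0
        self.traj = traj
        self.frame = traj.frames[frame]

    def _peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _pop(self) -> str:
        tok = self._peek()
        if tok is None:
            raise QueryError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self._or_expr()
        if self._peek() is not None:
            raise QueryError(f"unexpected token {self._peek()!r}")
        return mask

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self._peek() == "or":
            self._pop()
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._unary()
        while self._peek() == "and":
            self._pop()
            mask = mask & self._unary()
        return mask

    def _unary(self) -> np.ndarray:
        if self._peek() == "not":
            self._pop()
            return ~self._unary()
        return self._primary()

    def _primary(self) -> np.ndarray:
        tok = self._pop()
        if tok == "(":
            mask = self._or_expr()
            if self._pop() != ")":
                raise QueryError("unbalanced parentheses")
            return mask
        if tok == "within":
            try:
                radius = float(self._pop())
            except ValueError:
                raise QueryError("'within' must be followed by a distance") from None
            if self._pop() != "of":
                raise QueryError("'within <R>' must be followed by 'of'")
            sub = self._unary()
            return self._within(sub, radius)
        if tok == "water":
            names = np.array([a.residue_name for a in self.traj.atoms])
            return np.isin(names, list(_WATER_RESIDUES))
        if tok in _FIELD_ALIASES:
            fieldname = _FIELD_ALIASES[tok]
            value = self._pop()
            if fieldname == "residue_id":
                try:
                    ival = int(value)
                except ValueError:
                    raise QueryError(f"residue_id needs an integer, got {value!r}") from None
                return np.array([a.residue_id == ival for a in self.traj.atoms])
            return np.array(
                [getattr(a, fieldname) == value for a in self.traj.atoms]
            )
        raise QueryError(f"unknown selection token {tok!r}")

    def _within(self, sub: np.ndarray, radius: float) -> np.ndarray:
        if not sub.any():
            return np.zeros(self.traj.n_atoms, dtype=bool)
        coords = self.frame.coordinates
        ref = coords[sub]
        delta = coords[:, None, :] - ref[None, :, :]
        delta = minimum_image_displacement(delta, self.frame.box)
        dmin = np.sqrt((delta**2).sum(axis=-1)).min(axis=1)
        return dmin <= radius  # inclusive boundary


def select(traj: Trajectory, query: str, frame: int = 0) -> list[int]:
    """Evaluate a selection expression; returns sorted unique atom indices.

    ``within R of <expr>`` measures the minimum atom-atom distance against the
    sub-selection in the given reference frame (default frame 0), inclusive of
    the boundary (d <= R), with the minimum-image convention when the frame
    has a box.  An empty result is an empty list, not an error.
    """
    if not (0 <= frame < traj.n_frames):
        raise QueryError(f"reference frame {frame} out of range")
    tokens = re.findall(r"\(|\)|[^\s()]+", query)
    if not tokens:
        raise QueryError("empty selection expression")
    mask = _SelectionParser(tokens, traj, frame).parse()
    return [int(i) for i in np.nonzero(mask)[0]]
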