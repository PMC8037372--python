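"""Synthetic inputs emulating the PYP dark-state study conditions.

The raw classical-MD and QM/MM trajectories behind the published analysis are
not public, so every downstream stage is exercised on generated data whose
summary statistics match the reported ones:

* a toy five-atom active site (O_E46, H1, O_pCA, H2, O_Y42) embedded in 3-D
  so the six published neutron-structure distances hold exactly,
* a QM/MM-like trajectory whose proton-sharing coordinate ξ follows
  N(μ = −0.06 Å, σ = 0.14 Å) (i.i.d. draws or an Ornstein–Uhlenbeck process
  for sub-picosecond recrossing dynamics), emitted as coordinates so the
  whole pipeline runs on geometry rather than on pre-made ξ values,
* classical-MD-like independent Gaussian distance channels
  (H···O_pCA: 1.79 ± 0.07 Å for the Y42 hydrogen, 1.71 ± 0.05 Å for the E46
  hydrogen, O_Y42–H: 1.00 ± 0.04 Å),
* uniform / dry-pocket water-oxygen boxes for RDF tests,
* promolecular densities written as cube files.

Every generator is a pure function of (parameters, seed); no global RNG state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional

import numpy as np

from .constants import BOHR_TO_ANGSTROM
from .errors import FeasibilityError, GridSizeError, PackingError, ParameterError
from .proton_coordinate import HBondTriplet, XiSeries, xi_series
from .qtaim import PromolecularModel
from .trajectory_io import AtomRecord, DensityGrid, Frame, Trajectory, write_cube

__all__ = [
    "GeneratorPreset",
    "PRESETS",
    "build_toy_active_site",
    "generate_xi_trajectory",
    "generate_distance_trajectory",
    "generate_water_fixture",
    "write_promolecular_cube",
    "TOY_SITE_DISTANCES",
]

logger = logging.getLogger("hbshare.synthetic")


@dataclass(frozen=True)
class GeneratorPreset:
    """An immutable named parameter set for a generator."""

    name: str
    parameters: Mapping[str, float | int | str]

    def __post_init__(self):
        object.__setattr__(self, "parameters", MappingProxyType(dict(self.parameters)))


#: Neutron-structure distances (Å) of the two short HBs in the dark-state
#: active site; the six values fully constrain each donor–H–acceptor pair.
TOY_SITE_DISTANCES: Mapping[str, float] = MappingProxyType(
    {
        "d_opca_oy42": 2.52,
        "d_opca_h2": 1.65,
        "d_oy42_h2": 0.96,
        "d_opca_oe46": 2.56,
        "d_opca_h1": 1.37,
        "d_oe46_h1": 1.21,
    }
)

PRESETS: Mapping[str, GeneratorPreset] = MappingProxyType(
    {
        # QM/MM-like proton-sharing coordinate statistics
        "pyp-dark-qmmm": GeneratorPreset(
            "pyp-dark-qmmm",
            {
                "mu": -0.06,        # Å, mean of xi
                "sigma": 0.14,      # Å, sd of xi
                "oo_mean": 2.5,     # Å, donor-acceptor O-O distance
                "oo_sd": 0.05,      # Å
                "n": 20000,
                "dt": 10.0,         # fs between emitted frames
                "mode": "iid",
                "tau": 50.0,        # fs, OU relaxation time (mode="ou")
                "seed": 42,
            },
        ),
        # classical-MD-like HB distance channels
        "pyp-dark-classical": GeneratorPreset(
            "pyp-dark-classical",
            {
                "y42_mean": 1.79, "y42_sd": 0.07,      # H2···O_pCA
                "e46_mean": 1.71, "e46_sd": 0.05,      # H1···O_pCA
                "oy42_h_mean": 1.00, "oy42_h_sd": 0.04,  # O_Y42-H2 covalent
                "n": 10000,
                "dt": 10.0,
                "seed": 7,
            },
        ),
    }
)


# --------------------------------------------------------------------------
# toy active site
# --------------------------------------------------------------------------

def _check_triangle(d_oo: float, d_oh1: float, d_oh2: float, label: str) -> None:
    for a, b, c, names in (
        (d_oh1, d_oh2, d_oo, f"{label}: d(O,H) + d(H,O') >= d(O,O')"),
        (d_oo, d_oh1, d_oh2, f"{label}: d(O,O') + d(O,H) >= d(H,O')"),
        (d_oo, d_oh2, d_oh1, f"{label}: d(O,O') + d(H,O') >= d(O,H)"),
    ):
        if a + b < c:
            raise FeasibilityError(
                f"infeasible distances, violated inequality {names} "
                f"({a:.3f} + {b:.3f} < {c:.3f})"
            )


def _trilaterate(origin: np.ndarray, other: np.ndarray, d_from_origin: float,
                 d_from_other: float, normal_dir: np.ndarray) -> np.ndarray:
    """Place a point at given distances from two anchors, in the plane spanned
    by the anchor axis and ``normal_dir``, on the +normal side."""
    axis = other - origin
    base = float(np.linalg.norm(axis))
    u = axis / base
    x = (base**2 + d_from_origin**2 - d_from_other**2) / (2 * base)
    y_sq = d_from_origin**2 - x**2
    y = math.sqrt(max(y_sq, 0.0))
    v = normal_dir - (normal_dir @ u) * u
    nv = np.linalg.norm(v)
    if nv < 1e-12:  # anchors parallel to requested normal; pick any perpendicular
        v = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
        v = v - (v @ u) * u
        nv = np.linalg.norm(v)
    v = v / nv
    return origin + x * u + y * v


def build_toy_active_site(
    source: str = "table1",
    distances: Optional[Mapping[str, float]] = None,
    branch_angle_deg: float = 115.0,
    include_c69: bool = False,
) -> Trajectory:
    """Embed the five-atom short-HB motif in 3-D from its six distances.

    Atom order: O_E46, H1, O_pCA, H2, O_Y42 (+ optional C69 S–H pair).  The
    canonical embedding puts O_pCA at the origin, O_E46 on +x, both branches
    in the xy-plane with the hydrogens on the +y side; ``branch_angle_deg``
    is the O_E46–O_pCA–O_Y42 angle, the one degree of freedom the distances
    leave open.  All six requested distances hold to 1e-6 Å.
    """
    if source == "table1":
        dist = dict(TOY_SITE_DISTANCES)
    elif source == "custom":
        if distances is None:
            raise ParameterError("source='custom' requires a distances mapping")
        dist = dict(TOY_SITE_DISTANCES)
        unknown = set(distances) - set(dist)
        if unknown:
            raise ParameterError(f"unknown distance keys: {sorted(unknown)}")
        dist.update(distances)
    else:
        raise ParameterError(f"unknown source {source!r}")
    _check_triangle(dist["d_opca_oe46"], dist["d_oe46_h1"], dist["d_opca_h1"], "pCA-E46")
    _check_triangle(dist["d_opca_oy42"], dist["d_oy42_h2"], dist["d_opca_h2"], "pCA-Y42")

    o_pca = np.zeros(3)
    o_e46 = np.array([dist["d_opca_oe46"], 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    h1 = _trilaterate(o_e46, o_pca, dist["d_oe46_h1"], dist["d_opca_h1"], ey)
    theta = math.radians(branch_angle_deg)
    o_y42 = dist["d_opca_oy42"] * np.array([math.cos(theta), math.sin(theta), 0.0])
    # +y side relative to the O_pCA -> O_Y42 axis, staying in the xy-plane
    axis = o_y42 / np.linalg.norm(o_y42)
    normal = np.array([-axis[1], axis[0], 0.0])
    h2 = _trilaterate(o_y42, o_pca, dist["d_oy42_h2"], dist["d_opca_h2"], normal)

    atoms = [
        AtomRecord(0, "OE2", "O", "GLU", 46),
        AtomRecord(1, "HE2", "H", "GLU", 46),
        AtomRecord(2, "O4'", "O", "PCA", 69),
        AtomRecord(3, "HH", "H", "TYR", 42),
        AtomRecord(4, "OH", "O", "TYR", 42),
    ]
    coords = [o_e46, h1, o_pca, h2, o_y42]
    if include_c69:
        # illustrative placement of the C69 sulfhydryl near the chromophore
        sg = np.array([0.0, -3.5, 0.0])
        hg = sg + np.array([0.0, 1.34, 0.0])
        atoms += [AtomRecord(5, "SG", "S", "CYS", 69), AtomRecord(6, "HG", "H", "CYS", 69)]
        coords += [sg, hg]
    frame = Frame(0, 0.0, np.array(coords))
    traj = Trajectory(atoms=atoms, frames=[frame])
    _assert_distances(traj, dist)
    return traj


def _assert_distances(traj: Trajectory, dist: Mapping[str, float]) -> None:
    c = traj.frames[0].coordinates
    pairs = {
        "d_opca_oy42": (2, 4), "d_opca_h2": (2, 3), "d_oy42_h2": (4, 3),
        "d_opca_oe46": (2, 0), "d_opca_h1": (2, 1), "d_oe46_h1": (0, 1),
    }
    for key, (i, j) in pairs.items():
        got = float(np.linalg.norm(c[i] - c[j]))
        if abs(got - dist[key]) > 1e-6:
            raise FeasibilityError(
                f"embedding failed: {key} = {got:.8f}, requested {dist[key]:.8f}"
            )


# --------------------------------------------------------------------------
# xi trajectory
# --------------------------------------------------------------------------

def _resolve_preset(preset: str | Mapping[str, float | int | str],
                    expected: str) -> dict:
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ParameterError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            )
        if preset != expected:
            raise ParameterError(f"preset {preset!r} is not a {expected!r}-type preset")
        return dict(PRESETS[preset].parameters)
    params = dict(PRESETS[expected].parameters)
    params.update(preset)
    return params


def generate_xi_trajectory(
    preset: str | Mapping[str, float | int | str] = "pyp-dark-qmmm",
    seed: Optional[int] = None,
) -> tuple[Trajectory, XiSeries]:
    """Generate a 3-atom O_E46–H–O_pCA trajectory with prescribed ξ statistics.

    The O–O distance is drawn per frame as N(oo_mean, oo_sd) and the shared
    hydrogen is placed on the O–O axis so that ξ = d(O_E46,H) − d(H,O_pCA)
    follows the requested law: i.i.d. Gaussian draws (``mode="iid"``) or a
    stationary Ornstein–Uhlenbeck process with relaxation time ``tau``
    (``mode="ou"``), integrated at 0.5 fs and subsampled to the emitted frame
    spacing ``dt`` so recrossings are resolved.

    A seed is required (pure function of parameters and seed).
    """
    p = _resolve_preset(preset, "pyp-dark-qmmm")
    if seed is not None:
        p["seed"] = seed
    if p.get("seed") is None:
        raise ParameterError("a seed is required")
    n, dt = int(p["n"]), float(p["dt"])
    mu, sigma = float(p["mu"]), float(p["sigma"])
    if n < 2:
        raise ParameterError("n must be >= 2")
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    rng = np.random.default_rng(int(p["seed"]))
    mode = str(p.get("mode", "iid"))
    if mode == "iid":
        xi = rng.normal(mu, sigma, size=n)
    elif mode == "ou":
        tau = float(p.get("tau", 50.0))
        dt_int = 0.5  # fs, internal integration step
        stride = max(1, int(round(dt / dt_int)))
        a = math.exp(-dt_int / tau)
        noise = sigma * math.sqrt(1.0 - a * a)
        steps = n * stride
        eps = rng.normal(0.0, 1.0, size=steps)
        path = np.empty(steps)
        x = rng.normal(mu, sigma)  # stationary start
        for k in range(steps):
            x = mu + a * (x - mu) + noise * eps[k]
            path[k] = x
        xi = path[stride - 1 :: stride][:n]
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    d_oo = rng.normal(float(p["oo_mean"]), float(p["oo_sd"]), size=n)
    # keep |xi| strictly inside the O-O distance (proton between the oxygens)
    limit = 0.98 * d_oo
    xi = np.clip(xi, -limit, limit)
    d_dh = (d_oo + xi) / 2.0

    atoms = [
        AtomRecord(0, "OE2", "O", "GLU", 46),
        AtomRecord(1, "H1", "H", "GLU", 46),
        AtomRecord(2, "O4'", "O", "PCA", 69),
    ]
    frames = []
    for k in range(n):
        coords = np.array(
            [[0.0, 0.0, 0.0], [d_dh[k], 0.0, 0.0], [d_oo[k], 0.0, 0.0]]
        )
        frames.append(Frame(k, k * dt, coords))
    traj = Trajectory(atoms=atoms, frames=frames)
    triplet = HBondTriplet(0, 1, 2, labels=("O_E46", "H1", "O_pCA"))
    return traj, xi_series(traj, triplet)


# --------------------------------------------------------------------------
# classical distance channels
# --------------------------------------------------------------------------

def generate_distance_trajectory(
    preset: str | Mapping[str, float | int | str] = "pyp-dark-classical",
    seed: Optional[int] = None,
) -> Trajectory:
    """Independent Gaussian HB distance channels embedded as moving atoms.

    Atom order: O_pCA(0), H1(1), O_E46(2), H2(3), O_Y42(4).  Channels (the
    published classical-MD / QM/MM summary statistics are the defaults):
    d(H1, O_pCA) ~ N(e46_mean, e46_sd) along −x, d(H2, O_pCA) ~
    N(y42_mean, y42_sd) along +y, and d(O_Y42, H2) ~ N(oy42_h_mean,
    oy42_h_sd) further along +y.  Channels are generated independently (no
    published covariances).
    """
    p = _resolve_preset(preset, "pyp-dark-classical")
    if seed is not None:
        p["seed"] = seed
    if p.get("seed") is None:
        raise ParameterError("a seed is required")
    n, dt = int(p["n"]), float(p["dt"])
    if n < 2:
        raise ParameterError("n must be >= 2")
    rng = np.random.default_rng(int(p["seed"]))
    d_e46 = rng.normal(float(p["e46_mean"]), float(p["e46_sd"]), size=n)
    d_y42 = rng.normal(float(p["y42_mean"]), float(p["y42_sd"]), size=n)
    d_oh = rng.normal(float(p["oy42_h_mean"]), float(p["oy42_h_sd"]), size=n)
    atoms = [
        AtomRecord(0, "O4'", "O", "PCA", 69),
        AtomRecord(1, "HE2", "H", "GLU", 46),
        AtomRecord(2, "OE2", "O", "GLU", 46),
        AtomRecord(3, "HH", "H", "TYR", 42),
        AtomRecord(4, "OH", "O", "TYR", 42),
    ]
    frames = []
    for k in range(n):
        coords = np.array(
            [
                [0.0, 0.0, 0.0],
                [-d_e46[k], 0.0, 0.0],
                [-d_e46[k] - 1.0, 0.0, 0.0],
                [0.0, d_y42[k], 0.0],
                [0.0, d_y42[k] + d_oh[k], 0.0],
            ]
        )
        frames.append(Frame(k, k * dt, coords))
    return Trajectory(atoms=atoms, frames=frames)


# --------------------------------------------------------------------------
# water fixtures
# --------------------------------------------------------------------------

def generate_water_fixture(
    kind: str = "uniform",
    box: float = 20.0,
    n_waters: int = 200,
    exclusion_radius: float = 4.0,
    n_frames: int = 100,
    seed: Optional[int] = None,
    dt: float = 10.0,
) -> Trajectory:
    """Water-oxygen box around a central probe oxygen (ideal-gas frames).

    Atom 0 is the probe (residue PCA) at the box center; atoms 1..n_waters are
    water oxygens placed uniformly, with rejection inside the exclusion sphere
    for ``kind="dry-pocket"``.  Frames are independent draws.
    """
    if seed is None:
        raise ParameterError("a seed is required")
    if n_waters < 1:
        raise ParameterError("n_waters must be >= 1")
    if kind not in ("uniform", "dry-pocket"):
        raise ParameterError(f"unknown kind {kind!r}")
    if kind == "dry-pocket" and exclusion_radius >= box / 2:
        raise ParameterError("exclusion_radius must be < box/2")
    rng = np.random.default_rng(int(seed))
    center = np.full(3, box / 2.0)
    if kind == "dry-pocket":
        acceptance = 1.0 - (4.0 / 3.0) * np.pi * exclusion_radius**3 / box**3
        if acceptance < 0.01:
            raise PackingError(
                f"acceptance rate {acceptance:.4f} below 1%; shrink the exclusion sphere"
            )
    atoms = [AtomRecord(0, "O4'", "O", "PCA", 69)] + [
        AtomRecord(i + 1, "OW", "O", "WAT", 1000 + i) for i in range(n_waters)
    ]
    box_vec = np.full(3, float(box))
    frames = []
    for k in range(n_frames):
        pts = np.empty((n_waters, 3))
        filled = 0
        while filled < n_waters:
            cand = rng.uniform(0.0, box, size=(n_waters - filled, 3))
            if kind == "dry-pocket":
                delta = cand - center
                delta -= box_vec * np.round(delta / box_vec)
                keep = (delta**2).sum(axis=1) >= exclusion_radius**2
                cand = cand[keep]
            pts[filled : filled + len(cand)] = cand
            filled += len(cand)
        coords = np.vstack([center, pts])
        frames.append(Frame(k, k * dt, coords, box=box_vec.copy()))
    return Trajectory(atoms=atoms, frames=frames)


# --------------------------------------------------------------------------
# promolecular cube export
# --------------------------------------------------------------------------

def write_promolecular_cube(
    model: PromolecularModel,
    spacing: float,
    padding: float,
    path,
    max_points: float = 1e8,
) -> DensityGrid:
    """Sample a promolecular model on a regular grid and write it as a cube.

    ``spacing`` and ``padding`` are in bohr.  Grid values equal the analytic
    field at the nodes; the written grid is returned as well.
    """
    if spacing <= 0:
        raise ParameterError("spacing must be > 0")
    if padding == 0:
        logger.warning("padding is 0: nuclei sit on the grid boundary")
    lo = model.atom_positions.min(axis=0) - padding
    hi = model.atom_positions.max(axis=0) + padding
    counts = np.maximum(2, np.ceil((hi - lo) / spacing).astype(int) + 1)
    if np.prod(counts.astype(float)) > max_points:
        raise GridSizeError(
            f"grid of {np.prod(counts.astype(float)):.3g} points exceeds the "
            f"{max_points:.0g}-point guard"
        )
    xs, ys, zs = (lo[i] + spacing * np.arange(counts[i]) for i in range(3))
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    # vectorized promolecular evaluation over all grid nodes
    values = np.zeros(pts.shape[0])
    amp = model.electrons * model.zeta**3 / np.pi
    for pos, a, z in zip(model.atom_positions, amp, model.zeta):
        r = np.sqrt(((pts - pos) ** 2).sum(axis=1))
        values += a * np.exp(-2.0 * z * r)
    numbers = np.array(
        [{"H": 1, "C": 6, "N": 7, "O": 8, "S": 16}.get(el, 0) for el in model.elements]
    )
    grid = DensityGrid(
        origin=lo,
        axes=np.diag([spacing] * 3),
        counts=counts,
        values=values.reshape(tuple(counts)),
        atom_numbers=numbers,
        atom_charges=model.electrons.astype(float),
        atom_positions=model.atom_positions.copy(),
    )
    write_cube(grid, path, comment="promolecular density (hbshare synthetic)")
    return grid
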