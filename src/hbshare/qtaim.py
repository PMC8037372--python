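"""Electron-density topology and energy-density-based hydrogen-bond typing.

The module characterizes hydrogen bonds from the topology of the electron
density ρ in the spirit of Bader's atoms-in-molecules analysis:

* **Bond critical points (BCPs)** — stationary points of ρ with Hessian
  signature (3,−1) — are located by a damped Newton–Raphson search on ∇ρ.
* **Energy densities** at a point are estimated without a wavefunction using
  the Kirzhnits semiclassical kinetic-energy functional

      G = (3/10)(3π²)^{2/3} ρ^{5/3} + |∇ρ|²/(72 ρ) + ∇²ρ/6,

  combined with the local virial theorem V = ¼∇²ρ − 2G and H = G + V.
  At a critical point |∇ρ|² = 0, so (ρ, ∇²ρ) alone determine H there.
* **Classification** follows the established sign taxonomy: a BCP with
  ∇²ρ > 0 and H > 0 marks a weak HB (< 12 kcal/mol), ∇²ρ > 0 with H < 0 a
  moderate HB (12–24 kcal/mol), and ∇²ρ < 0 with H < 0 a strong HB
  (> 24 kcal/mol, the regime of resonance-assisted and low-barrier HBs).
  A short HB whose two BCPs are both strong/covalent is scored LBHB-like
  (proton shared, quasi-covalent to both oxygens); one covalent plus one
  moderate closed-shell contact is SIHB-like (proton localized, largely
  electrostatic to the far oxygen).

Two density backends implement the same :class:`DensityField` contract: an
analytic promolecular model (sum of single-exponential spherical atoms, with
closed-form gradient and Hessian) and a cubic-spline interpolated grid field
read from a cube file.  All field quantities are in atomic units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Protocol, Sequence, Union

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, FERMI_PREFACTOR
from .errors import ParameterError, StructureError
from .proton_coordinate import HBondTriplet
from .trajectory_io import DensityGrid

__all__ = [
    "DensityField",
    "PromolecularModel",
    "GridField",
    "CriticalPointRecord",
    "HBClassification",
    "promolecular_field",
    "find_critical_point",
    "locate_hb_bcps",
    "kirzhnits_energy_densities",
    "classify_hb",
    "interaction_verdict",
    "DEFAULT_ZETA",
    "DEFAULT_ELECTRONS",
]

logger = logging.getLogger("hbshare.qtaim")

#: Default single-exponential decay constants, bohr^-1 (effective valence decay).
DEFAULT_ZETA: dict[str, float] = {"H": 1.0, "C": 1.60, "N": 1.95, "O": 2.25, "S": 1.85}

#: Default electron counts per neutral atom.
DEFAULT_ELECTRONS: dict[str, float] = {"H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "S": 16.0}

_ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16}

#: Critical-point searches are excluded within this distance of a nucleus
#: (bohr): exponential densities have a cusp there, not a smooth maximum.
NUCLEUS_EXCLUSION_BOHR = 0.2


class DensityField(Protocol):
    """Evaluatable scalar density field, all quantities in atomic units."""

    atom_positions: np.ndarray  # (n, 3) bohr
    atom_labels: list[str]

    def rho(self, point: np.ndarray) -> float: ...
    def grad(self, point: np.ndarray) -> np.ndarray: ...
    def hessian(self, point: np.ndarray) -> np.ndarray: ...


# --------------------------------------------------------------------------
# promolecular model
# --------------------------------------------------------------------------


@dataclass
class PromolecularModel:
    """Sum of spherical single-exponential atomic densities.

    Each atom contributes ρ_a(r) = (N_a ζ_a³ / π) exp(−2 ζ_a r), which
    integrates to exactly N_a electrons.  Gradient and Hessian are closed
    form, so the field is an exact, cheap substrate for topology searches.
    """

    elements: list[str]
    atom_positions: np.ndarray          # (n,3) bohr
    electrons: np.ndarray               # N_a per atom
    zeta: np.ndarray                    # bohr^-1 per atom

    def __post_init__(self):
        self.atom_positions = np.atleast_2d(np.asarray(self.atom_positions, dtype=float))
        self.electrons = np.asarray(self.electrons, dtype=float)
        self.zeta = np.asarray(self.zeta, dtype=float)
        if np.any(self.zeta <= 0):
            raise ParameterError("decay exponents must be positive")

    @property
    def atom_labels(self) -> list[str]:
        return list(self.elements)

    def _terms(self, point: np.ndarray):
        delta = np.asarray(point, dtype=float) - self.atom_positions
        r = np.sqrt((delta**2).sum(axis=1))
        amp = self.electrons * self.zeta**3 / np.pi
        rho_a = amp * np.exp(-2.0 * self.zeta * r)
        return delta, r, rho_a

    def rho(self, point: np.ndarray) -> float:
        return float(self._terms(point)[2].sum())

    def grad(self, point: np.ndarray) -> np.ndarray:
        delta, r, rho_a = self._terms(point)
        out = np.zeros(3)
        for d, ri, ra, z in zip(delta, r, rho_a, self.zeta):
            if ri == 0.0:
                continue  # cusp: radial derivative direction undefined
            out += (-2.0 * z * ra / ri) * d
        return out

    def hessian(self, point: np.ndarray) -> np.ndarray:
        delta, r, rho_a = self._terms(point)
        out = np.zeros((3, 3))
        eye = np.eye(3)
        for d, ri, ra, z in zip(delta, r, rho_a, self.zeta):
            if ri == 0.0:
                continue
            u = d / ri
            fp = -2.0 * z * ra          # dρ_a/dr
            fpp = 4.0 * z**2 * ra       # d²ρ_a/dr²
            out += fpp * np.outer(u, u) + (fp / ri) * (eye - np.outer(u, u))
        return out

    def laplacian(self, point: np.ndarray) -> float:
        return float(np.trace(self.hessian(point)))


def promolecular_field(
    atoms: Sequence[tuple[str, Sequence[float]]],
    zeta_overrides: Optional[dict[str, float]] = None,
    electron_overrides: Optional[dict[str, float]] = None,
    units: str = "angstrom",
) -> PromolecularModel:
    """Build a promolecular density from (element, position) pairs.

    Positions are Å by default (``units="bohr"`` to pass atomic units).
    Unknown elements need an explicit ζ override.
    """
    if not atoms:
        raise ParameterError("need at least one atom")
    if units not in ("angstrom", "bohr"):
        raise ParameterError(f"unknown units {units!r}")
    zeta_map = dict(DEFAULT_ZETA)
    if zeta_overrides:
        zeta_map.update(zeta_overrides)
    ne_map = dict(DEFAULT_ELECTRONS)
    if electron_overrides:
        ne_map.update(electron_overrides)
    elements, positions, electrons, zetas = [], [], [], []
    for element, pos in atoms:
        el = element.capitalize()
        if el not in zeta_map:
            raise ParameterError(
                f"no decay exponent for element {element!r}; pass zeta_overrides"
            )
        if zeta_map[el] <= 0:
            raise ParameterError(f"decay exponent for {el} must be > 0")
        elements.append(el)
        positions.append(np.asarray(pos, dtype=float))
        electrons.append(ne_map.get(el, float(_ATOMIC_NUMBER.get(el, 0))))
        zetas.append(zeta_map[el])
    positions = np.array(positions)
    if units == "angstrom":
        positions = positions * ANGSTROM_TO_BOHR
    return PromolecularModel(
        elements=elements,
        atom_positions=positions,
        electrons=np.array(electrons),
        zeta=np.array(zetas),
    )


# --------------------------------------------------------------------------
# grid-interpolated field
# --------------------------------------------------------------------------


class GridField:
    """Tricubic-spline interpolated density field over a :class:`DensityGrid`.

    The grid is prefiltered once into cubic B-spline coefficients
    (``scipy.ndimage.spline_filter``) and evaluated with ``map_coordinates``,
    so point queries are cheap.  Gradient and Hessian are symmetric central
    differences of the interpolant (step ``fd_step`` bohr; default half the
    grid spacing, which averages out sub-knot spline curvature error and
    keeps the Hessian exactly symmetric).
    """

    def __init__(self, grid: DensityGrid, fd_step: Optional[float] = None):
        from scipy import ndimage

        xs, ys, zs = grid.grid_vectors()  # validates axis-aligned grid
        self._origin = grid.origin
        self._steps = np.diag(grid.axes)
        self._coeff = ndimage.spline_filter(grid.values, order=3, mode="mirror")
        self.grid = grid
        self.fd_step = 0.5 * float(np.min(self._steps)) if fd_step is None else fd_step
        self.atom_positions = np.atleast_2d(grid.atom_positions)
        self.atom_labels = [str(z) for z in grid.atom_numbers]

    def _eval(self, points: np.ndarray) -> np.ndarray:
        from scipy import ndimage

        pts = np.atleast_2d(points)
        idx = (pts - self._origin) / self._steps
        return ndimage.map_coordinates(
            self._coeff, idx.T, order=3, prefilter=False, mode="mirror"
        )

    def rho(self, point: np.ndarray) -> float:
        return float(self._eval(np.asarray(point, dtype=float))[0])

    def grad(self, point: np.ndarray) -> np.ndarray:
        p = np.asarray(point, dtype=float)
        h = self.fd_step
        pts = np.array([p + h * e for e in np.eye(3)] + [p - h * e for e in np.eye(3)])
        v = self._eval(pts)
        return (v[:3] - v[3:]) / (2 * h)

    def hessian(self, point: np.ndarray) -> np.ndarray:
        p = np.asarray(point, dtype=float)
        h = self.fd_step
        eye = np.eye(3)
        pts = [p]
        for i in range(3):
            pts += [p + h * eye[i], p - h * eye[i]]
        for i in range(3):
            for j in range(i + 1, 3):
                pts += [
                    p + h * (eye[i] + eye[j]),
                    p - h * (eye[i] + eye[j]),
                    p + h * (eye[i] - eye[j]),
                    p - h * (eye[i] - eye[j]),
                ]
        v = self._eval(np.array(pts))
        out = np.empty((3, 3))
        f0 = v[0]
        for i in range(3):
            out[i, i] = (v[1 + 2 * i] + v[2 + 2 * i] - 2 * f0) / h**2
        idx = 7
        for i in range(3):
            for j in range(i + 1, 3):
                out[i, j] = out[j, i] = (v[idx] + v[idx + 1] - v[idx + 2] - v[idx + 3]) / (
                    4 * h**2
                )
                idx += 4
        return out


# --------------------------------------------------------------------------
# critical points
# --------------------------------------------------------------------------


@dataclass
class CriticalPointRecord:
    """A converged stationary point of ρ with its local properties (a.u.)."""

    position: np.ndarray       # bohr
    rank: int
    signature: int
    rho_bcp: float
    lap_bcp: float
    G: float
    V: float
    H: float
    grad_norm: float
    flanking_atoms: tuple[str, str] = ("", "")
    d_O_angstrom: float = float("nan")   # distance to nearest flanking O
    d_H_angstrom: float = float("nan")   # distance to nearest flanking H

    @property
    def is_bcp(self) -> bool:
        return self.rank == 3 and self.signature == -1


def _rank_signature(hess: np.ndarray, zero_tol: float = 1e-6) -> tuple[int, int]:
    eigvals = np.linalg.eigvalsh(hess)
    nonzero = eigvals[np.abs(eigvals) > zero_tol]
    return len(nonzero), int(np.sign(nonzero).sum())


def _make_record(field: DensityField, pos: np.ndarray) -> CriticalPointRecord:
    rho = field.rho(pos)
    g = field.grad(pos)
    hess = field.hessian(pos)
    lap = float(np.trace(hess))
    rank, sig = _rank_signature(hess)
    G, V, H = kirzhnits_energy_densities(rho, float(g @ g), lap)
    # flanking atoms: the two nearest, with O/H distances in Å for reporting
    d = np.sqrt(((field.atom_positions - pos) ** 2).sum(axis=1))
    order = np.argsort(d)
    labels = [field.atom_labels[i] for i in order[:2]]
    d_o = d_h = float("nan")
    for i in order:
        lab = field.atom_labels[i].upper()
        if np.isnan(d_o) and (lab.startswith("O") or lab == "8"):
            d_o = d[i] * BOHR_TO_ANGSTROM
        if np.isnan(d_h) and (lab.startswith("H") or lab == "1"):
            d_h = d[i] * BOHR_TO_ANGSTROM
        if not (np.isnan(d_o) or np.isnan(d_h)):
            break
    return CriticalPointRecord(
        position=np.array(pos, dtype=float),
        rank=rank,
        signature=sig,
        rho_bcp=rho,
        lap_bcp=lap,
        G=G,
        V=V,
        H=H,
        grad_norm=float(np.sqrt(g @ g)),
        flanking_atoms=(labels[0], labels[1]) if len(labels) >= 2 else ("", ""),
        d_O_angstrom=d_o,
        d_H_angstrom=d_h,
    )


def find_critical_point(
    field: DensityField,
    seed: np.ndarray,
    gtol: float = 1e-9,
    max_iter: int = 100,
    max_step: float = 0.3,
) -> Optional[CriticalPointRecord]:
    """Newton–Raphson search for a stationary point of ρ from ``seed`` (bohr).

    Hessian-solved steps are damped to ``max_step`` bohr.  Returns ``None`` on
    non-convergence, on a persistently singular Hessian, or when the iterate
    enters the nucleus exclusion sphere (exponential-cusp handling).
    """
    x = np.array(seed, dtype=float)
    for _ in range(max_iter):
        if _near_nucleus(field, x):
            return None
        g = field.grad(x)
        if np.sqrt(g @ g) < gtol:
            record = _make_record(field, x)
            return record
        hess = field.hessian(x)
        step = _solve_step(hess, g)
        if step is None:
            return None
        norm = np.sqrt(step @ step)
        if norm > max_step:
            step = step * (max_step / norm)
        x = x + step
    return None


def _near_nucleus(field: DensityField, x: np.ndarray) -> bool:
    if field.atom_positions.size == 0:
        return False
    d = np.sqrt(((field.atom_positions - x) ** 2).sum(axis=1))
    return bool(np.min(d) < NUCLEUS_EXCLUSION_BOHR)


def _solve_step(hess: np.ndarray, g: np.ndarray) -> Optional[np.ndarray]:
    for reg in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.solve(hess + reg * np.eye(3), -g)
        except np.linalg.LinAlgError:
            continue
    return None


def locate_hb_bcps(
    field: DensityField,
    triplets: Iterable[HBondTriplet],
    triplet_positions: Sequence[np.ndarray],
    dedupe_tol: float = 1e-3,
) -> list[CriticalPointRecord]:
    """Locate the bond critical points of donor–H–acceptor motifs.

    ``triplet_positions[k]`` holds the (donor_O, H, acceptor_O) coordinates in
    bohr for the k-th triplet.  One seed is placed at each O–H midpoint
    (donor-side first, then acceptor-side, triplets in input order), converged
    points are deduplicated within ``dedupe_tol`` bohr, and only (3,−1) points
    are kept.  Non-convergent seeds produce a warning and a partial result.
    """
    records: list[CriticalPointRecord] = []
    for k, (triplet, pos) in enumerate(zip(triplets, triplet_positions)):
        donor, hydrogen, acceptor = (np.asarray(p, dtype=float) for p in pos)
        for side, seed in (("donor", (donor + hydrogen) / 2),
                           ("acceptor", (hydrogen + acceptor) / 2)):
            rec = find_critical_point(field, seed)
            if rec is None:
                logger.warning(
                    "BCP seed (%s side of triplet %d) did not converge", side, k
                )
                continue
            if not rec.is_bcp:
                logger.warning(
                    "critical point from %s side of triplet %d has signature "
                    "(%d,%+d); discarded",
                    side, k, rec.rank, rec.signature,
                )
                continue
            if any(
                np.sqrt(((rec.position - r.position) ** 2).sum()) < dedupe_tol
                for r in records
            ):
                continue
            records.append(rec)
    return records


# --------------------------------------------------------------------------
# energy densities and classification
# --------------------------------------------------------------------------


def kirzhnits_energy_densities(
    rho: Union[float, np.ndarray],
    grad_sq: Union[float, np.ndarray],
    lap: Union[float, np.ndarray],
):
    """Kirzhnits kinetic, potential, and total energy densities (a.u.).

    G = (3/10)(3π²)^{2/3} ρ^{5/3} + |∇ρ|²/(72ρ) + ∇²ρ/6 (the gradient term is
    defined as 0 where ρ = 0), V = ¼∇²ρ − 2G by the local virial theorem, and
    H = G + V.  At a critical point |∇ρ|² = 0, so printed (ρ, ∇²ρ) pairs alone
    reproduce H there.
    """
    rho = np.asarray(rho, dtype=float)
    grad_sq = np.asarray(grad_sq, dtype=float)
    lap = np.asarray(lap, dtype=float)
    if np.any(rho < 0):
        raise ParameterError("rho must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        grad_term = np.where(rho > 0, grad_sq / (72.0 * rho), 0.0)
    G = FERMI_PREFACTOR * rho ** (5.0 / 3.0) + grad_term + lap / 6.0
    V = 0.25 * lap - 2.0 * G
    H = G + V
    if G.ndim == 0:
        return float(G), float(V), float(H)
    return G, V, H


@dataclass(frozen=True)
class HBClassification:
    """Sign-rule strength label for one BCP.

    ``weak``: ∇²ρ > 0 and H > 0 (< 12 kcal/mol); ``moderate``: ∇²ρ > 0 and
    H < 0 (12–24 kcal/mol); ``strong``: ∇²ρ < 0 and H < 0 (> 24 kcal/mol).
    Exact zeros (and the ∇²ρ < 0, H > 0 corner, which the taxonomy does not
    cover) yield ``indeterminate`` with the candidate labels reported.
    """

    label: str
    covalent_contact: bool     # ∇²ρ < 0 and H < 0
    closed_shell: bool         # ∇²ρ > 0
    energy_band: str
    candidates: tuple[str, ...] = ()


_BANDS = {
    "weak": "< 12 kcal/mol",
    "moderate": "12-24 kcal/mol",
    "strong": "> 24 kcal/mol",
    "indeterminate": "n/a",
}


def classify_hb(lap_bcp: float, H_bcp: float) -> HBClassification:
    """Classify a hydrogen-bond BCP by the signs of ∇²ρ and H."""
    if not (np.isfinite(lap_bcp) and np.isfinite(H_bcp)):
        raise ParameterError("inputs must be finite")
    if lap_bcp == 0.0 or H_bcp == 0.0:
        cands = []
        if lap_bcp >= 0 and H_bcp >= 0:
            cands.append("weak")
        if lap_bcp >= 0 and H_bcp <= 0:
            cands.append("moderate")
        if lap_bcp <= 0 and H_bcp <= 0:
            cands.append("strong")
        return HBClassification(
            label="indeterminate",
            covalent_contact=False,
            closed_shell=lap_bcp > 0,
            energy_band=_BANDS["indeterminate"],
            candidates=tuple(cands),
        )
    if lap_bcp > 0:
        label = "weak" if H_bcp > 0 else "moderate"
    else:
        label = "strong" if H_bcp < 0 else "indeterminate"
    return HBClassification(
        label=label,
        covalent_contact=(lap_bcp < 0 and H_bcp < 0),
        closed_shell=(lap_bcp > 0),
        energy_band=_BANDS[label],
    )


def interaction_verdict(
    donor_side: HBClassification, acceptor_side: HBClassification
) -> str:
    """Type of an O···H···O interaction from its two BCP classifications.

    ``LBHB-like``: both BCPs strong/covalent (proton shared, quasi-covalent to
    both oxygens).  ``SIHB-like``: one strong/covalent and one
    moderate/closed-shell (proton localized; short ionic HB to the far
    oxygen).  Anything else is ``ordinary``.
    """
    pair = (donor_side, acceptor_side)
    if any(not isinstance(c, HBClassification) for c in pair):
        raise ParameterError("both BCP classifications are required")
    strong = [c.label == "strong" and c.covalent_contact for c in pair]
    moderate = [c.label == "moderate" and c.closed_shell for c in pair]
    if all(strong):
        return "LBHB-like"
    if (strong[0] and moderate[1]) or (strong[1] and moderate[0]):
        return "SIHB-like"
    return "ordinary"
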