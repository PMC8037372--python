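"""Density fields, critical-point searches, energy densities, classification."""

import numpy as np
import pytest
from scipy.integrate import quad

from hbshare.constants import ANGSTROM_TO_BOHR, FERMI_PREFACTOR
from hbshare.errors import ParameterError
from hbshare.proton_coordinate import HBondTriplet
from hbshare.qtaim import (
    HBClassification,
    classify_hb,
    find_critical_point,
    interaction_verdict,
    kirzhnits_energy_densities,
    locate_hb_bcps,
    promolecular_field,
)


class TestPromolecularField:
    def test_single_hydrogen_closed_form(self):
        field = promolecular_field([("H", (0, 0, 0))], units="bohr")
        assert field.rho([0.5, 0, 0]) == pytest.approx(np.exp(-1.0) / np.pi, rel=1e-12)

    def test_oxygen_normalization_by_quadrature(self):
        field = promolecular_field([("O", (0, 0, 0))], units="bohr")
        zeta = field.zeta[0]
        radial = lambda r: 4 * np.pi * r**2 * (8 * zeta**3 / np.pi) * np.exp(-2 * zeta * r)
        total, _ = quad(radial, 0, 12.0)
        assert total == pytest.approx(8.0, abs=1e-3)

    def test_gradient_matches_finite_difference(self):
        field = promolecular_field(
            [("O", (0, 0, 0)), ("H", (0.96, 0, 0)), ("H", (-0.24, 0.93, 0))]
        )
        rng = np.random.default_rng(0)
        h = 1e-4
        for _ in range(5):
            p = rng.uniform(-1, 2, size=3) * ANGSTROM_TO_BOHR
            g = field.grad(p)
            fd = np.array(
                [
                    (field.rho(p + h * e) - field.rho(p - h * e)) / (2 * h)
                    for e in np.eye(3)
                ]
            )
            assert np.allclose(g, fd, rtol=1e-6, atol=1e-10)

    def test_hessian_symmetric_and_consistent(self):
        field = promolecular_field([("O", (0, 0, 0)), ("H", (0.96, 0, 0))])
        p = np.array([0.7, 0.2, -0.1])
        hess = field.hessian(p)
        assert np.allclose(hess, hess.T, atol=1e-10)
        h = 1e-4
        fd_lap = sum(
            (field.rho(p + h * e) + field.rho(p - h * e) - 2 * field.rho(p)) / h**2
            for e in np.eye(3)
        )
        assert np.trace(hess) == pytest.approx(fd_lap, rel=1e-5)

    def test_unknown_element_needs_override(self):
        with pytest.raises(ParameterError):
            promolecular_field([("Xx", (0, 0, 0))])
        field = promolecular_field([("Xx", (0, 0, 0))],
                                   zeta_overrides={"Xx": 1.5},
                                   electron_overrides={"Xx": 2.0})
        assert field.rho([0, 0, 1.0]) > 0


def axial_grid_scan_cp(field, x_lo, x_hi, resolution=1e-3):
    """Brute-force oracle: minimum of |grad rho| along the internuclear axis."""
    xs = np.arange(x_lo, x_hi, resolution)
    norms = [np.linalg.norm(field.grad([x, 0.0, 0.0])) for x in xs]
    return xs[int(np.argmin(norms))]


class TestFindCriticalPoint:
    def test_symmetric_oxygen_pair_midpoint(self):
        d = 2.8 * ANGSTROM_TO_BOHR
        field = promolecular_field([("O", (0, 0, 0)), ("O", (d, 0, 0))], units="bohr")
        rec = find_critical_point(field, np.array([d / 2 + 0.1, 0.05, 0.0]))
        assert rec is not None
        assert rec.signature == -1 and rec.rank == 3
        assert np.allclose(rec.position, [d / 2, 0, 0], atol=1e-8)

    def test_oh_pair_matches_grid_scan(self, oh_fields, oh_midpoint_seed):
        field, _, _ = oh_fields
        rec = find_critical_point(field, oh_midpoint_seed)
        assert rec is not None and rec.is_bcp
        assert rec.grad_norm < 1e-9
        d_oh = 0.96 * ANGSTROM_TO_BOHR
        x_scan = axial_grid_scan_cp(field, 0.25, d_oh - 0.25)
        assert abs(rec.position[0] - x_scan) < 1e-3
        assert abs(rec.position[1]) < 1e-8 and abs(rec.position[2]) < 1e-8

    def test_record_reproducible_from_field(self, oh_fields, oh_midpoint_seed):
        field, _, _ = oh_fields
        rec = find_critical_point(field, oh_midpoint_seed)
        assert field.rho(rec.position) == pytest.approx(rec.rho_bcp, rel=1e-12)
        assert np.trace(field.hessian(rec.position)) == pytest.approx(
            rec.lap_bcp, rel=1e-12
        )
        assert rec.H == pytest.approx(rec.G + rec.V, abs=1e-12)

    def test_seed_at_nucleus_excluded(self, oh_fields):
        field, _, _ = oh_fields
        assert find_critical_point(field, np.array([0.0, 0.0, 0.0])) is None

    def test_grid_field_matches_analytic_within_1pc(self, oh_fields, oh_midpoint_seed):
        analytic, gridded, _ = oh_fields
        rec_a = find_critical_point(analytic, oh_midpoint_seed)
        rec_g = find_critical_point(gridded, oh_midpoint_seed)
        assert rec_g is not None and rec_g.is_bcp
        for name in ("rho_bcp", "lap_bcp", "G", "V", "H"):
            assert getattr(rec_g, name) == pytest.approx(
                getattr(rec_a, name), rel=0.01
            )


class TestLocateHbBcps:
    def test_toy_active_site_has_four_bcps(self, toy_site):
        coords = toy_site.frames[0].coordinates
        field = promolecular_field(
            [(a.element, xyz) for a, xyz in zip(toy_site.atoms, coords)]
        )
        pos = coords * ANGSTROM_TO_BOHR
        records = locate_hb_bcps(
            field,
            [HBondTriplet(0, 1, 2), HBondTriplet(4, 3, 2)],
            [(pos[0], pos[1], pos[2]), (pos[4], pos[3], pos[2])],
        )
        assert len(records) == 4
        for rec in records:
            assert rec.rank == 3 and rec.signature == -1
            assert rec.grad_norm < 1e-9
            assert rec.H == pytest.approx(rec.G + rec.V, abs=1e-12)
            if rec.G > 0 and rec.V < 0:
                assert rec.V / rec.G < 0

    def test_single_triplet_gives_two_bcps(self):
        coords = np.array([[0.0, 0, 0], [1.21, 0, 0], [2.58, 0, 0]])
        field = promolecular_field(
            [("O", coords[0]), ("H", coords[1]), ("O", coords[2])]
        )
        pos = coords * ANGSTROM_TO_BOHR
        records = locate_hb_bcps(
            field, [HBondTriplet(0, 1, 2)], [(pos[0], pos[1], pos[2])]
        )
        assert len(records) == 2

    def test_duplicate_seeds_deduplicated(self):
        coords = np.array([[0.0, 0, 0], [1.21, 0, 0], [2.58, 0, 0]])
        field = promolecular_field(
            [("O", coords[0]), ("H", coords[1]), ("O", coords[2])]
        )
        pos = coords * ANGSTROM_TO_BOHR
        triplet = HBondTriplet(0, 1, 2)
        records = locate_hb_bcps(
            field,
            [triplet, triplet],
            [(pos[0], pos[1], pos[2]), (pos[0], pos[1], pos[2])],
        )
        assert len(records) == 2


class TestKirzhnits:
    def test_thomas_fermi_limit(self):
        # rho=1, no gradient, no laplacian: G is the Fermi constant, H = -G
        G, V, H = kirzhnits_energy_densities(1.0, 0.0, 0.0)
        assert G == pytest.approx(FERMI_PREFACTOR, rel=1e-12)
        assert H == pytest.approx(-FERMI_PREFACTOR, rel=1e-12)

    def test_identity_h_equals_g_plus_v(self):
        rng = np.random.default_rng(1)
        rho = rng.uniform(0.01, 0.5, size=20)
        grad_sq = rng.uniform(0, 0.1, size=20)
        lap = rng.uniform(-1, 1, size=20)
        G, V, H = kirzhnits_energy_densities(rho, grad_sq, lap)
        assert np.allclose(H, G + V, atol=1e-12)

    def test_zero_density_gradient_term(self):
        G, V, H = kirzhnits_energy_densities(0.0, 0.0, 0.1)
        assert np.isfinite(H)

    def test_negative_density_rejected(self):
        with pytest.raises(ParameterError):
            kirzhnits_energy_densities(-0.1, 0.0, 0.0)


class TestClassification:
    def test_sign_rules(self):
        weak = classify_hb(0.05, 0.01)
        assert weak.label == "weak" and weak.closed_shell and not weak.covalent_contact
        moderate = classify_hb(1.51e-1, -1.92e-2)
        assert moderate.label == "moderate" and moderate.closed_shell
        strong = classify_hb(-2.83e-1, -1.74e-1)
        assert strong.label == "strong" and strong.covalent_contact

    def test_exact_zero_is_indeterminate(self):
        cls = classify_hb(0.0, -0.1)
        assert cls.label == "indeterminate"
        assert "moderate" in cls.candidates and "strong" in cls.candidates

    def test_nonfinite_rejected(self):
        with pytest.raises(ParameterError):
            classify_hb(float("nan"), 0.1)

    def test_verdicts(self):
        strong = classify_hb(-0.2, -0.15)
        moderate = classify_hb(0.15, -0.02)
        weak = classify_hb(0.05, 0.01)
        assert interaction_verdict(strong, strong) == "LBHB-like"
        assert interaction_verdict(strong, moderate) == "SIHB-like"
        assert interaction_verdict(moderate, strong) == "SIHB-like"
        assert interaction_verdict(weak, weak) == "ordinary"
        assert interaction_verdict(strong, weak) == "ordinary"
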