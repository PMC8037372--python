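"""Physical constants and unit conversions shared across the package.

Atomic units (bohr, hartree) are used internally for electron-density work;
Ångström and femtoseconds at the trajectory I/O boundary.  There is exactly
one bohr/Å constant in the package — every conversion goes through it.
"""

#: 1 bohr in Å (single source of truth for all unit conversions).
BOHR_TO_ANGSTROM: float = 0.52917721

#: 1 Å in bohr.
ANGSTROM_TO_BOHR: float = 1.0 / BOHR_TO_ANGSTROM

#: Boltzmann constant in kcal mol^-1 K^-1 (CODATA, as used for PMFs).
KB_KCAL_PER_MOL_K: float = 1.987204259e-3

#: Simulation temperature of the reference study conditions (K).
ROOM_TEMPERATURE_K: float = 303.15

#: Default frame spacing assigned to trajectory frames without a time stamp (fs).
DEFAULT_FRAME_DT_FS: float = 10.0

#: Thomas-Fermi kinetic-energy prefactor (3/10)(3*pi^2)^(2/3), atomic units.
FERMI_PREFACTOR: float = 0.3 * (3.0 * 3.141592653589793**2) ** (2.0 / 3.0)
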