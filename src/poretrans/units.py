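"""Simulation-unit system and mapping to real (SI / laboratory) units.

The simulation works in reduced units built from four base quantities: the
bead diameter ``sigma`` (length), the bead mass ``m``, the thermal energy
``kBT`` and the elementary charge ``e``.  Anchoring the reduced Bjerrum
length to its value in water at room temperature fixes ``sigma`` in
angstroms, and from there every derived unit (time, force, electric field,
concentration) follows dimensionally:

    tau_u = sigma * sqrt(m / kBT)         (time)
    f_u   = kBT / sigma                   (force)
    E_u   = kBT / (e * sigma)             (electric field)
    c_u   = 1 / sigma^3                   (number concentration)

The module also provides the Odijk--Skolnick--Fixman (OSF) estimate of the
persistence length of a uniformly charged chain in salt solution,

    l_p = l_p0 + lambda_B / (4 * (kappa * l_c)^2),

with ``kappa = sqrt(8 pi lambda_B I)`` the inverse Debye length, ``l_c`` the
charge spacing along the backbone and ``I`` the (monovalent) ionic strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "KB",
    "N_AVOGADRO",
    "UnitSystem",
    "SaltSpec",
    "OSFPersistence",
    "length_unit_from_bjerrum",
    "real_unit_table",
    "salt_concentration",
    "osf_persistence_length",
    "format_unit_table",
]

#: Boltzmann constant, J/K.
KB = 1.380649e-23
#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.02214e23
#: Room temperature used for the default thermal energy, K.
T_ROOM = 300.0
#: Bjerrum length of water at room temperature, angstrom.
BJERRUM_WATER_A = 7.14


def length_unit_from_bjerrum(bjerrum_real_A: float, bjerrum_sigma: float) -> float:
    """Angstroms per sigma fixed by matching the reduced Bjerrum length.

    If the model sets the Bjerrum length to ``bjerrum_sigma`` reduced units
    while the solvent's physical Bjerrum length is ``bjerrum_real_A``
    angstrom, the length unit is their ratio.
    """
    if bjerrum_real_A <= 0 or bjerrum_sigma <= 0:
        raise ValueError("Bjerrum lengths must be strictly positive")
    return bjerrum_real_A / bjerrum_sigma


@dataclass(frozen=True)
class UnitSystem:
    """The (sigma, m, kBT, e) reduced-unit system and its SI anchors.

    Parameters
    ----------
    length_unit_A:
        Angstrom per sigma.
    mass_unit_gmol:
        Gram per mole per bead mass m (a coarse-grained monomer mass).
    thermal_energy_J:
        Joule per kBT.  The default is the rounded value at 300 K used when
        quoting derived units; keep it if you want the printed unit table to
        match published mappings to three figures.
    charge_unit_C:
        Coulomb per elementary charge e.
    bjerrum_sigma:
        Reduced Bjerrum length lambda_B in sigma.
    """

    length_unit_A: float = BJERRUM_WATER_A / 3.0
    mass_unit_gmol: float = 200.0
    thermal_energy_J: float = 4.14e-21
    charge_unit_C: float = 1.602e-19
    bjerrum_sigma: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "length_unit_A",
            "mass_unit_gmol",
            "thermal_energy_J",
            "charge_unit_C",
            "bjerrum_sigma",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    # -- derived SI quantities -------------------------------------------
    @property
    def length_unit_m(self) -> float:
        return self.length_unit_A * 1e-10

    @property
    def mass_unit_kg(self) -> float:
        return self.mass_unit_gmol * 1e-3 / N_AVOGADRO

    @property
    def time_unit_s(self) -> float:
        """tau_u = sigma * sqrt(m / kBT), seconds."""
        return self.length_unit_m * math.sqrt(self.mass_unit_kg / self.thermal_energy_J)

    @property
    def time_unit_ps(self) -> float:
        return self.time_unit_s * 1e12

    @property
    def force_unit_N(self) -> float:
        return self.thermal_energy_J / self.length_unit_m

    @property
    def force_unit_pN(self) -> float:
        return self.force_unit_N * 1e12

    @property
    def field_unit_V_per_m(self) -> float:
        """kBT / (e sigma), volts per meter."""
        return self.thermal_energy_J / (self.charge_unit_C * self.length_unit_m)

    @property
    def concentration_unit_molar(self) -> float:
        """1/sigma^3 expressed in mol/L."""
        sigma_m = self.length_unit_m
        return 1.0 / (sigma_m**3 * 1e3 * N_AVOGADRO)

    # -- conversions ------------------------------------------------------
    def to_real(self, value: float, kind: str) -> float:
        """Convert a reduced quantity to real units (see :meth:`unit_factor`)."""
        return value * self.unit_factor(kind)

    def from_real(self, value: float, kind: str) -> float:
        """Inverse of :meth:`to_real`; round-trips to machine precision."""
        return value / self.unit_factor(kind)

    def unit_factor(self, kind: str) -> float:
        factors = {
            "length_A": self.length_unit_A,
            "time_ps": self.time_unit_ps,
            "force_pN": self.force_unit_pN,
            "field_V_per_m": self.field_unit_V_per_m,
            "concentration_molar": self.concentration_unit_molar,
            "energy_J": self.thermal_energy_J,
        }
        try:
            return factors[kind]
        except KeyError:
            raise KeyError(
                f"unknown quantity kind {kind!r}; one of {sorted(factors)}"
            ) from None


def real_unit_table(u: UnitSystem) -> dict[str, float]:
    """Derived real units of the reduced system as a flat mapping."""
    return {
        "length_A_per_sigma": u.length_unit_A,
        "mass_gmol": u.mass_unit_gmol,
        "energy_J_per_kBT": u.thermal_energy_J,
        "charge_C_per_e": u.charge_unit_C,
        "time_ps_per_tau": u.time_unit_ps,
        "force_pN_per_unit": u.force_unit_pN,
        "field_V_per_m_per_unit": u.field_unit_V_per_m,
        "concentration_molar_per_unit": u.concentration_unit_molar,
    }


def format_unit_table(u: UnitSystem) -> str:
    """Flat key-value text rendering of :func:`real_unit_table`."""
    rows = real_unit_table(u)
    width = max(len(k) for k in rows)
    return "\n".join(f"{k:<{width}}  {v:.6g}" for k, v in rows.items())


@dataclass(frozen=True)
class SaltSpec:
    """Added salt in a walled box, and chain parameters for OSF stiffness.

    The salt occupies the fluid volume only: the slab taken up by the
    membrane wall is excluded when converting a molecule count into a
    concentration.
    """

    n_salt: int = 256
    box_x: float = 48.0
    box_y: float = 49.36
    box_z: float = 200.0
    wall_thickness: float = 4.5
    charge_spacing: float = 1.0       # l_c, sigma
    intrinsic_persistence: float = 1.0  # l_p0, sigma

    def __post_init__(self) -> None:
        if self.box_z <= self.wall_thickness:
            raise ValueError("box_z must exceed the wall thickness")
        if self.n_salt < 0:
            raise ValueError("n_salt must be non-negative")
        if self.charge_spacing <= 0 or self.intrinsic_persistence < 0:
            raise ValueError("chain stiffness parameters must be positive")

    @property
    def fluid_volume(self) -> float:
        """Accessible solution volume in sigma^3 (wall slab removed)."""
        return self.box_x * self.box_y * (self.box_z - self.wall_thickness)

    @property
    def ionic_strength(self) -> float:
        """Monovalent ionic strength I = Cs in sigma^-3."""
        return self.n_salt / self.fluid_volume


def salt_concentration(spec: SaltSpec, u: UnitSystem) -> tuple[float, float]:
    """Salt concentration as (sigma^-3, mol/L)."""
    cs = spec.ionic_strength
    return cs, cs * u.concentration_unit_molar


@dataclass(frozen=True)
class OSFPersistence:
    """OSF persistence-length estimate, reduced and real."""

    lp_electrostatic_sigma: float
    lp_total_sigma: float
    lp_total_A: float
    inverse_debye_sigma: float

    @property
    def debye_length_sigma(self) -> float:
        return 1.0 / self.inverse_debye_sigma


def osf_persistence_length(spec: SaltSpec, u: UnitSystem) -> OSFPersistence:
    """OSF persistence length for the charged chain in the salt solution.

    kappa = sqrt(8 pi lambda_B I); l_p,e = lambda_B / (4 (kappa l_c)^2);
    l_p = l_p0 + l_p,e.  Raises for zero ionic strength, where the
    electrostatic term diverges (no screening).
    """
    I = spec.ionic_strength
    if I <= 0:
        raise ValueError(
            "electrostatic persistence length diverges at zero ionic strength "
            "(kappa = 0); add salt or report the unscreened limit explicitly"
        )
    kappa = math.sqrt(8.0 * math.pi * u.bjerrum_sigma * I)
    lp_e = u.bjerrum_sigma / (4.0 * (kappa * spec.charge_spacing) ** 2)
    lp_total = spec.intrinsic_persistence + lp_e
    return OSFPersistence(
        lp_electrostatic_sigma=lp_e,
        lp_total_sigma=lp_total,
        lp_total_A=lp_total * u.length_unit_A,
        inverse_debye_sigma=kappa,
    )
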