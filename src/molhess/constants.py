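"""Physical constants, unit conversions, and per-element reference data.

All internal quantities are in Hartree atomic units; conversions to SI or
spectroscopic units happen only at input/output boundaries.  The constant
values follow CODATA 2018.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA 2018 constants used by the spectroscopy conversions.

    Attributes
    ----------
    N_A : Avogadro constant (1/mol).
    eps0 : vacuum permittivity (F/m).
    c : speed of light in vacuum (m/s).
    e : elementary charge (C).
    amu_to_kg : atomic mass constant (kg).
    bohr_to_m : Bohr radius (m).
    hartree_to_J : Hartree energy (J).
    """

    N_A: float = 6.02214076e23
    eps0: float = 8.8541878128e-12
    c: float = 2.99792458e8
    e: float = 1.602176634e-19
    amu_to_kg: float = 1.66053906660e-27
    bohr_to_m: float = 0.529177210903e-10
    hartree_to_J: float = 4.3597447222071e-18

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be positive")


CONSTANTS = PhysicalConstants()

BOHR_TO_ANGSTROM = CONSTANTS.bohr_to_m * 1e10  # 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM


def ir_intensity_prefactor(constants: PhysicalConstants = CONSTANTS) -> float:
    """Unit prefactor converting |dmu/dQ|^2 in e^2/amu to km/mol.

    The Napierian integrated attenuation coefficient of mode k is

        A_k = (1/(4 pi eps0)) * (N_A pi / (3 c^2)) * |dmu/dQ_k|^2

    With the squared dipole-moment gradient expressed in e^2/amu, collecting
    the constants and converting m/mol to km/mol yields approximately
    974.88 km/mol * amu / e^2.
    """
    k = constants
    si = k.N_A * 3.141592653589793 * k.e**2 / (
        4 * 3.141592653589793 * k.eps0 * 3 * k.c**2 * k.amu_to_kg
    )
    return si / 1000.0  # m/mol -> km/mol


def eigenvalue_to_wavenumber(constants: PhysicalConstants = CONSTANTS) -> float:
    """Conversion factor: sqrt(hartree/(bohr^2 amu)) -> cm^-1.

    A mass-weighted Hessian eigenvalue lam (hartree/(bohr^2 amu)) maps to a
    harmonic wavenumber  omega = sqrt(lam_SI)/(2 pi c) / 100.
    """
    k = constants
    lam_si = k.hartree_to_J / (k.bohr_to_m**2 * k.amu_to_kg)  # s^-2 per a.u.
    return (lam_si**0.5) / (2 * 3.141592653589793 * k.c) / 100.0


# Element symbol -> nuclear charge for the supported range.
ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}

Z_TO_ELEMENT = {z: sym for sym, z in ELEMENT_Z.items()}

# Most-abundant-isotope masses (amu).  Overridable per atom in a run config;
# the common convention for harmonic frequency tables.
ISOTOPE_MASS = {
    "H": 1.00782503207, "He": 4.00260325415, "Li": 7.016004548,
    "Be": 9.012182201, "B": 11.009305406, "C": 12.0,
    "N": 14.003074004, "O": 15.994914620, "F": 18.998403224,
    "Ne": 19.992440175, "Na": 22.989769281, "Mg": 23.985041699,
    "Al": 26.981538627, "Si": 27.976926532, "P": 30.973761629,
    "S": 31.972070999, "Cl": 34.968852682, "Ar": 39.962383123,
}
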