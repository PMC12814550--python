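"""Molecular geometry container and XYZ input.

Coordinates are stored in bohr; the XYZ format carries angstrom and is
converted on read.  Only closed-shell (even electron count) systems are
supported by the electronic-structure layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, ELEMENT_Z, ISOTOPE_MASS


class ParseError(ValueError):
    """Malformed structure file."""


class UnsupportedElementError(ValueError):
    """Element outside the supported table."""


@dataclass
class Molecule:
    """A molecule: element symbols, nuclear charges, positions (bohr), masses (amu)."""

    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), bohr
    total_charge: int = 0
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for el in self.elements:
            if el not in ELEMENT_Z:
                raise UnsupportedElementError(f"unsupported element {el!r}")
        if self.masses is None:
            self.masses = np.array([ISOTOPE_MASS[el] for el in self.elements])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (len(self.elements),):
                raise ValueError("masses must have one entry per atom")

    @property
    def charges(self) -> np.ndarray:
        """Nuclear charges Z."""
        return np.array([ELEMENT_Z[el] for el in self.elements], dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_electrons(self) -> int:
        n = int(self.charges.sum()) - self.total_charge
        if n < 0:
            raise ValueError("negative electron count")
        return n

    def require_closed_shell(self) -> None:
        if self.n_electrons % 2 != 0:
            raise ValueError(
                f"odd electron count ({self.n_electrons}); only closed-shell "
                "systems are supported"
            )

    def displaced(self, atom: int, component: int, step: float) -> "Molecule":
        """Copy with one Cartesian coordinate shifted by ``step`` bohr."""
        coords = self.coords.copy()
        coords[atom, component] += step
        return Molecule(list(self.elements), coords, self.total_charge,
                        self.masses.copy())

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        return Molecule(list(self.elements), np.asarray(coords, float),
                        self.total_charge, self.masses.copy())

    def nuclear_repulsion(self) -> float:
        z = self.charges
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i):
                e += z[i] * z[j] / np.linalg.norm(self.coords[i] - self.coords[j])
        return e

    def center_of_nuclear_charge(self) -> np.ndarray:
        z = self.charges
        return (z[:, None] * self.coords).sum(axis=0) / z.sum()

    def to_xyz(self, comment: str = "") -> str:
        lines = [str(self.n_atoms), comment]
        for el, xyz in zip(self.elements, self.coords * BOHR_TO_ANGSTROM):
            lines.append(f"{el:<2s} {xyz[0]:18.12f} {xyz[1]:18.12f} {xyz[2]:18.12f}")
        return "\n".join(lines) + "\n"


def read_xyz(path, total_charge: int = 0) -> Molecule:
    """Read a standard XYZ file (count line, comment line, ``El x y z`` in angstrom)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    return parse_xyz("\n".join(lines), total_charge=total_charge)


def parse_xyz(text: str, total_charge: int = 0) -> Molecule:
    lines = [ln for ln in text.splitlines()]
    if not lines:
        raise ParseError("empty XYZ input")
    try:
        count = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"malformed atom-count line: {lines[0]!r}") from exc
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != count:
        raise ParseError(f"count line says {count} atoms but found {len(body)}")
    elements, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"malformed atom line: {ln!r}")
        el = parts[0].capitalize()
        if el not in ELEMENT_Z:
            raise UnsupportedElementError(f"unsupported element {parts[0]!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise ParseError(f"malformed coordinates in line: {ln!r}") from exc
        elements.append(el)
        coords.append(xyz)
    coords = np.array(coords) * ANGSTROM_TO_BOHR
    return Molecule(elements, coords, total_charge=total_charge)
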