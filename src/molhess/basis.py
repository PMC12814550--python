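"""Gaussian basis-set ingestion and shell bookkeeping.

Supports segmented contractions with angular momentum l <= 4.  Two file
dialects are read: Gaussian-94-style text blocks and an equivalent JSON
structure.  Contraction coefficients are renormalized on load so every
contracted spherical AO has unit self-overlap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .molecule import Molecule, UnsupportedElementError
from .spherical import (MAX_L, UnsupportedAngularMomentumError, _df, n_cart,
                        n_sph)

_AM_LETTERS = {"S": 0, "P": 1, "D": 2, "F": 3, "G": 4}

# Bundled basis sets resolvable by name (case-insensitive).
_BUILTIN = {
    "sto-3g": "sto-3g.g94",
    "def2-sv(p)": "def2-svp-h-cno.g94",
    "def2-svp": "def2-svp-h-cno.g94",
}


@dataclass
class GaussianShell:
    """One contracted shell of Cartesian/spherical Gaussians.

    exponents are stored in canonically sorted (strictly decreasing) order;
    coefficients carry the primitive normalization of the (l,0,0) component
    and an overall factor making the contracted spherical AO unit-normalized.
    """

    center_index: int
    l: int
    exponents: np.ndarray
    coefficients: np.ndarray
    center: np.ndarray  # (3,) bohr

    def __post_init__(self) -> None:
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.l > MAX_L or self.l < 0:
            raise UnsupportedAngularMomentumError(f"l={self.l} unsupported")
        if np.any(self.exponents <= 0):
            raise ValueError("primitive exponents must be positive")
        order = np.argsort(-self.exponents, kind="stable")
        self.exponents = self.exponents[order]
        self.coefficients = self.coefficients[order]
        if np.any(np.diff(self.exponents) >= 0):
            raise ValueError("duplicate primitive exponents in one shell")
        self.center = np.asarray(self.center, dtype=float)

    @property
    def n_prim(self) -> int:
        return len(self.exponents)

    @property
    def n_sph(self) -> int:
        return n_sph(self.l)

    @property
    def n_cart(self) -> int:
        return n_cart(self.l)


def _primitive_norm(alpha: float, l: int) -> float:
    """Normalization of the (l,0,0) Cartesian primitive."""
    return ((2 * alpha / math.pi) ** 0.75
            * (4 * alpha) ** (l / 2) / math.sqrt(_df(2 * l - 1)))


def _normalize_shell(l: int, exps: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Fold primitive norms into coefficients and scale the contraction to
    unit self-overlap of the (l,0,0) component (hence of every spherical
    component, by rotational invariance)."""
    c = coefs * np.array([_primitive_norm(a, l) for a in exps])
    s = 0.0
    for ci, ai in zip(c, exps):
        for cj, aj in zip(c, exps):
            p = ai + aj
            s += ci * cj * (math.pi / p) ** 1.5 * _df(2 * l - 1) / (2 * p) ** l
    return c / math.sqrt(s)


def normalized_shell(center_index: int, l: int, exponents, coefficients,
                     center) -> GaussianShell:
    """Construct a shell with primitive norms folded in and the contracted
    function scaled to unit self-overlap (what load_basis does)."""
    e = np.asarray(exponents, float)
    c = _normalize_shell(l, e, np.asarray(coefficients, float))
    return GaussianShell(center_index, l, e, c, np.asarray(center, float))


@dataclass
class AOBasis:
    """An ordered set of shells placed on a molecule, with AO index maps."""

    molecule: Molecule
    shells: list[GaussianShell]

    def __post_init__(self) -> None:
        offs, coffs = [], []
        n, nc = 0, 0
        for sh in self.shells:
            offs.append(n)
            coffs.append(nc)
            n += sh.n_sph
            nc += sh.n_cart
        self.ao_offsets = offs
        self.cart_offsets = coffs
        self.n_ao = n
        self.n_cart = nc

    @property
    def n_shells(self) -> int:
        return len(self.shells)

    def shells_on_atom(self, atom: int) -> list[int]:
        return [i for i, sh in enumerate(self.shells) if sh.center_index == atom]

    def ao_atom_map(self) -> np.ndarray:
        """Atom index owning each spherical AO."""
        out = np.empty(self.n_ao, dtype=int)
        for sh, off in zip(self.shells, self.ao_offsets):
            out[off:off + sh.n_sph] = sh.center_index
        return out


def _parse_g94(text: str) -> dict[str, list[tuple[int, list[float], list[float]]]]:
    blocks: dict[str, list] = {}
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("!")]
    i = 0
    while i < len(lines):
        if lines[i].strip() == "****":
            i += 1
            continue
        head = lines[i].split()
        element = head[0].capitalize()
        i += 1
        shells = []
        while i < len(lines) and lines[i].strip() != "****":
            parts = lines[i].split()
            letter = parts[0].upper()
            if letter not in _AM_LETTERS:
                raise ValueError(f"unknown shell type {parts[0]!r}")
            nprim = int(parts[1])
            i += 1
            exps, coefs = [], []
            for _ in range(nprim):
                vals = lines[i].replace("D", "E").replace("d", "e").split()
                exps.append(float(vals[0]))
                coefs.append(float(vals[1]))
                i += 1
            shells.append((_AM_LETTERS[letter], exps, coefs))
        blocks[element] = shells
        i += 1
    return blocks


def _parse_json(text: str) -> dict[str, list[tuple[int, list[float], list[float]]]]:
    data = json.loads(text)
    blocks = {}
    for element, shells in data["elements"].items():
        blocks[element.capitalize()] = [
            (int(sh["l"]), [float(x) for x in sh["exponents"]],
             [float(x) for x in sh["coefficients"]])
            for sh in shells
        ]
    return blocks


def basis_to_json(blocks) -> str:
    return json.dumps(
        {"elements": {el: [{"l": l, "exponents": e, "coefficients": c}
                           for (l, e, c) in shells]
                      for el, shells in blocks.items()}},
        indent=1,
    )


def _read_basis_source(name_or_path: str) -> str:
    key = str(name_or_path).lower()
    if key in _BUILTIN:
        return (resources.files("molhess.data") / _BUILTIN[key]).read_text()
    with open(name_or_path) as fh:
        return fh.read()


def load_basis(name_or_path: str, molecule: Molecule) -> AOBasis:
    """Load a basis by bundled name or file path and place it on a molecule.

    Shells are ordered by atom, then ascending angular momentum, then by
    file order; every contracted function is renormalized to unit
    self-overlap.
    """
    text = _read_basis_source(name_or_path)
    if text.lstrip().startswith("{"):
        blocks = _parse_json(text)
    else:
        blocks = _parse_g94(text)
    shells: list[GaussianShell] = []
    for atom, el in enumerate(molecule.elements):
        if el not in blocks:
            raise UnsupportedElementError(
                f"element {el} not present in basis {name_or_path}"
            )
        for l, exps, coefs in sorted(blocks[el], key=lambda t: t[0]):
            if l > MAX_L:
                raise UnsupportedAngularMomentumError(f"l={l} unsupported")
            e = np.asarray(exps, float)
            c = _normalize_shell(l, e, np.asarray(coefs, float))
            shells.append(GaussianShell(atom, l, e, c, molecule.coords[atom]))
    return AOBasis(molecule, shells)
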