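"""Cartesian <-> real solid-harmonic (spherical) shell transformations.

Cartesian components of angular momentum l are ordered lexicographically
(xx, xy, xz, yy, yz, zz for l=2); spherical components run m = -l..+l.
The transformation rows are real solid harmonics, generated once per l by
an exact symbolic recursion and normalized in closed form, so that a
transformed one-shell overlap block of a normalized shell is the
(2l+1)-dimensional identity.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

MAX_L = 4


class UnsupportedAngularMomentumError(ValueError):
    pass


def _check_l(l: int) -> None:
    if not (0 <= l <= MAX_L):
        raise UnsupportedAngularMomentumError(
            f"angular momentum l={l} outside supported range 0..{MAX_L}"
        )


@lru_cache(maxsize=None)
def cart_components(l: int) -> tuple[tuple[int, int, int], ...]:
    """Cartesian exponent triples (lx, ly, lz) in lexicographic order.

    Not capped at MAX_L: recursion intermediates reach higher l than the
    shells themselves.
    """
    if l < 0:
        raise UnsupportedAngularMomentumError(f"negative l={l}")
    comps = []
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            comps.append((lx, ly, l - lx - ly))
    return tuple(comps)


def n_cart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def n_sph(l: int) -> int:
    _check_l(l)
    return 2 * l + 1


def _df(n: int) -> int:
    """Double factorial with (-1)!! = 1."""
    r = 1
    while n > 1:
        r *= n
        n -= 2
    return r


@lru_cache(maxsize=None)
def _solid_harmonic_polys(l: int):
    """Real solid harmonics S_{l,m}, m=-l..l, as monomial-coefficient dicts.

    Built by the standard diagonal/vertical recursion on real solid
    harmonics, carried out exactly in sympy rationals.
    """
    import sympy as sp

    x, y, z = sp.symbols("x y z")
    r2 = x * x + y * y + z * z
    # table[l][m] -> sympy expression
    table = {0: {0: sp.Integer(1)}}
    for ll in range(l):
        nxt = {}
        top = table[ll][ll]
        bot = table[ll][-ll]
        fac = sp.sqrt(sp.Rational(2 * ll + 1, 2 * ll + 2) * (2 if ll == 0 else 1))
        cross = 0 if ll == 0 else 1
        nxt[ll + 1] = sp.expand(fac * (x * top - cross * y * bot))
        nxt[-(ll + 1)] = sp.expand(fac * (y * top + cross * x * bot))
        for m in range(-ll, ll + 1):
            term = (2 * ll + 1) * z * table[ll][m]
            if abs(m) <= ll - 1:
                term -= sp.sqrt(sp.Integer((ll + m) * (ll - m))) * r2 * table[ll - 1][m]
            nxt[m] = sp.expand(term / sp.sqrt(sp.Integer((ll + 1 + m) * (ll + 1 - m))))
        table[ll + 1] = nxt
    out = []
    for m in range(-l, l + 1):
        poly = sp.Poly(table[l][m], x, y, z)
        out.append({monom: float(coef) for monom, coef in zip(poly.monoms(), poly.coeffs())})
    return out


@lru_cache(maxsize=None)
def _one_shell_overlap_unit(l: int) -> np.ndarray:
    """Overlap of unit-normalized Cartesian components of one shell.

    Exponent-independent: entries are ratios of double-factorial products.
    """
    comps = cart_components(l)
    raw = np.zeros((len(comps), len(comps)))
    for i, a in enumerate(comps):
        for j, b in enumerate(comps):
            s = [a[k] + b[k] for k in range(3)]
            if all(v % 2 == 0 for v in s):
                raw[i, j] = _df(s[0] - 1) * _df(s[1] - 1) * _df(s[2] - 1)
    d = 1.0 / np.sqrt(np.diag(raw))
    return raw * d[:, None] * d[None, :]


@lru_cache(maxsize=None)
def _component_norms(l: int) -> np.ndarray:
    """Self-overlap of raw component (lx,ly,lz) relative to (l,0,0).

    sqrt of this ratio converts shell-normalized raw Cartesian integrals to
    unit-normalized Cartesian component integrals (and back).
    """
    comps = cart_components(l)
    ratios = np.array(
        [_df(2 * a[0] - 1) * _df(2 * a[1] - 1) * _df(2 * a[2] - 1) / _df(2 * l - 1)
         for a in comps]
    )
    return np.sqrt(ratios)


@lru_cache(maxsize=None)
def cart_to_spherical(l: int) -> np.ndarray:
    """(2l+1, ncart) matrix: rows express spherical AOs in unit-normalized
    Cartesian components.  l=0,1 reduce to identity-like maps."""
    _check_l(l)
    comps = cart_components(l)
    polys = _solid_harmonic_polys(l)
    norms = _component_norms(l)
    mat = np.zeros((2 * l + 1, len(comps)))
    for row, poly in enumerate(polys):
        for col, comp in enumerate(comps):
            if comp in poly:
                # raw-monomial coefficient -> unit-normalized component basis
                mat[row, col] = poly[comp] * norms[col]
    o_unit = _one_shell_overlap_unit(l)
    for row in range(mat.shape[0]):
        nrm = mat[row] @ o_unit @ mat[row]
        mat[row] /= np.sqrt(nrm)
    mat.setflags(write=False)
    return mat


@lru_cache(maxsize=None)
def cart_to_spherical_raw(l: int) -> np.ndarray:
    """Transformation acting on raw shell-normalized Cartesian integral
    indices (the convention the integral recursions produce)."""
    return cart_to_spherical(l) / _component_norms(l)[None, :]
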