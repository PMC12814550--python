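"""Independent brute-force reference implementations used by the tests.

Everything here deliberately avoids the production recursion kernels:

* ERIs come from a McMurchie-Davidson Hermite expansion evaluated per
  primitive quartet, fully in Cartesian representation, contracted only
  at the very end (a late-contraction reference path).
* The Boys function is obtained from the regularized incomplete gamma
  function of scipy.
* Derivatives are checked with central finite differences (2- or 4-point
  stencils) of user-supplied evaluators.

These paths are orders of magnitude slower than the production engine
and are meant for fixture-sized problems only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import gamma, gammainc

from .basis import AOBasis, GaussianShell
from .spherical import cart_components, cart_to_spherical_raw


def boys_reference(m_max: int, T: float) -> np.ndarray:
    """Boys function from the lower incomplete gamma function."""
    out = np.empty(m_max + 1)
    if T < 1e-14:
        return 1.0 / (2 * np.arange(m_max + 1) + 1.0)
    for m in range(m_max + 1):
        out[m] = gamma(m + 0.5) * gammainc(m + 0.5, T) / (2 * T ** (m + 0.5))
    return out


def _md_e(i: int, j: int, t: int, Qx: float, a: float, b: float) -> float:
    """Hermite expansion coefficient E_t^{ij} (recursive, scalar)."""
    p = a + b
    q = a * b / p
    if t < 0 or t > i + j:
        return 0.0
    if i == j == t == 0:
        return math.exp(-q * Qx * Qx)
    if j == 0:
        return (_md_e(i - 1, j, t - 1, Qx, a, b) / (2 * p)
                - q * Qx / a * _md_e(i - 1, j, t, Qx, a, b)
                + (t + 1) * _md_e(i - 1, j, t + 1, Qx, a, b))
    return (_md_e(i, j - 1, t - 1, Qx, a, b) / (2 * p)
            + q * Qx / b * _md_e(i, j - 1, t, Qx, a, b)
            + (t + 1) * _md_e(i, j - 1, t + 1, Qx, a, b))


def _md_r(t, u, v, n, p, PQ, Fm) -> float:
    if t < 0 or u < 0 or v < 0:
        return 0.0
    if t == u == v == 0:
        return (-2.0 * p) ** n * Fm[n]
    if t > 0:
        return ((t - 1) * _md_r(t - 2, u, v, n + 1, p, PQ, Fm)
                + PQ[0] * _md_r(t - 1, u, v, n + 1, p, PQ, Fm))
    if u > 0:
        return ((u - 1) * _md_r(t, u - 2, v, n + 1, p, PQ, Fm)
                + PQ[1] * _md_r(t, u - 1, v, n + 1, p, PQ, Fm))
    return ((v - 1) * _md_r(t, u, v - 2, n + 1, p, PQ, Fm)
            + PQ[2] * _md_r(t, u, v - 1, n + 1, p, PQ, Fm))


def primitive_eri_md(ca, cb, cc, cd, a, b, c, d, A, B, C, D) -> float:
    """(ab|cd) over four primitive Cartesian Gaussians (unnormalized)."""
    p = a + b
    q = c + d
    alpha = p * q / (p + q)
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    PQ = P - Q
    mtot = sum(ca) + sum(cb) + sum(cc) + sum(cd)
    Fm = boys_reference(mtot, alpha * float(PQ @ PQ))
    val = 0.0
    for t in range(ca[0] + cb[0] + 1):
        E1 = _md_e(ca[0], cb[0], t, A[0] - B[0], a, b)
        if E1 == 0.0:
            continue
        for u in range(ca[1] + cb[1] + 1):
            E2 = _md_e(ca[1], cb[1], u, A[1] - B[1], a, b)
            if E2 == 0.0:
                continue
            for v in range(ca[2] + cb[2] + 1):
                E3 = _md_e(ca[2], cb[2], v, A[2] - B[2], a, b)
                if E3 == 0.0:
                    continue
                for tt in range(cc[0] + cd[0] + 1):
                    E4 = _md_e(cc[0], cd[0], tt, C[0] - D[0], c, d)
                    if E4 == 0.0:
                        continue
                    for uu in range(cc[1] + cd[1] + 1):
                        E5 = _md_e(cc[1], cd[1], uu, C[1] - D[1], c, d)
                        if E5 == 0.0:
                            continue
                        for vv in range(cc[2] + cd[2] + 1):
                            E6 = _md_e(cc[2], cd[2], vv, C[2] - D[2], c, d)
                            if E6 == 0.0:
                                continue
                            val += (E1 * E2 * E3 * E4 * E5 * E6
                                    * (-1) ** (tt + uu + vv)
                                    * _md_r(t + tt, u + uu, v + vv, 0,
                                            alpha, PQ, Fm))
    return val * 2 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))


def eri_quartet_reference(sha: GaussianShell, shb: GaussianShell,
                          shc: GaussianShell, shd: GaussianShell) -> np.ndarray:
    """Late-contraction reference ERI block in the spherical basis.

    All recursions run per primitive quartet in pure Cartesian form;
    contraction happens only at the very end, followed by a single
    Cartesian-to-spherical transformation of all four indices.
    """
    comps = [cart_components(sh.l) for sh in (sha, shb, shc, shd)]
    shape = tuple(len(c) for c in comps)
    cart = np.zeros(shape)
    for ia, ea in enumerate(sha.exponents):
        for ib, eb in enumerate(shb.exponents):
            for ic, ec in enumerate(shc.exponents):
                for id_, ed in enumerate(shd.exponents):
                    w = (sha.coefficients[ia] * shb.coefficients[ib]
                         * shc.coefficients[ic] * shd.coefficients[id_])
                    for p, ca in enumerate(comps[0]):
                        for q, cb in enumerate(comps[1]):
                            for r, cc in enumerate(comps[2]):
                                for s, cd in enumerate(comps[3]):
                                    cart[p, q, r, s] += w * primitive_eri_md(
                                        ca, cb, cc, cd, ea, eb, ec, ed,
                                        sha.center, shb.center,
                                        shc.center, shd.center)
    t = [cart_to_spherical_raw(sh.l) for sh in (sha, shb, shc, shd)]
    return np.einsum("ip,jq,kr,ls,pqrs->ijkl", t[0], t[1], t[2], t[3], cart)


# --------------------------------------------------------- dense CPHF solve

def dense_cphf_solve(scf, rhs) -> np.ndarray:
    """Direct dense solution of the coupled-perturbed HF equations.

    Builds the explicit orbital-Hessian action from the full MO-basis ERI
    tensor and solves all right-hand sides with a dense linear solve.
    Feasible for n_occ*n_virt up to ~2000.
    """
    from .eri import full_eri_tensor

    no, nv = scf.n_occ, scf.n_virt
    dim = no * nv
    if dim > 2000:
        raise ValueError(f"dense CPHF dimension {dim} too large")
    g_ao = full_eri_tensor(scf.basis)
    C = scf.C
    g_mo = np.einsum("mp,nq,mnts,tr,sw->pqrw", C, C, g_ao, C, C,
                     optimize=True)
    o = slice(0, no)
    v = slice(no, no + nv)
    eps = scf.eps
    de = eps[o][None, :] - eps[v][:, None]          # (nv, no)
    # L[ai,bj] = (eps_i - eps_a) delta - [4(ai|bj) - c_x (ab|ji) - c_x (aj|bi)]
    cx = scf.c_x
    A = (4.0 * g_mo[v, o, v, o]
         - cx * np.einsum("abji->aibj", g_mo[v, v, o, o])
         - cx * np.einsum("ajbi->aibj", g_mo[v, o, v, o]))
    L = np.diag(de.ravel()) - A.reshape(dim, dim)
    w = np.linalg.eigvalsh(0.5 * (L + L.T))
    if np.abs(w).min() < 1e-10:
        raise np.linalg.LinAlgError("singular CPHF system")
    R = rhs.R.reshape(-1, dim)
    U = np.linalg.solve(L, R.T).T
    return U.reshape(rhs.R.shape)


# ---------------------------------------------------------------- FD schemes

@dataclass
class FDScheme:
    """Central finite-difference scheme for geometric derivatives."""

    step: float = 1e-3
    stencil: int = 2  # 2- or 4-point central

    def first(self, f: Callable[[float], float]) -> float:
        h = self.step
        if self.stencil == 4:
            return (f(-2 * h) - 8 * f(-h) + 8 * f(h) - f(2 * h)) / (12 * h)
        return (f(h) - f(-h)) / (2 * h)

    def second(self, f: Callable[[float], float]) -> float:
        h = self.step
        return (f(h) - 2 * f(0.0) + f(-h)) / (h * h)


def fd_derivative(f, molecule, atom: int, component: int, order: int = 1,
                  step: float = 1e-3, stencil: int = 2):
    """Central finite difference of f(molecule) w.r.t. one nuclear
    coordinate.  f may return a scalar or an ndarray; an error estimate
    from step halving accompanies first derivatives."""
    scheme = FDScheme(step, stencil)

    def g(h):
        return f(molecule.displaced(atom, component, h))

    if order == 1:
        val = scheme.first(g)
        half = FDScheme(step / 2, stencil).first(g)
        return val, np.max(np.abs(np.asarray(val) - np.asarray(half)))
    if order == 2:
        return scheme.second(g), None
    raise ValueError("order must be 1 or 2")


def fd_gradient(f, molecule, step: float = 1e-3, stencil: int = 2) -> np.ndarray:
    """FD nuclear gradient of a scalar function of geometry, (n_atoms, 3)."""
    g = np.zeros((molecule.n_atoms, 3))
    for a in range(molecule.n_atoms):
        for d in range(3):
            g[a, d] = fd_derivative(f, molecule, a, d, 1, step, stencil)[0]
    return g
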