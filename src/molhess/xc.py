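"""Numerical exchange-correlation layer.

Molecular quadrature grid (Gauss-Chebyshev radial shells, product
Gauss-Legendre x uniform-phi angular shells, Becke fuzzy-cell
partitioning), a pluggable functional-derivative provider interface, the
XC energy/potential, the frozen-density XC contributions to the Hessian,
the perturbed XC matrix entering the coupled-perturbed right-hand sides,
and the XC kernel contraction used by the response solver.

Spin convention: closed shell throughout, quantities are alpha-resolved
(rho_a = rho/2, sigma_aa = grad rho_a . grad rho_a); the functional
provider returns all spin-resolved derivative channels so that the
chain-rule assemblies below can keep the alpha/beta bookkeeping explicit.

Geometric derivatives of the grid weights are excluded (fixed-weight
approximation): all derivative formulas below hold at frozen quadrature
weights and points, and the finite-difference oracles in the test suite
apply the same convention.  A numeric strict mode that rebuilds the grid
is available for the gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .basis import AOBasis
from .molecule import Molecule
from .spherical import cart_components, cart_to_spherical_raw

# Bragg-Slater-like radial scale parameters (angstrom -> bohr on use)
_RADII_ANG = {"H": 0.35, "He": 0.35, "Li": 1.45, "Be": 1.05, "B": 0.85,
              "C": 0.70, "N": 0.65, "O": 0.60, "F": 0.50, "Ne": 0.45,
              "Na": 1.80, "Mg": 1.50, "P": 1.00, "S": 1.00, "Cl": 1.00}

_LEVELS = {"coarse": (30, 8), "medium": (60, 16), "fine": (75, 18),
           "veryfine": (95, 24)}


class GridConfigError(ValueError):
    pass


class FunctionalCapabilityError(RuntimeError):
    pass


@dataclass
class MolecularGrid:
    points: np.ndarray            # (N, 3) bohr
    weights: np.ndarray           # (N,) bohr^3
    level: str
    molecule: Molecule


def _radial_shell(n_rad: int, R: float):
    """Gauss-Chebyshev (2nd kind) radial points with the Becke map
    r = R (1+x)/(1-x)."""
    i = np.arange(1, n_rad + 1)
    x = np.cos(i * math.pi / (n_rad + 1))
    w_cheb = math.pi / (n_rad + 1) * np.sin(i * math.pi / (n_rad + 1)) ** 2
    w_x = w_cheb / np.sqrt(1.0 - x * x)          # for plain dx integration
    r = R * (1.0 + x) / (1.0 - x)
    drdx = 2.0 * R / (1.0 - x) ** 2
    w_r = w_x * drdx * r * r
    return r, w_r


@lru_cache(maxsize=None)
def _angular_shell(n_theta: int):
    """Product quadrature on the unit sphere, exact for spherical
    harmonics up to degree 2*n_theta - 1."""
    t, wt = np.polynomial.legendre.leggauss(n_theta)
    phi = (np.arange(2 * n_theta) + 0.5) * math.pi / n_theta
    ct = t[:, None] * np.ones_like(phi)[None, :]
    st = np.sqrt(1 - t * t)[:, None] * np.ones_like(phi)[None, :]
    x = (st * np.cos(phi)[None, :]).ravel()
    y = (st * np.sin(phi)[None, :]).ravel()
    z = ct.ravel()
    w = (wt[:, None] * np.ones_like(phi)[None, :]).ravel() \
        * (math.pi / n_theta)
    return np.stack([x, y, z], axis=1), w


def _becke_weights(molecule: Molecule, parent: int, pts: np.ndarray
                   ) -> np.ndarray:
    """Becke fuzzy-cell partition-of-unity weight of ``parent`` at pts."""
    coords = molecule.coords
    na = molecule.n_atoms
    if na == 1:
        return np.ones(len(pts))
    dist = np.stack([np.linalg.norm(pts - coords[a], axis=1)
                     for a in range(na)])
    P = np.ones((na, len(pts)))
    for a in range(na):
        for b in range(na):
            if a == b:
                continue
            Rab = np.linalg.norm(coords[a] - coords[b])
            mu = (dist[a] - dist[b]) / Rab
            f = mu
            for _ in range(3):
                f = 1.5 * f - 0.5 * f ** 3
            P[a] *= 0.5 * (1.0 - f)
    return P[parent] / P.sum(axis=0)


def build_grid(molecule: Molecule, level: str = "fine") -> MolecularGrid:
    """Atom-centered molecular quadrature grid with Becke partitioning."""
    if level not in _LEVELS:
        raise GridConfigError(
            f"unknown grid level {level!r}; choose from {sorted(_LEVELS)}")
    n_rad, n_theta = _LEVELS[level]
    ang_pts, ang_w = _angular_shell(n_theta)
    all_pts, all_w = [], []
    for a, el in enumerate(molecule.elements):
        R = _RADII_ANG.get(el, 0.80) / 0.529177210903
        r, w_r = _radial_shell(n_rad, R)
        pts = (r[:, None, None] * ang_pts[None, :, :]).reshape(-1, 3) \
            + molecule.coords[a]
        w = (w_r[:, None] * ang_w[None, :]).ravel()
        w = w * _becke_weights(molecule, a, pts)
        keep = w > 1e-16
        all_pts.append(pts[keep])
        all_w.append(w[keep])
    return MolecularGrid(np.concatenate(all_pts), np.concatenate(all_w),
                         level, molecule)


# ----------------------------------------------------------- AOs on the grid

def _shell_monomials(shell):
    """Primitive monomial-Gaussian expansion [(coef, lx, ly, lz, alpha)]
    per raw Cartesian component of a shell."""
    out = []
    for (lx, ly, lz) in cart_components(shell.l):
        terms = [(float(c), lx, ly, lz, float(a))
                 for c, a in zip(shell.coefficients, shell.exponents)]
        out.append(terms)
    return out


def _diff_terms(terms, axis):
    """d/dx_axis of a monomial-Gaussian term list."""
    out = {}
    for (c, lx, ly, lz, a) in terms:
        l = (lx, ly, lz)
        if l[axis] > 0:
            low = list(l)
            low[axis] -= 1
            key = (tuple(low), a)
            out[key] = out.get(key, 0.0) + c * l[axis]
        up = list(l)
        up[axis] += 1
        key = (tuple(up), a)
        out[key] = out.get(key, 0.0) - 2.0 * a * c
    return [(c, lx, ly, lz, a) for ((lx, ly, lz), a), c in out.items()
            if c != 0.0]


def _eval_terms(terms, d, r2):
    """Evaluate a term list on points; d = pts - center (N,3), r2 = |d|^2."""
    val = np.zeros(len(r2))
    for (c, lx, ly, lz, a) in terms:
        t = c * np.exp(-a * r2)
        if lx:
            t = t * d[:, 0] ** lx
        if ly:
            t = t * d[:, 1] ** ly
        if lz:
            t = t * d[:, 2] ** lz
        val += t
    return val


def ao_values(basis: AOBasis, points: np.ndarray, order: int = 1):
    """Spherical AO values and Cartesian derivatives on grid points.

    Returns [ao0 (nao,N), ao1 (3,nao,N), ao2 (3,3,nao,N),
    ao3 (3,3,3,nao,N)] truncated at ``order``.
    """
    n = basis.n_ao
    N = len(points)
    out = [np.zeros((n, N))]
    if order >= 1:
        out.append(np.zeros((3, n, N)))
    if order >= 2:
        out.append(np.zeros((3, 3, n, N)))
    if order >= 3:
        out.append(np.zeros((3, 3, 3, n, N)))
    for sh, off in zip(basis.shells, basis.ao_offsets):
        d = points - sh.center
        r2 = (d * d).sum(axis=1)
        mono = _shell_monomials(sh)
        T = cart_to_spherical_raw(sh.l)
        cart0 = np.stack([_eval_terms(t, d, r2) for t in mono])
        sph = T @ cart0
        out[0][off:off + sh.n_sph] = sph
        if order >= 1:
            d1 = [[_diff_terms(t, ax) for t in mono] for ax in range(3)]
            for ax in range(3):
                cart = np.stack([_eval_terms(t, d, r2) for t in d1[ax]])
                out[1][ax, off:off + sh.n_sph] = T @ cart
        if order >= 2:
            d2 = [[[_diff_terms(t, ay) for t in d1[ax]] for ay in range(3)]
                  for ax in range(3)]
            for ax in range(3):
                for ay in range(3):
                    cart = np.stack([_eval_terms(t, d, r2)
                                     for t in d2[ax][ay]])
                    out[2][ax, ay, off:off + sh.n_sph] = T @ cart
        if order >= 3:
            for ax in range(3):
                for ay in range(3):
                    d3 = [[_diff_terms(t, az) for t in d2[ax][ay]]
                          for az in range(3)]
                    for az in range(3):
                        cart = np.stack([_eval_terms(t, d, r2)
                                         for t in d3[az]])
                        out[3][ax, ay, az, off:off + sh.n_sph] = T @ cart
    return out


# ------------------------------------------------------ functional providers

@dataclass
class FunctionalEval:
    """Pointwise functional derivatives (spin-resolved channels).

    Arrays over grid points; absent second derivatives mean the provider
    cannot serve Hessian/response assemblies.
    """

    f: np.ndarray                  # energy density integrand
    f_ra: np.ndarray
    f_saa: np.ndarray
    f_sab: np.ndarray
    # second derivatives
    f_rara: np.ndarray | None = None
    f_rarb: np.ndarray | None = None
    f_rasaa: np.ndarray | None = None
    f_rasab: np.ndarray | None = None
    f_rasbb: np.ndarray | None = None
    f_rbsaa: np.ndarray | None = None
    f_rbsab: np.ndarray | None = None
    f_saasaa: np.ndarray | None = None
    f_saasab: np.ndarray | None = None
    f_saasbb: np.ndarray | None = None
    f_sabsab: np.ndarray | None = None
    f_sabsbb: np.ndarray | None = None

    def require_second(self):
        for name in ("f_rara", "f_rarb", "f_rasaa", "f_rasab", "f_rasbb",
                     "f_rbsaa", "f_rbsab", "f_saasaa", "f_saasab",
                     "f_saasbb", "f_sabsab", "f_sabsbb"):
            if getattr(self, name) is None:
                raise FunctionalCapabilityError(
                    f"functional lacks second derivative {name}")


class SlaterExchange:
    """Dirac/Slater LDA exchange, spin-resolved closed form."""

    name = "slater-x"
    gga = False

    def evaluate(self, rho_a: np.ndarray, sigma_aa: np.ndarray
                 ) -> FunctionalEval:
        cs = -0.75 * (6.0 / math.pi) ** (1.0 / 3.0)
        r = np.maximum(rho_a, 1e-250)
        z = np.zeros_like(r)
        return FunctionalEval(
            f=2.0 * cs * r ** (4.0 / 3.0),
            f_ra=(4.0 / 3.0) * cs * r ** (1.0 / 3.0),
            f_saa=z, f_sab=z,
            f_rara=(4.0 / 9.0) * cs * r ** (-2.0 / 3.0),
            f_rarb=z, f_rasaa=z, f_rasab=z, f_rasbb=z, f_rbsaa=z,
            f_rbsab=z, f_saasaa=z, f_saasab=z, f_saasbb=z, f_sabsab=z,
            f_sabsbb=z)


class ToyDensitySquared:
    """Analytic test functional f = c (rho_a^2 + rho_b^2)."""

    name = "toy-rho2"
    gga = False

    def __init__(self, c: float = 0.1):
        self.c = c

    def evaluate(self, rho_a, sigma_aa) -> FunctionalEval:
        z = np.zeros_like(rho_a)
        return FunctionalEval(
            f=2.0 * self.c * rho_a ** 2,
            f_ra=2.0 * self.c * rho_a,
            f_saa=z, f_sab=z,
            f_rara=2.0 * self.c * np.ones_like(rho_a),
            f_rarb=z, f_rasaa=z, f_rasab=z, f_rasbb=z, f_rbsaa=z,
            f_rbsab=z, f_saasaa=z, f_saasab=z, f_saasbb=z, f_sabsab=z,
            f_sabsbb=z)


class ToySigma:
    """Analytic test GGA functional f = c (sigma_aa + sigma_bb)."""

    name = "toy-sigma"
    gga = True

    def __init__(self, c: float = 0.05):
        self.c = c

    def evaluate(self, rho_a, sigma_aa) -> FunctionalEval:
        z = np.zeros_like(rho_a)
        c = self.c * np.ones_like(rho_a)
        return FunctionalEval(
            f=2.0 * self.c * sigma_aa,
            f_ra=z, f_saa=c, f_sab=z,
            f_rara=z, f_rarb=z, f_rasaa=z, f_rasab=z, f_rasbb=z,
            f_rbsaa=z, f_rbsab=z, f_saasaa=z, f_saasab=z, f_saasbb=z,
            f_sabsab=z, f_sabsbb=z)


FUNCTIONALS = {"slater-x": SlaterExchange, "toy-rho2": ToyDensitySquared,
               "toy-sigma": ToySigma}


# ------------------------------------------------------------ grid densities

def _density(D, ao0, ao1=None):
    """rho_a and (optionally) grad rho_a from the total density matrix."""
    half = 0.5 * D
    tmp = half @ ao0
    rho_a = (ao0 * tmp).sum(axis=0)
    if ao1 is None:
        return rho_a, None
    grad_a = 2.0 * np.einsum("xmp,mp->xp", ao1, tmp)
    return rho_a, grad_a


def _rho_xi(D, basis, ao, atom, comp):
    """Explicit basis-derivative parts rho_a^(xi) and (grad rho_a)^(xi)
    at frozen density matrix, for xi = (atom, comp)."""
    ao0, ao1, ao2 = ao[0], ao[1], ao[2]
    mask = basis.ao_atom_map() == atom
    Dm = 0.5 * D[mask]              # alpha block rows on the atom
    t = Dm @ ao0                    # (nA, N)
    a1 = ao1[comp][mask]
    rho_xi = -2.0 * (a1 * t).sum(axis=0)
    grad_xi = np.empty((3, len(rho_xi)))
    for e in range(3):
        u_e = Dm @ ao1[e]
        grad_xi[e] = -2.0 * ((ao2[e, comp][mask] * t).sum(axis=0)
                             + (a1 * u_e).sum(axis=0))
    return rho_xi, grad_xi


def _rho_xi_zeta(D, basis, ao, atom_a, comp_d, atom_b, comp_e,
                 need_grad: bool = True):
    """Second explicit basis-derivative parts rho_a^(xi,zeta) and
    (grad rho_a)^(xi,zeta) at frozen density matrix."""
    ao0, ao1, ao2 = ao[0], ao[1], ao[2]
    ao3 = ao[3] if need_grad else None
    amap = basis.ao_atom_map()
    ma = amap == atom_a
    mb = amap == atom_b
    Dab = 0.5 * D[ma][:, mb]
    N = ao0.shape[1]
    rho = np.zeros(N)
    grad = np.zeros((3, N)) if need_grad else None
    # cross term: both derivatives on different functions
    v_e = Dab @ ao1[comp_e][mb]
    rho += 2.0 * (ao1[comp_d][ma] * v_e).sum(axis=0)
    if need_grad:
        for g in range(3):
            w_ge = Dab @ ao2[g, comp_e][mb]
            grad[g] += 2.0 * ((ao2[g, comp_d][ma] * v_e).sum(axis=0)
                              + (ao1[comp_d][ma] * w_ge).sum(axis=0))
    # same-center term: both derivatives on one function
    if atom_a == atom_b:
        Dm = 0.5 * D[ma]
        t = Dm @ ao0
        rho += 2.0 * (ao2[comp_d, comp_e][ma] * t).sum(axis=0)
        if need_grad:
            for g in range(3):
                u_g = Dm @ ao1[g]
                grad[g] += 2.0 * (
                    (ao3[g, comp_d, comp_e][ma] * t).sum(axis=0)
                    + (ao2[comp_d, comp_e][ma] * u_g).sum(axis=0))
    return rho, grad


def _coefs(fe: FunctionalEval):
    """Recurring closed-shell coefficient groupings of the chain rule."""
    return {
        "gga": 2.0 * fe.f_saa + fe.f_sab,
        "rr": None if fe.f_rara is None else fe.f_rara + fe.f_rarb,
        "rs": None if fe.f_rasaa is None
        else fe.f_rasaa + fe.f_rasab + fe.f_rasbb,
        "sr": None if fe.f_rasaa is None
        else 2.0 * fe.f_rasaa + fe.f_rasab + 2.0 * fe.f_rbsaa + fe.f_rbsab,
        "ss": None if fe.f_saasaa is None
        else (2.0 * fe.f_saasaa + 3.0 * fe.f_saasab + fe.f_sabsab
              + 2.0 * fe.f_saasbb + fe.f_sabsbb),
    }


def _evaluate(D, basis, grid, functional, order: int):
    ao = ao_values(basis, grid.points, order)
    rho_a, grad_a = _density(D, ao[0], ao[1] if order >= 1 else None)
    sigma_aa = (grad_a * grad_a).sum(axis=0) if grad_a is not None \
        else np.zeros_like(rho_a)
    fe = functional.evaluate(rho_a, sigma_aa)
    return ao, rho_a, grad_a, fe


def xc_energy(D, basis, grid, functional) -> float:
    ao, rho_a, grad_a, fe = _evaluate(D, basis, grid, functional, 1)
    return float(grid.weights @ fe.f)


def xc_energy_matrix(D, basis, grid, functional):
    """XC energy and potential matrix for the SCF Fock operator."""
    ao, rho_a, grad_a, fe = _evaluate(D, basis, grid, functional, 1)
    w = grid.weights
    E = float(w @ fe.f)
    a = w * fe.f_ra
    V = (ao[0] * a) @ ao[0].T
    coef = _coefs(fe)["gga"]
    for e in range(3):
        b = w * coef * grad_a[e]
        half = (ao[1][e] * b) @ ao[0].T
        V += half + half.T
    return E, 0.5 * (V + V.T)


def xc_gradient(D, basis, grid, functional,
                weight_derivatives: bool = False) -> np.ndarray:
    """Frozen-density XC nuclear gradient (fixed-weight approximation).

    With weight_derivatives=True the quadrature-motion contribution is
    added numerically by rebuilding the grid at displaced geometries.
    """
    ao, rho_a, grad_a, fe = _evaluate(D, basis, grid, functional, 2)
    w = grid.weights
    coef = _coefs(fe)["gga"]
    na = basis.molecule.n_atoms
    out = np.zeros((na, 3))
    for a in range(na):
        for d in range(3):
            rho_xi, grad_xi = _rho_xi(D, basis, ao, a, d)
            X = (grad_a * grad_xi).sum(axis=0)
            out[a, d] = 2.0 * (w * (fe.f_ra * rho_xi + coef * X)).sum()
    if weight_derivatives:
        out += _weight_motion_correction(D, basis, grid, functional)
    return out


def _weight_motion_correction(D, basis, grid, functional,
                              step: float = 1e-4) -> np.ndarray:
    """Numeric difference between the full frozen-density derivative
    (grid rebuilt with the nuclei) and the fixed-weight derivative."""
    from .basis import load_basis  # noqa: F401  (geometry rebuild below)

    mol = basis.molecule
    na = mol.n_atoms
    out = np.zeros((na, 3))
    for a in range(na):
        for d in range(3):
            vals = []
            for s in (step, -step):
                m2 = mol.displaced(a, d, s)
                b2 = _rebuild_basis(basis, m2)
                g2 = build_grid(m2, grid.level)
                vals.append(xc_energy(D, b2, g2, functional))
                # fixed-grid energy at the same displaced basis
                vals.append(xc_energy(D, b2, grid, functional))
            full = (vals[0] - vals[2]) / (2 * step)
            frozen = (vals[1] - vals[3]) / (2 * step)
            out[a, d] = full - frozen
    return out


def _rebuild_basis(basis: AOBasis, mol2: Molecule) -> AOBasis:
    import copy

    shells = []
    for sh in basis.shells:
        new = copy.copy(sh)
        new.center = mol2.coords[sh.center_index]
        shells.append(new)
    return AOBasis(mol2, shells)


_H_TERMS = ("rho_rho", "rho_sigma", "rho_second_deriv", "sigma_rho", "sigma_sigma", "grad_dot_grad", "grad_second_deriv")
_F_TERMS = ("kernel_rho", "kernel_sigma", "moved_basis_local", "gga_kernel_rho", "gga_kernel_sigma", "perturbed_gradient", "moved_basis_gga")


def xc_hessian_terms(D, basis, grid, functional, terms=None) -> np.ndarray:
    """Frozen-density XC contribution to the Hessian, (na, 3, na, 3).

    The chain-rule expansion of 2 d/dzeta of the fixed-weight integrand
    [f_ra rho^(xi) + (2 f_saa + f_sab) grad rho . (grad rho)^(xi)]:
    density-density and density-sigma kernel couplings ('rho_rho',
    'rho_sigma'), the explicit rho^(xi,zeta) term ('rho_second_deriv'),
    and the four GGA terms ('sigma_rho', 'sigma_sigma', 'grad_dot_grad',
    'grad_second_deriv', the last carrying (grad rho)^(xi,zeta)).
    ``terms`` selects a subset (all by default).
    """
    terms = set(_H_TERMS if terms is None else terms)
    need_order = 3 if functional.gga else 2
    ao, rho_a, grad_a, fe = _evaluate(D, basis, grid, functional, need_order)
    fe.require_second()
    c = _coefs(fe)
    w = grid.weights
    na = basis.molecule.n_atoms
    pre = [[None] * 3 for _ in range(na)]
    for a in range(na):
        for d in range(3):
            rho_xi, grad_xi = _rho_xi(D, basis, ao, a, d)
            X = (grad_a * grad_xi).sum(axis=0)
            pre[a][d] = (rho_xi, grad_xi, X)
    H = np.zeros((na, 3, na, 3))
    for a in range(na):
        for d in range(3):
            rho_x, grad_x, Xx = pre[a][d]
            for b in range(na):
                for e in range(3):
                    if (b, e) < (a, d):
                        continue
                    rho_z, grad_z, Xz = pre[b][e]
                    val = np.zeros_like(rho_a)
                    if "rho_rho" in terms:
                        val += c["rr"] * rho_x * rho_z
                    if "rho_sigma" in terms:
                        val += c["rs"] * rho_x * (2.0 * Xz)
                    if "sigma_rho" in terms:
                        val += c["sr"] * Xx * rho_z
                    if "sigma_sigma" in terms:
                        val += c["ss"] * Xx * (2.0 * Xz)
                    if "grad_dot_grad" in terms:
                        val += c["gga"] * (grad_x * grad_z).sum(axis=0)
                    if "rho_second_deriv" in terms or "grad_second_deriv" in terms:
                        rho_xz, grad_xz = _rho_xi_zeta(
                            D, basis, ao, a, d, b, e,
                            need_grad="grad_second_deriv" in terms and functional.gga)
                        if "rho_second_deriv" in terms:
                            val += fe.f_ra * rho_xz
                        if "grad_second_deriv" in terms and grad_xz is not None:
                            val += c["gga"] * (grad_a * grad_xz).sum(axis=0)
                    hv = 2.0 * float(w @ val)
                    H[a, d, b, e] = hv
                    H[b, e, a, d] = hv
    return H


def xc_fock_derivative(D, basis, grid, functional, terms=None) -> np.ndarray:
    """Perturbed XC matrix d v^xc_mn / d xi at frozen density,
    (na, 3, n_ao, n_ao); enters the coupled-perturbed right-hand sides.

    Terms: density-response couplings through the kernel ('kernel_rho',
    'kernel_sigma', 'gga_kernel_rho', 'gga_kernel_sigma'), the moved
    basis-function terms ('moved_basis_local', 'moved_basis_gga'), and
    the perturbed density gradient term ('perturbed_gradient').
    """
    terms = set(_F_TERMS if terms is None else terms)
    ao, rho_a, grad_a, fe = _evaluate(D, basis, grid, functional, 2)
    fe.require_second()
    c = _coefs(fe)
    w = grid.weights
    na = basis.molecule.n_atoms
    n = basis.n_ao
    amap = basis.ao_atom_map()
    out = np.zeros((na, 3, n, n))
    ao0, ao1, ao2 = ao[0], ao[1], ao[2]
    for a in range(na):
        mask = amap == a
        for d in range(3):
            rho_xi, grad_xi = _rho_xi(D, basis, ao, a, d)
            sig_xi = 2.0 * (grad_a * grad_xi).sum(axis=0)
            # scalar channel multiplying chi_m chi_n
            s = np.zeros_like(rho_a)
            if "kernel_rho" in terms:
                s += c["rr"] * rho_xi
            if "kernel_sigma" in terms:
                s += c["rs"] * sig_xi
            V = (ao0 * (w * s)) @ ao0.T
            # channel multiplying grad rho . grad(chi_m chi_n)
            g = np.zeros_like(rho_a)
            if "gga_kernel_rho" in terms:
                g += c["sr"] * rho_xi
            if "gga_kernel_sigma" in terms:
                g += c["ss"] * sig_xi
            for e in range(3):
                be = w * g * grad_a[e]
                half = (ao1[e] * be) @ ao0.T
                V += half + half.T
            if "perturbed_gradient" in terms:
                for e in range(3):
                    be = w * c["gga"] * grad_xi[e]
                    half = (ao1[e] * be) @ ao0.T
                    V += half + half.T
            if "moved_basis_local" in terms:
                am = ao0.copy()
                half = -(ao1[d][mask] * (w * fe.f_ra)[None, :]) @ ao0.T
                V[mask] += half
                V[:, mask] += half.T
            if "moved_basis_gga" in terms:
                # (grad(chi_m chi_n))^(xi): differentiate the moved AO
                for e in range(3):
                    be = w * c["gga"] * grad_a[e]
                    h1 = -(ao2[e, d][mask] * be) @ ao0.T
                    h2 = -(ao1[d][mask] * be) @ ao1[e].T
                    V[mask] += h1 + h2
                    V[:, mask] += (h1 + h2).T
            out[a, d] = 0.5 * (V + V.T)
    return out


def xc_kernel_contraction(X_ao, D, basis, grid, functional) -> np.ndarray:
    """f^xc[X]: XC kernel contraction of a total-density perturbation
    X_ao; the XC part of the auxiliary Fock matrix.  Linear in X."""
    ao, rho_a, grad_a, fe = _evaluate(D, basis, grid, functional, 1)
    fe.require_second()
    c = _coefs(fe)
    w = grid.weights
    ao0, ao1 = ao[0], ao[1]
    Xh = 0.5 * np.asarray(X_ao)
    t = Xh @ ao0
    rho_t = (ao0 * t).sum(axis=0)
    grad_t = np.stack([2.0 * (ao1[e] * (0.5 * (Xh + Xh.T) @ ao0)).sum(axis=0)
                       for e in range(3)])
    sig_t = 2.0 * (grad_a * grad_t).sum(axis=0)
    s = c["rr"] * rho_t + c["rs"] * sig_t
    V = (ao0 * (w * s)) @ ao0.T
    g = c["sr"] * rho_t + c["ss"] * sig_t
    for e in range(3):
        be = w * (g * grad_a[e] + c["gga"] * grad_t[e])
        half = (ao1[e] * be) @ ao0.T
        V += half + half.T
    return 0.5 * (V + V.T)
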