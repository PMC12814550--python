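"""Coupled-perturbed Hartree-Fock/Kohn-Sham equations for nuclear
displacements.

For each of the 3N perturbations xi the occupied-virtual response U_ai
solves

    (eps_i - eps_a) U_ai - G_ai[U] = R_ai,
    R_ai = F^(xi)_ai - eps_i S^(xi)_ai + G_ai[D^S],

where F^(xi) is the frozen-density derivative Fock matrix, D^S is the
occupied-occupied relaxation density -2 C_o S^(xi),occ C_o^T fixed by the
orthonormality condition (U_ij = -1/2 S^(xi)_ij), and G_ai[X] is the
auxiliary-Fock contraction [2(mn|ts) - c_x (ms|tn)] (plus the XC kernel)
of the symmetrized AO response density.

All 3N right-hand sides are solved together in one shared reduced space
(block Krylov with the orbital-energy-difference diagonal as the
preconditioner); converged systems are frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eri import build_fock_2e
from .eri_deriv import fock_derivative_2e
from .oneelec import one_electron_derivatives
from .scf import SCFState


class IllConditioningError(RuntimeError):
    pass


class CPHFConvergenceError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


@dataclass
class PerturbationRHS:
    """Right-hand sides and their ingredients, one per perturbation
    (n_atoms, 3, n_virt, n_occ)."""

    R: np.ndarray
    F_mo: np.ndarray      # full MO derivative Fock (frozen density)
    S_mo: np.ndarray      # full MO derivative overlap
    F_ao: np.ndarray      # AO derivative Fock (frozen density)
    S_ao: np.ndarray      # AO derivative overlap
    n_occ: int


@dataclass
class ResponseSet:
    """CPHF solutions and everything needed downstream."""

    scf: SCFState
    rhs: PerturbationRHS
    U: np.ndarray                 # (n_atoms, 3, n_virt, n_occ)
    residual_norms: np.ndarray
    iterations: int
    history: list = field(default_factory=list)

    def perturbed_density(self, atom: int, comp: int) -> np.ndarray:
        """Total AO density derivative D^xi (response + occ-occ parts)."""
        scf = self.scf
        Co, Cv = scf.C_occ, scf.C_virt
        no = scf.n_occ
        X = Cv @ self.U[atom, comp] @ Co.T
        s_oo = self.rhs.S_mo[atom, comp, :no, :no]
        return 2.0 * (X + X.T) - 2.0 * Co @ s_oo @ Co.T

    def perturbed_energy_weighted_density(self, atom: int, comp: int
                                          ) -> np.ndarray:
        """W^xi from the gauge-invariant form W = 1/2 D F D:
        W^xi = 1/2 (D^xi F D + D F^xi,tot D + D F D^xi)."""
        scf = self.scf
        D = scf.D
        F = self._fock_ao()
        Dxi = self.perturbed_density(atom, comp)
        Ftot = self.rhs.F_ao[atom, comp] + self._g_total(Dxi)
        return 0.5 * (Dxi @ F @ D + D @ Ftot @ D + D @ F @ Dxi)

    def hessian_response_term(self) -> np.ndarray:
        """Orbital-relaxation contribution to the Hessian:
        H[xi, zeta] = tr(D^xi F^(zeta)) - tr(W^xi S^(zeta)),
        symmetrized (the residual asymmetry is solver noise)."""
        scf = self.scf
        na = scf.molecule.n_atoms
        n3 = 3 * na
        n = scf.basis.n_ao
        F = self.rhs.F_ao.reshape(n3, n, n)
        S = self.rhs.S_ao.reshape(n3, n, n)
        Dxi = np.empty((n3, n, n))
        Wxi = np.empty((n3, n, n))
        for a in range(na):
            for d in range(3):
                Dxi[3 * a + d] = self.perturbed_density(a, d)
                Wxi[3 * a + d] = self.perturbed_energy_weighted_density(a, d)
        H = np.einsum("xmn,zmn->xz", Dxi, F) - np.einsum("xmn,zmn->xz", Wxi, S)
        return 0.5 * (H + H.T)

    def _fock_ao(self) -> np.ndarray:
        """Converged AO Fock matrix reconstructed as S C eps C^T S."""
        scf = self.scf
        S = scf.one.S
        return S @ (scf.C * scf.eps) @ scf.C.T @ S

    def _g_total(self, X_ao: np.ndarray) -> np.ndarray:
        """Auxiliary Fock (2e + XC kernel) of an AO density perturbation."""
        return _aux_fock_ao(self.scf, X_ao)


def build_rhs(scf: SCFState, der=None, dF2e=None) -> PerturbationRHS:
    """Assemble R_ai^xi for all 3N perturbations."""
    mol, basis = scf.molecule, scf.basis
    na = mol.n_atoms
    no, nv = scf.n_occ, scf.n_virt
    C, Co, Cv = scf.C, scf.C_occ, scf.C_virt
    if der is None:
        der = one_electron_derivatives(mol, basis, order=1)
    if dF2e is None:
        dF2e = fock_derivative_2e(scf.D, basis, scf.c_x, scf.screen)
    dF = der.dT + der.dV + dF2e
    if scf.functional is not None:
        from .xc import xc_fock_derivative

        dF = dF + xc_fock_derivative(scf.D, basis, scf.grid, scf.functional)
    F_mo = np.einsum("mp,admn,nq->adpq", C, dF, C)
    S_mo = np.einsum("mp,admn,nq->adpq", C, der.dS, C)
    R = np.zeros((na, 3, nv, no))
    for a in range(na):
        for d in range(3):
            s_oo = S_mo[a, d, :no, :no]
            DS = -2.0 * Co @ s_oo @ Co.T
            Gs = _aux_fock_ao(scf, DS)
            R[a, d] = (F_mo[a, d, no:, :no]
                       - S_mo[a, d, no:, :no] * scf.eps[:no][None, :]
                       + Cv.T @ Gs @ Co)
    return PerturbationRHS(R, F_mo, S_mo, dF, der.dS, no)


def _aux_fock_ao(scf: SCFState, X_ao: np.ndarray) -> np.ndarray:
    """AO auxiliary Fock of an AO (total) density perturbation."""
    G = build_fock_2e(scf.basis, X_ao / 2, scf.c_x, scf.screen, scf.cache)
    if scf.functional is not None:
        from .xc import xc_kernel_contraction

        G = G + xc_kernel_contraction(X_ao, scf.D, scf.basis, scf.grid,
                                      scf.functional)
    return G


def auxiliary_fock(scf: SCFState, U: np.ndarray) -> np.ndarray:
    """G_ai[U]: auxiliary-Fock action of an occupied-virtual trial matrix
    (..., n_virt, n_occ) -> same shape.  Linear in U."""
    Co, Cv = scf.C_occ, scf.C_virt
    single = U.ndim == 2
    Us = U[None] if single else U.reshape(-1, *U.shape[-2:])
    out = np.empty_like(Us)
    for k, u in enumerate(Us):
        X = Cv @ u @ Co.T
        D_U = 2.0 * (X + X.T)
        out[k] = Cv.T @ _aux_fock_ao(scf, D_U) @ Co
    return out[0] if single else out.reshape(U.shape)


def cphf_matvec(scf: SCFState, U: np.ndarray) -> np.ndarray:
    """L(U)_ai = (eps_i - eps_a) U_ai - G_ai[U]."""
    no = scf.n_occ
    de = scf.eps[:no][None, :] - scf.eps[no:][:, None]  # (nv, no), negative
    return de * U - auxiliary_fock(scf, U)


def solve_cphf(rhs: PerturbationRHS, scf: SCFState, tol: float = 1e-6,
               max_iter: int = 60) -> ResponseSet:
    """Shared-subspace iterative solution of all 3N CPHF systems."""
    no = scf.n_occ
    nv = scf.n_virt
    if nv == 0 or no == 0:
        # no response space (minimal-basis atoms): U is identically zero
        shape = rhs.R.shape
        return ResponseSet(scf, rhs, np.zeros(shape),
                           np.zeros(shape[:2]), 0, [])
    de = scf.eps[:no][None, :] - scf.eps[no:][:, None]
    gap = np.abs(de).min()
    if gap < 1e-8:
        raise IllConditioningError(
            f"orbital-energy gap {gap:.2e} too small for CPHF")
    R = rhs.R.reshape(-1, nv, no)
    nrhs = len(R)
    dim = nv * no
    Rf = R.reshape(nrhs, dim)
    precond = (1.0 / de).ravel()

    # subspace storage
    V: list[np.ndarray] = []
    LV: list[np.ndarray] = []

    def add_vectors(vecs):
        for v in vecs:
            w = v.copy()
            for u in V:
                w -= (u @ w) * u
            for u in V:
                w -= (u @ w) * u
            nrm = np.linalg.norm(w)
            if nrm > 1e-10:
                w /= nrm
                V.append(w)
                LV.append(cphf_matvec(scf, w.reshape(nv, no)).ravel())

    U = np.zeros((nrhs, dim))
    res = Rf.copy()
    history = []
    rn0 = np.abs(Rf).max(axis=1)
    if rn0.max() <= tol:
        # zero right-hand sides solve trivially
        return ResponseSet(scf, rhs, U.reshape(rhs.R.shape),
                           rn0.reshape(rhs.R.shape[:2]), 1, [rn0])
    add_vectors(list(precond * Rf))
    for it in range(1, max_iter + 1):
        Vm = np.array(V)
        Lm = np.array(LV)
        A = Vm @ Lm.T              # projected operator (symmetric)
        B = Vm @ Rf.T
        coef = np.linalg.solve(0.5 * (A + A.T), B)
        U = coef.T @ Vm
        res = Rf - coef.T @ Lm
        rn = np.abs(res).max(axis=1)
        history.append(rn.copy())
        if rn.max() <= tol:
            return ResponseSet(scf, rhs, U.reshape(rhs.R.shape),
                               rn.reshape(rhs.R.shape[:2]), it, history)
        if len(V) >= min(dim, nrhs * max_iter):
            break
        # expand with preconditioned residuals of unconverged systems
        new = [precond * r for r, n in zip(res, rn) if n > tol]
        before = len(V)
        add_vectors(new)
        if len(V) == before:
            break
    raise CPHFConvergenceError(
        f"CPHF stagnated after {it} iterations "
        f"(max residual {rn.max():.2e})", history)


def solve_cphf_for_hessian(scf: SCFState, der=None, tol: float = 1e-8
                           ) -> ResponseSet:
    rhs = build_rhs(scf, der=der)
    return solve_cphf(rhs, scf, tol=tol)
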