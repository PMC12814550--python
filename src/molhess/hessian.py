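"""Analytic nuclear gradients and Hessians for the closed-shell SCF
reference, and dipole-moment gradients from the orbital response.

Gradient (restricted closed shell):

    g_xi = E_nn^xi + tr(D h^xi) + dE_2e/dxi - tr(W S^xi) (+ E_xc^xi)

with D the total density, W = 2 C_occ eps_occ C_occ^T the energy-weighted
density, and the two-electron term evaluated by direct double contraction
of derivative integrals with the density.

Hessian: the frozen-density second-derivative terms (nuclear repulsion,
one-electron, two-electron, energy-weighted overlap, XC) plus the
orbital-response cross terms built from the coupled-perturbed solutions
U^xi and the derivative Fock/overlap matrices.  Correctness of the term
grouping is defined against finite differences of the analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eri_deriv import (eri_gradient_contraction, eri_hessian_contraction,
                        fock_derivative_2e)
from .molecule import Molecule
from .oneelec import one_electron_derivatives
from .scf import SCFState


class StateError(RuntimeError):
    pass


@dataclass
class GradientResult:
    g: np.ndarray                      # (n_atoms, 3) hartree/bohr
    decomposition: dict = field(default_factory=dict)


@dataclass
class HessianResult:
    H: np.ndarray                      # (3N, 3N) hartree/bohr^2
    decomposition: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


@dataclass
class DipoleGradient:
    dmu: np.ndarray                    # (3N, 3): d mu_c / d x_Ai, units e
    nuclear: np.ndarray
    electronic: np.ndarray


def nuclear_repulsion_gradient(mol: Molecule) -> np.ndarray:
    g = np.zeros((mol.n_atoms, 3))
    z = mol.charges
    for i in range(mol.n_atoms):
        for j in range(mol.n_atoms):
            if i == j:
                continue
            rij = mol.coords[i] - mol.coords[j]
            g[i] -= z[i] * z[j] * rij / np.linalg.norm(rij) ** 3
    return g


def nuclear_repulsion_hessian(mol: Molecule) -> np.ndarray:
    n = mol.n_atoms
    H = np.zeros((n, 3, n, 3))
    z = mol.charges
    eye = np.eye(3)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rij = mol.coords[i] - mol.coords[j]
            r = np.linalg.norm(rij)
            blk = z[i] * z[j] * (3.0 * np.outer(rij, rij) / r**5 - eye / r**3)
            H[i, :, j, :] -= blk   # cross term d2/dxi dxj
            H[i, :, i, :] += blk   # diagonal accumulates opposite sign
    return H.reshape(3 * n, 3 * n)


def analytic_gradient(scf: SCFState, functional=None, grid=None
                      ) -> GradientResult:
    """Analytic SCF nuclear gradient with per-term decomposition."""
    if not scf.converged:
        raise StateError("SCF reference is not converged")
    mol, basis = scf.molecule, scf.basis
    D, W = scf.D, scf.W_energy
    der = one_electron_derivatives(mol, basis, order=1)
    g_nn = nuclear_repulsion_gradient(mol)
    g_1e = np.einsum("adop,op->ad", der.dT + der.dV, D)
    g_ov = -np.einsum("adop,op->ad", der.dS, W)
    g_2e = eri_gradient_contraction(D, D, basis, scf.c_x, scf.screen)
    parts = {"nuclear": g_nn, "one_electron": g_1e, "two_electron": g_2e,
             "overlap": g_ov}
    functional = functional if functional is not None else scf.functional
    grid = grid if grid is not None else scf.grid
    if functional is not None:
        from .xc import xc_gradient

        parts["xc"] = xc_gradient(D, basis, grid, functional)
    g = sum(parts.values())
    return GradientResult(g, parts)


def dipole_gradient(scf: SCFState, response, der=None) -> DipoleGradient:
    """Dipole-moment gradient d mu / d x, shape (3N, 3), units e.

    nuclear part: Z_A on the diagonal; electronic part: derivative dipole
    integrals with the frozen density plus the CPHF response density.
    """
    mol, basis = scf.molecule, scf.basis
    na = mol.n_atoms
    if der is None:
        der = one_electron_derivatives(mol, basis, order=1)
    dmu = np.zeros((na, 3, 3))   # (atom, displacement, dipole component)
    z = mol.charges
    dip = scf.one.D_dip
    for a in range(na):
        for x in range(3):
            # nuclear term (origin fixed)
            dmu[a, x, x] += z[a]
            # integral-derivative term with frozen density
            dmu[a, x] -= np.einsum("cop,op->c", der.dDip[a, x], scf.D)
            # response term
            Dresp = response.perturbed_density(a, x)
            dmu[a, x] -= np.einsum("cop,op->c", dip, Dresp)
    nuclear = np.zeros((na, 3, 3))
    for a in range(na):
        nuclear[a, :, :] = np.eye(3) * z[a]
    electronic = dmu - nuclear
    return DipoleGradient(dmu.reshape(3 * na, 3), nuclear.reshape(3 * na, 3),
                          electronic.reshape(3 * na, 3))


def analytic_hessian(scf: SCFState, cphf_tol: float = 1e-8,
                     response=None) -> HessianResult:
    """Analytic SCF Hessian (3N x 3N) with term decomposition.

    Frozen-density terms use the second-derivative integrals; the
    response term combines the CPHF solutions with the derivative Fock
    and overlap matrices.
    """
    if not scf.converged:
        raise StateError("SCF reference is not converged")
    from .cphf import solve_cphf_for_hessian

    mol, basis = scf.molecule, scf.basis
    na = mol.n_atoms
    D, W = scf.D, scf.W_energy
    der = one_electron_derivatives(mol, basis, order=2)

    H_nn = nuclear_repulsion_hessian(mol)
    H_1e = np.einsum("adbeop,op->adbe", der.d2T + der.d2V, D).reshape(3 * na, 3 * na)
    H_ov = -np.einsum("adbeop,op->adbe", der.d2S, W).reshape(3 * na, 3 * na)
    H_2e = eri_hessian_contraction(D, D, basis, scf.c_x, scf.screen
                                   ).reshape(3 * na, 3 * na)
    parts = {"nuclear": H_nn, "one_electron": H_1e, "two_electron": H_2e,
             "overlap": H_ov}
    if scf.functional is not None:
        from .xc import xc_hessian_terms

        parts["xc"] = xc_hessian_terms(D, basis, scf.grid, scf.functional
                                       ).reshape(3 * na, 3 * na)

    if response is None:
        response = solve_cphf_for_hessian(scf, der=der, tol=cphf_tol)
    parts["response"] = response.hessian_response_term()
    H = sum(parts.values())
    meta = {"c_x": scf.c_x, "cphf_tol": cphf_tol,
            "n_ao": basis.n_ao, "scf_iterations": scf.iterations}
    return HessianResult(H, parts, meta)
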