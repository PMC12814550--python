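"""Closed-shell restricted self-consistent field (Hartree-Fock, and
hybrid-DFT-ready through the exact-exchange fraction c_x plus an
exchange-correlation hook).

Density convention, used everywhere downstream: the *total* density is
D = 2 C_occ C_occ^T; the two-electron Fock operator of
:func:`molhess.eri.build_fock_2e` contracts the *alpha* density D/2 with
2(mn|ts) - c_x (ms|tn), so that

    F = h + G[D/2] (+ V_xc),   E_2e = tr((D/2) G[D/2]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import AOBasis
from .eri import ERICache, SchwarzScreen, build_fock_2e, schwarz_bounds
from .molecule import Molecule
from .oneelec import OneElectronSet, one_electron_matrices


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass
class SCFState:
    """Converged (or final-iterate) SCF reference state."""

    molecule: Molecule
    basis: AOBasis
    C: np.ndarray           # MO coefficients (AO x MO)
    eps: np.ndarray         # orbital energies, ascending
    D: np.ndarray           # total density 2 C_occ C_occ^T
    E_total: float
    n_occ: int
    converged: bool
    c_x: float = 1.0
    functional: object | None = None
    grid: object | None = None
    one: OneElectronSet | None = None
    cache: ERICache | None = None
    screen: SchwarzScreen | None = None
    iterations: int = 0
    trace: list = field(default_factory=list)

    @property
    def C_occ(self) -> np.ndarray:
        return self.C[:, :self.n_occ]

    @property
    def C_virt(self) -> np.ndarray:
        return self.C[:, self.n_occ:]

    @property
    def n_virt(self) -> int:
        return self.C.shape[1] - self.n_occ

    @property
    def W_energy(self) -> np.ndarray:
        """Energy-weighted density 2 C_occ eps_occ C_occ^T."""
        Co = self.C_occ
        return 2.0 * (Co * self.eps[:self.n_occ]) @ Co.T

    def dipole_moment(self) -> np.ndarray:
        """Electric dipole (e*bohr) about the stored dipole origin:
        nuclear part minus electronic part."""
        mol, one = self.molecule, self.one
        nuc = ((mol.coords - one.dipole_origin)
               * mol.charges[:, None]).sum(axis=0)
        el = np.einsum("cmn,mn->c", one.D_dip, self.D)
        return nuc - el


def _orthogonalizer(S: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    if w[0] < 1e-8:
        keep = w > 1e-8
        return V[:, keep] / np.sqrt(w[keep])
    return (V / np.sqrt(w)) @ V.T


class _DIIS:
    def __init__(self, max_vec: int = 10):
        self.f, self.e = [], []
        self.max_vec = max_vec

    def add(self, F, err):
        self.f.append(F.copy())
        self.e.append(err.ravel().copy())
        if len(self.f) > self.max_vec:
            self.f.pop(0)
            self.e.pop(0)

    def extrapolate(self):
        n = len(self.f)
        if n < 2:
            return self.f[-1]
        B = -np.ones((n + 1, n + 1))
        B[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = self.e[i] @ self.e[j]
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            return self.f[-1]
        return sum(ci * Fi for ci, Fi in zip(c, self.f))


def run_scf(molecule: Molecule, basis: AOBasis, method: str = "hf",
            c_x: float | None = None, functional=None, grid=None,
            conv: float = 1e-6, screen_threshold: float = 1e-12,
            max_iter: int = 100, diis: bool = True,
            cache: ERICache | None = None) -> SCFState:
    """Converge the restricted SCF equations.

    method 'hf' sets c_x=1 and no functional; 'hybrid' uses the supplied
    c_x and functional (evaluated on ``grid``).  Convergence requires both
    the energy change and the max norm of FDS-SDF below ``conv``.
    """
    molecule.require_closed_shell()
    n_occ = molecule.n_electrons // 2
    if method == "hf":
        c_x = 1.0
        functional = None
    elif c_x is None:
        raise ValueError("hybrid method requires c_x")
    one = one_electron_matrices(molecule, basis)
    S, h = one.S, one.T_kin + one.V_nuc
    X = _orthogonalizer(S)
    screen = (schwarz_bounds(basis, screen_threshold)
              if screen_threshold > 0 else None)
    cache = cache or ERICache(basis)
    E_nn = molecule.nuclear_repulsion()

    # core-Hamiltonian guess
    Fp = X.T @ h @ X
    w, V = np.linalg.eigh(Fp)
    C = X @ V
    D = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T

    acc = _DIIS() if diis else None
    E_old = 0.0
    trace = []
    xc = None
    for it in range(1, max_iter + 1):
        G = build_fock_2e(basis, D / 2, c_x, screen, cache)
        F = h + G
        E_xc = 0.0
        if functional is not None:
            from .xc import xc_energy_matrix

            E_xc, V_xc = xc_energy_matrix(D, basis, grid, functional)
            F = F + V_xc
        E = E_nn + np.einsum("mn,mn->", D, h) \
            + 0.5 * np.einsum("mn,mn->", D, G) + E_xc
        err = F @ D @ S - S @ D @ F
        err_norm = np.abs(err).max()
        trace.append((it, E, err_norm))
        if abs(E - E_old) <= conv and err_norm <= conv and it > 1:
            eps, C = _diagonalize(F, X)
            D = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
            return SCFState(molecule, basis, C, eps, D, E, n_occ, True,
                            c_x=c_x, functional=functional, grid=grid,
                            one=one, cache=cache, screen=screen,
                            iterations=it, trace=trace)
        E_old = E
        if acc is not None:
            acc.add(F, X.T @ err @ X)
            F = acc.extrapolate()
        eps, C = _diagonalize(F, X)
        D = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
    raise ConvergenceError(
        f"SCF not converged in {max_iter} iterations "
        f"(dE={abs(E - E_old):.2e}, |FDS-SDF|={err_norm:.2e})", trace)


def _diagonalize(F, X):
    w, V = np.linalg.eigh(X.T @ F @ X)
    return w, X @ V
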