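"""Harmonic vibrational analysis: normal modes, IR intensities, rigid-body
projection, partial-Hessian subsystem analysis, and mode localization.

The mass-weighted Hessian H_mw = M^{-1/2} H M^{-1/2} is diagonalized;
eigenvalues convert to wavenumbers through sqrt(lambda)/(2 pi c) with
imaginary frequencies encoded as negative cm^-1 values.  IR intensities
follow the Napierian integrated attenuation coefficient

    A_k = (1/(4 pi eps0)) (N_A pi / (3 c^2)) |d mu/d Q_k|^2

whose unit prefactor, with |d mu/dQ|^2 in e^2/amu, evaluates to
974.88 km/mol amu/e^2 from CODATA constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (CONSTANTS, eigenvalue_to_wavenumber,
                        ir_intensity_prefactor)


@dataclass
class VibrationalResult:
    """Frequencies (cm^-1, negative = imaginary), Cartesian-to-normal-mode
    coefficients l_ik (columns, 1/sqrt(amu)), and IR intensities (km/mol)."""

    frequencies: np.ndarray      # (n_modes,)
    modes: np.ndarray            # (3n_sub, n_modes) mass-weighted-orthonormal
    intensities: np.ndarray      # (n_modes,) km/mol
    masses: np.ndarray           # per-atom masses used (amu)
    atom_indices: np.ndarray     # atoms included in the analysis
    projected: bool
    n_rigid_removed: int = 0

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)


def _rigid_body_vectors(coords: np.ndarray, masses: np.ndarray,
                        linear_tol: float = 1e-8) -> np.ndarray:
    """Mass-weighted orthonormal translation + rotation vectors (Eckart
    frame); 5 vectors for linear molecules, 6 otherwise (3 for one atom)."""
    n = len(masses)
    sq = np.sqrt(masses)
    com = (masses[:, None] * coords).sum(0) / masses.sum()
    x = coords - com
    vecs = []
    for d in range(3):
        t = np.zeros((n, 3))
        t[:, d] = sq
        vecs.append(t.ravel())
    # principal axes for the rotations
    inertia = np.zeros((3, 3))
    for i in range(n):
        r = x[i]
        inertia += masses[i] * ((r @ r) * np.eye(3) - np.outer(r, r))
    w, axes = np.linalg.eigh(inertia)
    for k in range(3):
        if w[k] < max(linear_tol, 1e-12 * w[-1]):
            continue  # rotation about a vanishing-inertia axis (linear)
        ax = axes[:, k]
        rot = np.cross(np.broadcast_to(ax, (n, 3)), x) * sq[:, None]
        vecs.append(rot.ravel())
    V = np.array(vecs).T
    # orthonormalize (drops numerically null rotations for single atoms)
    q, r = np.linalg.qr(V)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def vibrational_analysis(H: np.ndarray, dmu: np.ndarray | None,
                         masses: np.ndarray, coords: np.ndarray | None = None,
                         project: bool = True,
                         atom_indices: np.ndarray | None = None
                         ) -> VibrationalResult:
    """Diagonalize the mass-weighted Hessian and compute IR intensities.

    H: (3n, 3n) Cartesian Hessian (hartree/bohr^2), must be symmetric.
    dmu: (3n, 3) dipole-moment gradient in e (may be None -> zero
    intensities).  coords are required for rigid-body projection.
    """
    n3 = H.shape[0]
    if H.shape != (n3, n3):
        raise ValueError("Hessian must be square")
    if np.abs(H - H.T).max() > 1e-6:
        raise ValueError("Hessian is not symmetric")
    masses = np.asarray(masses, float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    n = n3 // 3
    if len(masses) != n:
        raise ValueError("one mass per atom required")
    inv_sq = np.repeat(1.0 / np.sqrt(masses), 3)
    Hmw = H * inv_sq[:, None] * inv_sq[None, :]
    Hmw = 0.5 * (Hmw + Hmw.T)

    n_rigid = 0
    if project:
        if coords is None:
            raise ValueError("projection requires coordinates")
        B = _rigid_body_vectors(np.asarray(coords, float), masses)
        n_rigid = B.shape[1]
        P = np.eye(n3) - B @ B.T
        Hmw = P @ Hmw @ P
        Hmw = 0.5 * (Hmw + Hmw.T)

    w, Q = np.linalg.eigh(Hmw)
    if project:
        # discard the n_rigid null-space modes (smallest |eigenvalue|)
        order = np.argsort(np.abs(w))
        rigid = set(order[:n_rigid])
        keep = [k for k in range(n3) if k not in rigid]
        w, Q = w[keep], Q[:, keep]
        order = np.argsort(w)
        w, Q = w[order], Q[:, order]

    conv = eigenvalue_to_wavenumber()
    freqs = np.sign(w) * conv * np.sqrt(np.abs(w))
    modes = Q * inv_sq[:, None]   # l_ik, units 1/sqrt(amu)
    if dmu is not None:
        dmudQ = modes.T @ dmu     # (n_modes, 3), e/sqrt(amu)
        inten = ir_intensity_prefactor() * (dmudQ ** 2).sum(axis=1)
    else:
        inten = np.zeros(len(freqs))
    idx = (np.arange(n) if atom_indices is None
           else np.asarray(atom_indices, int))
    return VibrationalResult(freqs, modes, inten, masses, idx, project,
                             n_rigid)


def partial_hessian(H: np.ndarray, dmu: np.ndarray | None,
                    masses: np.ndarray, coords: np.ndarray,
                    atom_subset, project: bool = True) -> VibrationalResult:
    """Partial-Hessian vibrational analysis of an atom subset.

    The (3n_sub x 3n_sub) subblock of the full Hessian is extracted and
    analyzed with the subset masses; the matching rows of the full-system
    dipole-moment gradient provide the intensities (no re-derivation).
    """
    subset = np.asarray(atom_subset, int)
    if subset.size == 0:
        raise ValueError("atom subset must be nonempty")
    if len(np.unique(subset)) != len(subset):
        raise ValueError("atom subset contains duplicates")
    n = len(masses)
    if subset.min() < 0 or subset.max() >= n:
        raise ValueError("atom subset out of range")
    rows = np.concatenate([3 * a + np.arange(3) for a in subset])
    Hsub = H[np.ix_(rows, rows)]
    dmusub = None if dmu is None else dmu[rows]
    return vibrational_analysis(
        Hsub, dmusub, np.asarray(masses, float)[subset],
        coords=np.asarray(coords, float)[subset], project=project,
        atom_indices=subset)


def mode_localization(result: VibrationalResult, partition) -> np.ndarray:
    """Fraction of each mode's mass-weighted displacement norm^2 inside
    each atom subset of ``partition`` (disjoint subsets of the analyzed
    atoms).  Shape (n_modes, n_subsets); over a full partition every row
    sums to 1."""
    subsets = [np.asarray(s, int) for s in partition]
    seen: set[int] = set()
    for s in subsets:
        if seen & set(s.tolist()):
            raise ValueError("partition subsets overlap")
        seen |= set(s.tolist())
    pos = {int(a): k for k, a in enumerate(result.atom_indices)}
    mw = result.modes * np.repeat(np.sqrt(result.masses), 3)[:, None]
    total = (mw ** 2).sum(axis=0)
    out = np.zeros((result.n_modes, len(subsets)))
    for col, s in enumerate(subsets):
        rows = np.concatenate([3 * pos[int(a)] + np.arange(3) for a in s])
        out[:, col] = (mw[rows] ** 2).sum(axis=0) / total
    return out
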