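"""High-level pipelines: geometry + config in, spectra and archives out.

These functions chain the library layers (SCF -> CPHF -> Hessian ->
normal modes -> broadened spectrum) and are the programmatic face of the
command-line interface.
"""

from __future__ import annotations

import numpy as np

from .basis import load_basis
from .config import RunConfig
from .hessian import (HessianResult, analytic_gradient, analytic_hessian,
                      dipole_gradient)
from .molecule import Molecule
from .oneelec import one_electron_derivatives
from .scf import SCFState, run_scf
from .spectrum import BroadenedSpectrum, StickSpectrum, broaden
from .vibrations import VibrationalResult, partial_hessian, vibrational_analysis


def _apply_masses(mol: Molecule, config: RunConfig) -> Molecule:
    if not config.mass_overrides:
        return mol
    masses = mol.masses.copy()
    for idx, m in config.mass_overrides.items():
        masses[int(idx)] = float(m)
    return Molecule(list(mol.elements), mol.coords.copy(),
                    mol.total_charge, masses)


def compute_scf(mol: Molecule, config: RunConfig) -> SCFState:
    mol = _apply_masses(mol, config)
    if mol.total_charge != config.total_charge:
        mol = Molecule(list(mol.elements), mol.coords.copy(),
                       config.total_charge, mol.masses.copy())
    basis = load_basis(config.basis, mol)
    functional = grid = None
    c_x = 1.0
    if config.method == "hybrid":
        from .xc import FUNCTIONALS, build_grid

        c_x = config.c_x
        if config.functional is not None:
            functional = FUNCTIONALS[config.functional]()
            grid = build_grid(mol, config.grid_level)
    return run_scf(mol, basis, method=config.method, c_x=c_x,
                   functional=functional, grid=grid, conv=config.scf_conv,
                   screen_threshold=config.eri_screen)


def compute_hessian_bundle(mol: Molecule, config: RunConfig) -> dict:
    """SCF + CPHF + analytic Hessian + dipole gradient in one pass."""
    from .cphf import build_rhs, solve_cphf

    scf = compute_scf(mol, config)
    der = one_electron_derivatives(scf.molecule, scf.basis, order=2)
    rhs = build_rhs(scf, der=der)
    response = solve_cphf(rhs, scf, tol=config.cphf_tol)
    hess = analytic_hessian(scf, response=response)
    dmu = dipole_gradient(scf, response, der=der)
    return {"scf": scf, "response": response, "hessian": hess,
            "dipole_gradient": dmu}


def compute_ir(mol: Molecule, config: RunConfig,
               bundle: dict | None = None) -> dict:
    """Full IR pipeline; returns the bundle extended with the
    vibrational analysis, stick spectrum and broadened spectrum."""
    if bundle is None:
        bundle = compute_hessian_bundle(mol, config)
    scf = bundle["scf"]
    vib = vibrational_analysis(bundle["hessian"].H,
                               bundle["dipole_gradient"].dmu,
                               scf.molecule.masses, scf.molecule.coords,
                               project=config.project_tr)
    sticks = StickSpectrum(vib.frequencies, vib.intensities)
    spec = broaden(sticks, config.gamma, shape=config.line_shape,
                   scale_factor=config.scale_factor)
    bundle.update({"vibrations": vib, "sticks": sticks, "spectrum": spec})
    return bundle


def compute_partial_ir(bundle: dict, config: RunConfig, atom_subset
                       ) -> dict:
    """Partial-Hessian IR analysis of an atom subset from a completed
    full-Hessian bundle."""
    scf = bundle["scf"]
    vib = partial_hessian(bundle["hessian"].H,
                          bundle["dipole_gradient"].dmu,
                          scf.molecule.masses, scf.molecule.coords,
                          atom_subset, project=config.project_tr)
    sticks = StickSpectrum(vib.frequencies, vib.intensities)
    spec = broaden(sticks, config.gamma, shape=config.line_shape,
                   scale_factor=config.scale_factor)
    return {"vibrations": vib, "sticks": sticks, "spectrum": spec}


# -------------------------------------------------------------- archives

def save_hessian_archive(path, mol: Molecule, hess: HessianResult,
                         dmu) -> None:
    np.savez(path, coords=mol.coords, elements=np.array(mol.elements),
             masses=mol.masses, total_charge=mol.total_charge,
             H=hess.H, dmu=dmu.dmu,
             **{f"H_{k}": v for k, v in hess.decomposition.items()})


def load_hessian_archive(path):
    data = np.load(path, allow_pickle=False)
    mol = Molecule([str(e) for e in data["elements"]], data["coords"],
                   int(data["total_charge"]), data["masses"])
    return mol, data["H"], data["dmu"]
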