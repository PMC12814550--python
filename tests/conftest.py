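"""Shared fixtures: fixture molecules, converged SCF states and response
solutions, cached per session because they are expensive to build."""

from __future__ import annotations

import numpy as np
import pytest

from molhess.basis import load_basis
from molhess.fixtures import fixture_molecule
from molhess.scf import run_scf

# Oracle tolerances used across the suite (single source to avoid drift).
TOL = {
    "fd_gradient": 1e-6,        # analytic vs FD energy gradient
    "fd_hessian": 1e-5,         # analytic vs FD-of-gradient Hessian
    "fd_integral_first": 1e-8,  # integral first derivatives vs FD
    "fd_integral_second": 1e-6,
    "eri_paths": 1e-10,         # early vs late contraction
    "perm_symmetry": 1e-12,
    "cphf_dense": 1e-8,
    "boys": 1e-13,
}


@pytest.fixture(scope="session")
def h2():
    return fixture_molecule("h2")


@pytest.fixture(scope="session")
def h2o():
    return fixture_molecule("h2o")


@pytest.fixture(scope="session")
def nh3():
    return fixture_molecule("nh3")


@pytest.fixture(scope="session")
def formamide():
    return fixture_molecule("formamide")


@pytest.fixture(scope="session")
def water_dimer():
    return fixture_molecule("water_dimer")


def _scf(mol, basis_name, **kw):
    basis = load_basis(basis_name, mol)
    kw.setdefault("conv", 1e-10)
    return run_scf(mol, basis, **kw)


@pytest.fixture(scope="session")
def scf_h2(h2):
    return _scf(h2, "sto-3g")


@pytest.fixture(scope="session")
def scf_h2o(h2o):
    return _scf(h2o, "sto-3g")


@pytest.fixture(scope="session")
def scf_h2o_def2(h2o):
    return _scf(h2o, "def2-sv(p)", conv=1e-9)


@pytest.fixture(scope="session")
def scf_nh3(nh3):
    return _scf(nh3, "sto-3g")


@pytest.fixture(scope="session")
def response_h2o(scf_h2o):
    from molhess.cphf import solve_cphf_for_hessian

    return solve_cphf_for_hessian(scf_h2o, tol=1e-10)


@pytest.fixture(scope="session")
def hessian_h2o(scf_h2o, response_h2o):
    from molhess.hessian import analytic_hessian

    return analytic_hessian(scf_h2o, response=response_h2o)


@pytest.fixture(scope="session")
def dipole_gradient_h2o(scf_h2o, response_h2o):
    from molhess.hessian import dipole_gradient

    return dipole_gradient(scf_h2o, response_h2o)


def random_shell(rng, l=None, center_span=1.2, max_prim=2):
    """A random normalized contracted shell for property tests."""
    from molhess.basis import GaussianShell

    if l is None:
        l = int(rng.integers(0, 3))
    npr = int(rng.integers(1, max_prim + 1))
    exps = np.sort(rng.uniform(0.25, 2.8, npr))[::-1]
    coefs = rng.uniform(0.3, 1.0, npr)
    center = rng.uniform(-center_span, center_span, 3)
    return GaussianShell(0, l, exps, coefs, center)


def moved_shell(sh, direction, step):
    import copy

    new = copy.copy(sh)
    c = sh.center.copy()
    c[direction] += step
    new.center = c
    return new
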