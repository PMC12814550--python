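"""Exchange-correlation layer: grid quality, the analytic chain-rule
assemblies against frozen-weight finite differences, and the kernel
contraction."""

import math

import numpy as np
import pytest

from molhess.basis import load_basis
from molhess.molecule import Molecule, parse_xyz
from molhess.scf import run_scf
from molhess.xc import (FUNCTIONALS, FunctionalCapabilityError, GridConfigError,
                        SlaterExchange, ToyDensitySquared, ToySigma,
                        _H_TERMS, _rebuild_basis, ao_values, build_grid,
                        xc_energy, xc_energy_matrix, xc_fock_derivative,
                        xc_gradient, xc_hessian_terms, xc_kernel_contraction)


@pytest.fixture(scope="module")
def h2_setup():
    mol = parse_xyz("2\nc\nH 0.05 -0.03 0\nH 0.02 0.01 0.74\n")
    basis = load_basis("sto-3g", mol)
    st = run_scf(mol, basis, conv=1e-10)
    grid = build_grid(mol, "medium")
    return mol, basis, st.D, grid


class TestGrid:
    def test_unknown_level(self):
        with pytest.raises(GridConfigError):
            build_grid(Molecule(["H", "H"], [[0, 0, 0], [0, 0, 1]]), "huge")

    def test_weights_positive(self, h2_setup):
        _, _, _, grid = h2_setup
        assert np.all(grid.weights > 0)

    def test_normalized_gaussian_integral(self):
        mol = Molecule(["H"], np.zeros((1, 3)))
        grid = build_grid(mol, "fine")
        a = 0.9
        rho = (a / math.pi) ** 1.5 * np.exp(-a * (grid.points ** 2).sum(1))
        assert abs(grid.weights @ rho - 1.0) < 1e-8

    @pytest.mark.parametrize("level,tol", [("medium", 1e-6), ("fine", 1e-6)])
    def test_electron_count(self, scf_h2o, level, tol):
        grid = build_grid(scf_h2o.molecule, level)
        ao = ao_values(scf_h2o.basis, grid.points, 0)
        ne = 2.0 * grid.weights @ ((0.5 * scf_h2o.D @ ao[0]) * ao[0]).sum(0)
        assert abs(ne - 10.0) < tol

    def test_ao_derivatives_vs_fd(self, h2_setup):
        """Grid AO gradients against finite differences of the values."""
        mol, basis, _, _ = h2_setup
        rng = np.random.default_rng(1)
        pts = rng.uniform(-2, 2, size=(40, 3))
        ao = ao_values(basis, pts, 1)
        h = 1e-5
        for d in range(3):
            shift = np.zeros(3)
            shift[d] = h
            fd = (ao_values(basis, pts + shift, 0)[0]
                  - ao_values(basis, pts - shift, 0)[0]) / (2 * h)
            assert np.abs(fd - ao[1][d]).max() < 1e-8


class TestSlater:
    def test_closed_form_on_gaussian_density(self):
        """Slater exchange of a unit normalized Gaussian density against
        the analytic integral of rho^{4/3}."""
        mol = Molecule(["H"], np.zeros((1, 3)))
        grid = build_grid(mol, "fine")
        a = 0.9
        rho_a = 0.5 * (a / math.pi) ** 1.5 \
            * np.exp(-a * (grid.points ** 2).sum(1))
        fe = SlaterExchange().evaluate(rho_a, np.zeros_like(rho_a))
        e = grid.weights @ fe.f
        cs = -0.75 * (6 / math.pi) ** (1 / 3)
        e_ref = 2 * cs * 0.5 ** (4 / 3) * (a / math.pi) ** 2 \
            * (3 * math.pi / (4 * a)) ** 1.5
        assert abs(e - e_ref) < 1e-7

    def test_closed_shell_spin_symmetry(self, h2_setup):
        _, _, D, grid = h2_setup
        rho = np.linspace(1e-3, 1.0, 50)
        fe = SlaterExchange().evaluate(rho, np.zeros_like(rho))
        # alpha/beta channels must be equivalent for identical densities
        assert np.abs(fe.f_rasaa - fe.f_rbsab * 0).max() == 0.0
        assert np.all(fe.f_rara < 0)


@pytest.mark.parametrize("functional", [ToyDensitySquared(0.13),
                                        ToySigma(0.07), SlaterExchange()],
                         ids=["toy-rho2", "toy-sigma", "slater-x"])
class TestChainRuleAssemblies:
    def test_gradient_vs_frozen_weight_fd(self, h2_setup, functional):
        mol, basis, D, grid = h2_setup
        g = xc_gradient(D, basis, grid, functional)
        h = 1e-4
        for a in range(2):
            for d in range(3):
                bp = _rebuild_basis(basis, mol.displaced(a, d, h))
                bm = _rebuild_basis(basis, mol.displaced(a, d, -h))
                fd = (xc_energy(D, bp, grid, functional)
                      - xc_energy(D, bm, grid, functional)) / (2 * h)
                assert abs(fd - g[a, d]) < 1e-8

    def test_hessian_terms_vs_fd_of_gradient(self, h2_setup, functional):
        mol, basis, D, grid = h2_setup
        H = xc_hessian_terms(D, basis, grid, functional)
        h = 1e-3
        for a in range(2):
            for d in range(3):
                bp = _rebuild_basis(basis, mol.displaced(a, d, h))
                bm = _rebuild_basis(basis, mol.displaced(a, d, -h))
                fd = (xc_gradient(D, bp, grid, functional)
                      - xc_gradient(D, bm, grid, functional)) / (2 * h)
                assert np.abs(fd - H[:, :, a, d]).max() < 1e-6

    def test_fock_derivative_vs_frozen_orbital_fd(self, h2_setup, functional):
        mol, basis, D, grid = h2_setup
        dV = xc_fock_derivative(D, basis, grid, functional)
        h = 1e-4
        for a in range(2):
            for d in range(3):
                _, Vp = xc_energy_matrix(
                    D, _rebuild_basis(basis, mol.displaced(a, d, h)), grid,
                    functional)
                _, Vm = xc_energy_matrix(
                    D, _rebuild_basis(basis, mol.displaced(a, d, -h)), grid,
                    functional)
                assert np.abs((Vp - Vm) / (2 * h) - dV[a, d]).max() < 1e-7

    def test_fock_derivative_translational_sum(self, h2_setup, functional):
        """At frozen weights the translational sum is zero only up to the
        quadrature error of the fixed grid, so this uses a fine grid."""
        mol, basis, D, _ = h2_setup
        grid = build_grid(mol, "fine")
        dV = xc_fock_derivative(D, basis, grid, functional)
        assert np.abs(dV.sum(axis=0)).max() < 1e-8

    def test_hessian_symmetric(self, h2_setup, functional):
        _, basis, D, grid = h2_setup
        H = xc_hessian_terms(D, basis, grid, functional)
        assert np.abs(H - H.transpose(2, 3, 0, 1)).max() < 1e-8


class TestTermStructure:
    def test_lda_limit_zeroes_gga_terms(self, h2_setup):
        """For a sigma-independent functional the entire second
        chain-rule family (the GGA terms) must vanish identically."""
        _, basis, D, grid = h2_setup
        fn = ToyDensitySquared(0.2)
        full = xc_fock_derivative(D, basis, grid, fn)
        no14 = xc_fock_derivative(D, basis, grid, fn,
                                  terms={"kernel_rho", "kernel_sigma", "moved_basis_local"})
        assert np.abs(full - no14).max() == 0.0

    def test_term_completeness(self, h2_setup):
        """Dropping any single Hessian term breaks the FD agreement; the
        full sum restores it (each term carries real weight)."""
        mol, basis, D, grid = h2_setup
        fn = SlaterExchange()
        h = 1e-3
        fd = np.zeros((2, 3, 2, 3))
        for a in range(2):
            for d in range(3):
                bp = _rebuild_basis(basis, mol.displaced(a, d, h))
                bm = _rebuild_basis(basis, mol.displaced(a, d, -h))
                fd[:, :, a, d] = (xc_gradient(D, bp, grid, fn)
                                  - xc_gradient(D, bm, grid, fn)) / (2 * h)
        full = xc_hessian_terms(D, basis, grid, fn)
        assert np.abs(full - fd).max() < 1e-6
        for drop in ("rho_rho", "rho_second_deriv"):   # LDA-active terms
            partial = xc_hessian_terms(D, basis, grid, fn,
                                       terms=set(_H_TERMS) - {drop})
            assert np.abs(partial - fd).max() > 1e-4

    def test_missing_second_derivatives_rejected(self, h2_setup):
        _, basis, D, grid = h2_setup

        class FirstOrderOnly(ToyDensitySquared):
            def evaluate(self, rho_a, sigma_aa):
                fe = super().evaluate(rho_a, sigma_aa)
                fe.f_rara = None
                return fe

        with pytest.raises(FunctionalCapabilityError):
            xc_hessian_terms(D, basis, grid, FirstOrderOnly())


class TestKernel:
    def test_zero_trial(self, h2_setup):
        _, basis, D, grid = h2_setup
        z = np.zeros_like(D)
        k = xc_kernel_contraction(z, D, basis, grid, SlaterExchange())
        assert np.abs(k).max() == 0.0

    def test_linearity(self, h2_setup):
        _, basis, D, grid = h2_setup
        rng = np.random.default_rng(7)
        X = rng.normal(size=D.shape)
        Y = rng.normal(size=D.shape)
        fn = SlaterExchange()
        lhs = xc_kernel_contraction(2.0 * X + 0.5 * Y, D, basis, grid, fn)
        rhs = (2.0 * xc_kernel_contraction(X, D, basis, grid, fn)
               + 0.5 * xc_kernel_contraction(Y, D, basis, grid, fn))
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_toy_rho2_analytic_kernel(self, h2_setup):
        """For f = c (rho_a^2 + rho_b^2) the kernel is a local 2c rho^t
        multiplication: assemble it analytically and compare."""
        _, basis, D, grid = h2_setup
        c = 0.13
        fn = ToyDensitySquared(c)
        rng = np.random.default_rng(8)
        X = rng.normal(size=D.shape)
        X = X + X.T
        k = xc_kernel_contraction(X, D, basis, grid, fn)
        ao = ao_values(basis, grid.points, 0)[0]
        rho_t = ((0.5 * X @ ao) * ao).sum(0)
        ref = (ao * (grid.weights * 2.0 * c * rho_t)) @ ao.T
        assert np.abs(k - ref).max() < 1e-8
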