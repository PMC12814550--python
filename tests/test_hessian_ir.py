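"""Analytic gradients/Hessians, dipole gradients, normal-mode analysis,
IR intensities, partial Hessians and mode localization."""

import math

import numpy as np
import pytest

from molhess.basis import load_basis
from molhess.constants import (ISOTOPE_MASS, eigenvalue_to_wavenumber,
                               ir_intensity_prefactor)
from molhess.hessian import (StateError, analytic_gradient, analytic_hessian,
                             dipole_gradient)
from molhess.molecule import parse_xyz
from molhess.oracles import fd_gradient
from molhess.scf import run_scf
from molhess.vibrations import (mode_localization, partial_hessian,
                                vibrational_analysis)

from conftest import TOL


class TestGradient:
    def test_h2o_vs_fd_energy(self, h2o):
        st = run_scf(h2o, load_basis("sto-3g", h2o), conv=1e-11)
        g = analytic_gradient(st).g

        def energy(mol):
            return run_scf(mol, load_basis("sto-3g", mol), conv=1e-11).E_total

        fd = fd_gradient(energy, h2o, step=1e-3, stencil=4)
        assert np.abs(fd - g).max() < TOL["fd_gradient"]

    def test_translational_sum(self, scf_nh3):
        g = analytic_gradient(scf_nh3).g
        assert np.abs(g.sum(axis=0)).max() < 1e-9

    def test_homonuclear_symmetry(self):
        mol = parse_xyz("2\nc\nH 0 0 0\nH 0 0 0.70\n")
        st = run_scf(mol, load_basis("sto-3g", mol), conv=1e-11)
        g = analytic_gradient(st).g
        assert abs(g[0, 2] + g[1, 2]) < 1e-12
        assert np.abs(g[:, :2]).max() < 1e-10

    def test_stationary_fixture_geometries(self, scf_h2o, scf_nh3):
        """The bundled geometries are stationary points of this model
        chemistry."""
        for st in (scf_h2o, scf_nh3):
            assert np.abs(analytic_gradient(st).g).max() < 1e-6

    def test_unconverged_state_rejected(self, h2o):
        st = run_scf(h2o, load_basis("sto-3g", h2o), conv=1e-10)
        st.converged = False
        with pytest.raises(StateError):
            analytic_gradient(st)


class TestHessian:
    def test_symmetry_and_sum_rules(self, hessian_h2o):
        H = hessian_h2o.H
        assert np.abs(H - H.T).max() < 1e-9
        assert np.abs(H.reshape(3, 3, 3, 3).sum(axis=0)).max() < 1e-6

    def test_h2o_vs_fd_of_gradient(self, h2o, hessian_h2o):
        def grad(mol):
            st = run_scf(mol, load_basis("sto-3g", mol), conv=1e-11)
            return analytic_gradient(st).g.ravel()

        h = 1e-3
        n3 = 9
        fd = np.zeros((n3, n3))
        for a in range(3):
            for d in range(3):
                fd[3 * a + d] = (grad(h2o.displaced(a, d, h))
                                 - grad(h2o.displaced(a, d, -h))) / (2 * h)
        assert np.abs(fd - hessian_h2o.H).max() < TOL["fd_hessian"]

    def test_h2_rigid_modes(self, scf_h2):
        hes = analytic_hessian(scf_h2)
        mol = scf_h2.molecule
        vib = vibrational_analysis(hes.H, None, mol.masses, mol.coords,
                                   project=False)
        w = np.sort(np.abs(vib.frequencies))
        # five rigid-body frequencies ~0 (linear molecule), one stretch > 0
        assert np.all(w[:5] < 1.0)
        assert w[5] > 1000.0
        vib_p = vibrational_analysis(hes.H, None, mol.masses, mol.coords,
                                     project=True)
        assert vib_p.n_modes == 1 and vib_p.n_rigid_removed == 5


class TestDipoleGradient:
    def test_vs_fd_dipole(self, h2o, scf_h2o, dipole_gradient_h2o):
        import molhess.oneelec as oe

        origin = scf_h2o.one.dipole_origin

        def dip(mol):
            b = load_basis("sto-3g", mol)
            st = run_scf(mol, b, conv=1e-11)
            one = oe.one_electron_matrices(mol, b, origin=origin)
            nuc = ((mol.coords - origin) * mol.charges[:, None]).sum(0)
            return nuc - np.einsum("cmn,mn->c", one.D_dip, st.D)

        h = 1e-3
        fd = np.zeros((9, 3))
        for a in range(3):
            for d in range(3):
                fd[3 * a + d] = (dip(h2o.displaced(a, d, h))
                                 - dip(h2o.displaced(a, d, -h))) / (2 * h)
        assert np.abs(fd - dipole_gradient_h2o.dmu).max() < 1e-5

    def test_neutral_charge_sum_rule(self, dipole_gradient_h2o):
        rows = dipole_gradient_h2o.dmu.reshape(3, 3, 3)
        assert np.abs(rows.sum(axis=0)).max() < 1e-6

    def test_single_atom_cancellation(self):
        from molhess.cphf import solve_cphf_for_hessian
        from molhess.molecule import Molecule

        he = Molecule(["He"], np.zeros((1, 3)))
        st = run_scf(he, load_basis("sto-3g", he), conv=1e-11)
        resp = solve_cphf_for_hessian(st)
        dmu = dipole_gradient(st, resp).dmu
        # neutral atom: nuclear and electronic response cancel exactly
        assert np.abs(dmu).max() < 1e-8


class TestVibrationalAnalysis:
    def test_unit_dipole_gradient_gives_prefactor(self):
        """A mode with |dmu/dQ|^2 = 1 e^2/amu has intensity equal to the
        974.88 km/mol unit prefactor."""
        k = 0.3
        H = np.array([[k, -k], [-k, k]])  # 1-D two-mass toy
        # build a synthetic 1-atom 3N=3 case instead: diagonal Hessian
        H = np.eye(3) * 0.25
        masses = np.array([1.0])
        dmu = np.eye(3)  # each Cartesian mode couples to one component
        vib = vibrational_analysis(H, dmu, masses,
                                   coords=np.zeros((1, 3)), project=False)
        assert np.abs(vib.intensities - ir_intensity_prefactor()
                      ).max() < 1e-8

    def test_diatomic_closed_form_frequency(self):
        """Analytic force constant k: omega = sqrt(k/mu_r)/(2 pi c)."""
        k = 0.37  # hartree/bohr^2
        m1, m2 = ISOTOPE_MASS["H"], ISOTOPE_MASS["Cl"]
        coords = np.array([[0, 0, 0], [0, 0, 2.4]])
        n3 = 6
        H = np.zeros((n3, n3))
        H[2, 2] = H[5, 5] = k
        H[2, 5] = H[5, 2] = -k
        vib = vibrational_analysis(H, None, np.array([m1, m2]), coords,
                                   project=True)
        mu_r = m1 * m2 / (m1 + m2)
        w_ref = eigenvalue_to_wavenumber() * math.sqrt(k / mu_r)
        w = vib.frequencies[np.argmax(np.abs(vib.frequencies))]
        assert abs(w - w_ref) / w_ref < 1e-8

    def test_imaginary_encoded_negative(self):
        H = -np.eye(3) * 0.1
        vib = vibrational_analysis(H, None, np.array([2.0]),
                                   coords=np.zeros((1, 3)), project=False)
        assert np.all(vib.frequencies < 0)

    def test_mode_orthonormality_mass_weighted(self, hessian_h2o, h2o):
        vib = vibrational_analysis(hessian_h2o.H, None, h2o.masses,
                                   h2o.coords)
        mw = vib.modes * np.repeat(np.sqrt(h2o.masses), 3)[:, None]
        assert np.abs(mw.T @ mw - np.eye(vib.n_modes)).max() < 1e-8

    def test_water_mode_count_and_positive(self, hessian_h2o,
                                           dipole_gradient_h2o, h2o):
        vib = vibrational_analysis(hessian_h2o.H, dipole_gradient_h2o.dmu,
                                   h2o.masses, h2o.coords)
        assert vib.n_modes == 3
        assert np.all(vib.frequencies > 0)
        assert np.all(vib.intensities >= 0)

    def test_rotational_invariance(self, h2o):
        """Rotating the molecule leaves frequencies and intensities
        unchanged."""
        from molhess.cphf import solve_cphf_for_hessian

        def spectrum(mol):
            st = run_scf(mol, load_basis("sto-3g", mol), conv=1e-11)
            resp = solve_cphf_for_hessian(st)
            hes = analytic_hessian(st, response=resp)
            dmu = dipole_gradient(st, resp).dmu
            return vibrational_analysis(hes.H, dmu, mol.masses, mol.coords)

        v0 = spectrum(h2o)
        th = 0.83
        R = np.array([[math.cos(th), 0, math.sin(th)], [0, 1, 0],
                      [-math.sin(th), 0, math.cos(th)]])
        v1 = spectrum(h2o.with_coords(h2o.coords @ R.T))
        assert np.abs(v0.frequencies - v1.frequencies).max() < 1e-6
        assert np.abs(v0.intensities - v1.intensities).max() < 1e-8

    def test_input_validation(self):
        with pytest.raises(ValueError):
            vibrational_analysis(np.ones((3, 3)) * np.array([[0, 1, 0]]),
                                 None, np.array([1.0]), np.zeros((1, 3)))
        with pytest.raises(ValueError):
            vibrational_analysis(np.eye(3), None, np.array([-1.0]),
                                 np.zeros((1, 3)))


class TestPartialHessian:
    def test_full_subset_identity(self, hessian_h2o, dipole_gradient_h2o,
                                  h2o):
        full = vibrational_analysis(hessian_h2o.H, dipole_gradient_h2o.dmu,
                                    h2o.masses, h2o.coords)
        part = partial_hessian(hessian_h2o.H, dipole_gradient_h2o.dmu,
                               h2o.masses, h2o.coords, [0, 1, 2])
        assert np.abs(full.frequencies - part.frequencies).max() < 1e-12
        assert np.abs(full.intensities - part.intensities).max() < 1e-12

    def test_decoupled_blocks_exact(self):
        """A block-diagonal Hessian of two decoupled fragments: each
        partial analysis reproduces the matching full-system modes."""
        rng = np.random.default_rng(41)
        coords = np.vstack([rng.uniform(0, 3, (4, 3)),
                            rng.uniform(50, 53, (5, 3))])
        masses = rng.uniform(1, 16, 9)
        from molhess.fixtures import synthetic_protein_hessian  # noqa: F401

        def spd(n3, seed):
            r = np.random.default_rng(seed)
            A = r.standard_normal((n3, n3))
            return A @ A.T + 0.1 * np.eye(n3)

        H = np.zeros((27, 27))
        H[:12, :12] = spd(12, 1)
        H[12:, 12:] = spd(27 - 12, 2)
        full = vibrational_analysis(H, None, masses, coords, project=False)
        p1 = partial_hessian(H, None, masses, coords, range(4),
                             project=False)
        p2 = partial_hessian(H, None, masses, coords, range(4, 9),
                             project=False)
        merged = np.sort(np.concatenate([p1.frequencies, p2.frequencies]))
        assert np.abs(np.sort(full.frequencies) - merged).max() < 1e-9

    def test_subset_validation(self, hessian_h2o, h2o):
        for bad in ([], [0, 0], [5]):
            with pytest.raises(ValueError):
                partial_hessian(hessian_h2o.H, None, h2o.masses, h2o.coords,
                                bad)


class TestModeLocalization:
    def test_full_partition_rows_sum_to_one(self, hessian_h2o, h2o):
        vib = vibrational_analysis(hessian_h2o.H, None, h2o.masses,
                                   h2o.coords)
        loc = mode_localization(vib, [[0], [1, 2]])
        assert np.abs(loc.sum(axis=1) - 1.0).max() < 1e-12

    def test_displacement_confined_to_one_subset(self):
        masses = np.ones(2)
        modes = np.zeros((6, 1))
        modes[0, 0] = 1.0   # displacement only on atom 0
        from molhess.vibrations import VibrationalResult

        vib = VibrationalResult(np.array([100.0]), modes, np.array([1.0]),
                                masses, np.arange(2), True)
        loc = mode_localization(vib, [[0], [1]])
        assert np.allclose(loc, [[1.0, 0.0]])

    def test_against_direct_norm_accounting(self):
        rng = np.random.default_rng(42)
        n_at = 5
        masses = rng.uniform(1, 16, n_at)
        q, _ = np.linalg.qr(rng.standard_normal((3 * n_at, 6)))
        modes = q / np.repeat(np.sqrt(masses), 3)[:, None]
        from molhess.vibrations import VibrationalResult

        vib = VibrationalResult(np.arange(6) + 1.0, modes, np.zeros(6),
                                masses, np.arange(n_at), True)
        loc = mode_localization(vib, [[0, 2], [1, 3]])
        for k in range(6):
            mw = q[:, k]
            for col, subset in enumerate([[0, 2], [1, 3]]):
                rows = np.concatenate([3 * a + np.arange(3) for a in subset])
                ref = (mw[rows] ** 2).sum() / (mw ** 2).sum()
                assert abs(loc[k, col] - ref) < 1e-12

    def test_overlapping_subsets_rejected(self, hessian_h2o, h2o):
        vib = vibrational_analysis(hessian_h2o.H, None, h2o.masses,
                                   h2o.coords)
        with pytest.raises(ValueError):
            mode_localization(vib, [[0, 1], [1, 2]])
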