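"""Geometric ERI derivatives: the differentiated recurrences against
finite differences of the plain quartets, operator composition, the
Kronecker-delta structure of the differentiated transfers, and the
density contractions."""

import numpy as np
import pytest

from molhess.basis import load_basis
from molhess.eri import build_fock_2e, eri_quartet, primitive_blocks
from molhess.eri_deriv import (eri_gradient_contraction,
                               eri_hessian_contraction, fock_derivative_2e,
                               ghrr_transfer, gvrr_raise,
                               quartet_first_derivatives,
                               quartet_second_derivatives)
from molhess.molecule import parse_xyz
from molhess.scf import run_scf

from conftest import TOL, moved_shell, random_shell


class TestGVRR:
    def test_one_shot_equals_composition(self):
        """Applying two first-order shift operators sequentially must
        equal the one-shot second-derivative operator."""
        rng = np.random.default_rng(21)
        sh = [random_shell(rng, l=l) for l in (0, 1, 0, 1)]
        prim, blocks = primitive_blocks(*sh, 3, 2)
        for (i, j) in ((0, 0), (0, 2), (1, 2)):
            one_shot = gvrr_raise(blocks, prim.exp_b,
                                  tuple(sorted((i, j))), axis="b", b_top=1,
                                  d_top=2)
            step1 = gvrr_raise(blocks, prim.exp_b, (i,), axis="b", b_top=2,
                               d_top=2)
            step2 = gvrr_raise(step1, prim.exp_b, (j,), axis="b", b_top=1,
                               d_top=2)
            for key in one_shot:
                if key in step2:
                    assert np.abs(one_shot[key] - step2[key]).max() < 1e-10

    def test_s_bra_second_derivative_vs_fd(self):
        """d2/dBz2 of an (ss|sd)-type quartet via the derivative engine
        matches two-step finite differences."""
        rng = np.random.default_rng(22)
        sh = [random_shell(rng, l=l) for l in (0, 0, 0, 2)]
        d2 = quartet_second_derivatives(*sh)[("B", "B")]
        h = 1e-4
        for z in range(3):
            fd = (eri_quartet(sh[0], moved_shell(sh[1], z, h), sh[2], sh[3])
                  - 2 * eri_quartet(*sh)
                  + eri_quartet(sh[0], moved_shell(sh[1], z, -h), sh[2],
                                sh[3])) / h ** 2
            assert np.abs(fd - d2[z, z]).max() < 1e-6

    def test_concentric_cross_derivative_structure(self):
        """All four s shells on one center: every first derivative block
        vanishes by spherical symmetry."""
        rng = np.random.default_rng(23)
        sh = [random_shell(rng, l=0, center_span=0.0) for _ in range(4)]
        d1 = quartet_first_derivatives(*sh)
        for cen in "ABCD":
            assert np.abs(d1[cen]).max() < 1e-12


class TestGHRR:
    def test_empty_spec_reduces_to_plain_hrr(self):
        rng = np.random.default_rng(24)
        sh = [random_shell(rng, l=l) for l in (1, 1, 0, 0)]
        d1 = quartet_first_derivatives(*sh)
        # the underived block produced alongside must equal eri_quartet
        from molhess.eri_deriv import _deriv_pipeline

        out = _deriv_pipeline(*sh, 1, 0, 1)
        assert np.abs(out[((), ())] - eri_quartet(*sh)).max() < 1e-12

    def test_missing_lower_blocks_rejected(self):
        with pytest.raises(KeyError):
            ghrr_transfer({(0,): {0: np.zeros((1, 1, 1))}},
                          np.zeros(3), 0, 0)

    def test_pp_ss_second_b_derivative_vs_fd(self):
        """Full (pp|ss) second derivative on B via the differentiated
        transfer chain vs two-step finite differences."""
        rng = np.random.default_rng(25)
        sh = [random_shell(rng, l=l) for l in (1, 1, 0, 0)]
        d2 = quartet_second_derivatives(*sh)[("B", "B")]
        for i in range(3):
            for j in range(i, 3):
                def q(si, sj, h):
                    b = moved_shell(moved_shell(sh[1], i, si * h), j, sj * h)
                    return eri_quartet(sh[0], b, sh[2], sh[3])

                def fd(h):
                    return (q(1, 1, h) - q(1, -1, h) - q(-1, 1, h)
                            + q(-1, -1, h)) / (4 * h * h)

                # Richardson step-halving removes the leading h^2 error
                est = (4 * fd(1e-3) - fd(2e-3)) / 3
                assert np.abs(est - d2[i, j]).max() < 1e-7


class TestDerivativeCompleteness:
    def test_four_center_first_derivatives_vs_fd(self):
        rng = np.random.default_rng(26)
        h = 1e-5
        for _ in range(4):
            sh = [random_shell(rng) for _ in range(4)]
            d1 = quartet_first_derivatives(*sh)
            for ci, cen in enumerate("ABCD"):
                for d in range(3):
                    p = list(sh)
                    p[ci] = moved_shell(sh[ci], d, h)
                    m = list(sh)
                    m[ci] = moved_shell(sh[ci], d, -h)
                    fd = (eri_quartet(*p) - eri_quartet(*m)) / (2 * h)
                    assert np.abs(fd - d1[cen][d]).max() < 1e-7

    def test_translational_sum_zero(self):
        rng = np.random.default_rng(27)
        for _ in range(6):
            sh = [random_shell(rng) for _ in range(4)]
            d1 = quartet_first_derivatives(*sh)
            total = d1["A"] + d1["B"] + d1["C"] + d1["D"]
            assert np.abs(total).max() < 1e-10

    def test_second_derivative_pair_symmetry(self):
        rng = np.random.default_rng(28)
        sh = [random_shell(rng, l=1) for _ in range(4)]
        d2 = quartet_second_derivatives(*sh)
        for (X, Y), blk in d2.items():
            if X == Y:
                assert np.abs(blk - blk.transpose(1, 0, 2, 3, 4, 5)
                              ).max() < 1e-10


@pytest.fixture(scope="module")
def h2_state():
    mol = parse_xyz("2\nc\nH 0.03 -0.02 0\nH 0.01 0.02 0.76\n")
    basis = load_basis("sto-3g", mol)
    return mol, basis, run_scf(mol, basis, conv=1e-11)


class TestContractions:
    def test_gradient_matches_frozen_density_fd(self, h2_state):
        mol, basis, st = h2_state
        D = st.D
        g = eri_gradient_contraction(D, D, basis)

        def e2e(m):
            b = load_basis("sto-3g", m)
            G = build_fock_2e(b, D / 2, 1.0)
            return 0.5 * np.einsum("mn,mn->", D, G)

        h = 1e-5
        for a in range(2):
            for d in range(3):
                fd = (e2e(mol.displaced(a, d, h))
                      - e2e(mol.displaced(a, d, -h))) / (2 * h)
                assert abs(fd - g[a, d]) < 1e-7

    def test_zero_density_zero_gradient(self, h2_state):
        _, basis, _ = h2_state
        z = np.zeros((basis.n_ao, basis.n_ao))
        assert np.abs(eri_gradient_contraction(z, z, basis)).max() == 0.0

    def test_gradient_translational_sum(self, scf_h2o):
        g = eri_gradient_contraction(scf_h2o.D, scf_h2o.D, scf_h2o.basis)
        assert np.abs(g.sum(axis=0)).max() < 1e-9

    def test_gradient_rotational_covariance(self, h2_state):
        """Rotating the molecule rotates the contracted gradient."""
        mol, basis, st = h2_state
        g0 = eri_gradient_contraction(st.D, st.D, basis)
        th = 0.37
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        mol_r = mol.with_coords(mol.coords @ R.T)
        basis_r = load_basis("sto-3g", mol_r)
        st_r = run_scf(mol_r, basis_r, conv=1e-11)
        g_r = eri_gradient_contraction(st_r.D, st_r.D, basis_r)
        assert np.abs(g0 @ R.T - g_r).max() < 1e-9

    def test_hessian_contraction_vs_fd_of_gradient(self, h2_state):
        mol, basis, st = h2_state
        D = st.D
        Hc = eri_hessian_contraction(D, D, basis)
        h = 1e-3
        for a in range(2):
            for d in range(3):
                bp = load_basis("sto-3g", mol.displaced(a, d, h))
                bm = load_basis("sto-3g", mol.displaced(a, d, -h))
                fd = (eri_gradient_contraction(D, D, bp)
                      - eri_gradient_contraction(D, D, bm)) / (2 * h)
                assert np.abs(fd - Hc[:, :, a, d]).max() < 1e-6

    def test_hessian_contraction_symmetries(self, scf_h2o):
        Hc = eri_hessian_contraction(scf_h2o.D, scf_h2o.D, scf_h2o.basis)
        assert np.abs(Hc - Hc.transpose(2, 3, 0, 1)).max() < 1e-10
        assert np.abs(Hc.sum(axis=0)).max() < 1e-7
        assert np.abs(Hc.sum(axis=2)).max() < 1e-7

    def test_fock_derivative_vs_frozen_density_fd(self, scf_h2o):
        mol, basis = scf_h2o.molecule, scf_h2o.basis
        D = scf_h2o.D
        dF = fock_derivative_2e(D, basis)
        h = 1e-4
        for a in range(mol.n_atoms):
            for d in range(3):
                bp = load_basis("sto-3g", mol.displaced(a, d, h))
                bm = load_basis("sto-3g", mol.displaced(a, d, -h))
                fd = (build_fock_2e(bp, D / 2, 1.0)
                      - build_fock_2e(bm, D / 2, 1.0)) / (2 * h)
                assert np.abs(fd - dF[a, d]).max() < 1e-7

    def test_fock_derivative_sum_and_zero(self, scf_h2o):
        dF = fock_derivative_2e(scf_h2o.D, scf_h2o.basis)
        assert np.abs(dF.sum(axis=0)).max() < 1e-9
        z = np.zeros_like(scf_h2o.D)
        assert np.abs(fock_derivative_2e(z, scf_h2o.basis)).max() == 0.0

    def test_density_shape_validated(self, scf_h2o):
        with pytest.raises(ValueError):
            eri_gradient_contraction(np.zeros((2, 2)), np.zeros((2, 2)),
                                     scf_h2o.basis)
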