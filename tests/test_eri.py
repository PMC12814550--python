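"""The shell-quartet ERI engine: Boys function, recurrence correctness
against the independent late-contraction reference, permutational
symmetry, Cauchy-Schwarz screening and the Fock distribution."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from molhess.basis import load_basis, normalized_shell
from molhess.boys import BoysDomainError, boys, boys_array
from molhess.eri import (ERICache, NumericalIntegrityError, build_fock_2e,
                         contract_density, eri_quartet, full_eri_tensor,
                         schwarz_bounds)
from molhess.oracles import boys_reference, eri_quartet_reference

from conftest import TOL, random_shell


class TestBoys:
    def test_zero_argument_closed_form(self):
        f = boys(10, 0.0)
        expected = 1.0 / (2 * np.arange(11) + 1)
        assert np.abs(f - expected).max() == 0.0

    @pytest.mark.parametrize("T", [0.3, 1.0, 7.5, 24.0, 60.0, 95.0])
    def test_quadrature_oracle(self, T):
        f = boys(8, T)
        for m in (0, 3, 8):
            ref = quad(lambda t: t ** (2 * m) * math.exp(-T * t * t),
                       0, 1, epsabs=1e-15, epsrel=1e-14)[0]
            assert abs(f[m] - ref) < TOL["boys"]

    def test_large_argument_asymptotic(self):
        T = 1e4
        assert abs(boys(0, T)[0] - 0.5 * math.sqrt(math.pi / T)) < 1e-12

    def test_negative_argument_rejected(self):
        with pytest.raises(BoysDomainError):
            boys(2, -1.0)

    def test_order_monotonicity(self):
        f = boys(12, 3.7)
        assert np.all(np.diff(f) < 0) and f[0] <= 1.0

    @pytest.mark.parametrize("T", [0.5, 5.0, 50.0])
    def test_downward_recursion_stability(self, T):
        """Reconstructing F_0 from the highest order must reproduce the
        direct value: the downward pass is the stable direction."""
        f = boys(20, T)
        v = f[20]
        for m in range(19, -1, -1):
            v = (2 * T * v + math.exp(-T)) / (2 * m + 1)
        assert abs(v - f[0]) < 1e-13

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(3)
        T = np.concatenate([[0.0, 79.99, 80.01, 1e5], rng.uniform(0, 150, 50)])
        vec = boys_array(16, T)
        ref = np.array([boys(16, t) for t in T])
        assert np.abs(vec - ref).max() < 1e-14

    def test_bounds_property(self):
        """0 < F_{m+1}(T) < F_m(T) <= 1 for every T > 0 (property-based)."""
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=80, deadline=None, derandomize=True)
        @given(st.floats(min_value=1e-12, max_value=1e6,
                         allow_nan=False, allow_infinity=False))
        def check(T):
            f = boys(10, T)
            assert f[0] <= 1.0
            assert np.all(f > 0)
            assert np.all(np.diff(f) < 0)

        check()

    def test_gammainc_reference_agreement(self):
        rng = np.random.default_rng(4)
        for T in rng.uniform(0.01, 200, 25):
            assert np.abs(boys(10, T) - boys_reference(10, T)).max() < TOL["boys"]


class TestQuartets:
    def test_concentric_s_closed_form(self):
        """Four identical concentric s primitives: (ss|ss) =
        2 pi^{5/2} / ((2a)^2 sqrt(4a)) F0(0) for unnormalized prims."""
        from molhess.basis import GaussianShell, _primitive_norm

        a = 0.8
        sh = GaussianShell(0, 0, np.array([a]), np.array([1.0]), np.zeros(3))
        norm = sh.coefficients[0]
        val = eri_quartet(sh, sh, sh, sh)[0, 0, 0, 0] / norm ** 4
        ref = 2 * math.pi ** 2.5 / ((2 * a) ** 2 * math.sqrt(4 * a))
        assert abs(val - ref) < 1e-12

    def test_permutational_symmetry_random(self):
        rng = np.random.default_rng(11)
        for _ in range(8):
            sh = [random_shell(rng) for _ in range(4)]
            g = eri_quartet(*sh)
            for perm, axes in ((
                (1, 0, 2, 3), (1, 0, 2, 3)), ((0, 1, 3, 2), (0, 1, 3, 2)),
                    ((2, 3, 0, 1), (2, 3, 0, 1)), ((3, 2, 1, 0), (3, 2, 1, 0))):
                gp = eri_quartet(*[sh[p] for p in perm])
                assert np.abs(np.transpose(gp, axes) - g).max() \
                    < TOL["perm_symmetry"]

    def test_late_contraction_reference_random(self):
        rng = np.random.default_rng(12)
        for _ in range(6):
            sh = [random_shell(rng) for _ in range(4)]
            fast = eri_quartet(*sh)
            slow = eri_quartet_reference(*sh)
            assert np.abs(fast - slow).max() < TOL["eri_paths"]

    def test_high_angular_momentum(self):
        rng = np.random.default_rng(13)
        sh = [random_shell(rng, l=l, max_prim=1) for l in (3, 4, 1, 0)]
        assert np.abs(eri_quartet(*sh) - eri_quartet_reference(*sh)).max() \
            < TOL["eri_paths"]

    def test_coincident_centers_regular(self):
        """All four centers on one point exercises the T -> 0 Boys limit
        without special-casing."""
        rng = np.random.default_rng(14)
        sh = [random_shell(rng, l=1, center_span=0.0) for _ in range(4)]
        fast = eri_quartet(*sh)
        slow = eri_quartet_reference(*sh)
        assert np.abs(fast - slow).max() < TOL["eri_paths"]


class TestSchwarz:
    def test_bounds_are_conservative(self, h2o):
        basis = load_basis("sto-3g", h2o)
        screen = schwarz_bounds(basis)
        ns = basis.n_shells
        for i in range(ns):
            for j in range(ns):
                for k in range(ns):
                    for l in range(ns):
                        blk = eri_quartet(basis.shells[i], basis.shells[j],
                                          basis.shells[k], basis.shells[l])
                        bound = screen.Q_pair[i, j] * screen.Q_pair[k, l]
                        assert np.abs(blk).max() <= bound + 1e-12

    def test_zero_threshold_keeps_everything(self, scf_h2o):
        basis = scf_h2o.basis
        screen = schwarz_bounds(basis, threshold=0.0)
        F1 = contract_density(basis, scf_h2o.D / 2, 1.0, screen)
        F2 = contract_density(basis, scf_h2o.D / 2, 1.0, None)
        assert np.abs(F1 - F2).max() == 0.0

    def test_screened_fock_error_bounded(self, scf_h2o_def2):
        basis = scf_h2o_def2.basis
        screen = schwarz_bounds(basis, threshold=1e-12)
        Dh = scf_h2o_def2.D / 2
        F_s = contract_density(basis, Dh, 1.0, screen)
        F_u = contract_density(basis, Dh, 1.0, None)
        assert np.abs(F_s - F_u).max() < 1e-10

    def test_distant_pair_screened_out(self):
        a = normalized_shell(0, 0, [1.2], [1.0], [0.0, 0.0, 0.0])
        b = normalized_shell(1, 0, [1.1], [1.0], [0.0, 0.0, 50.0])
        blk = eri_quartet(a, b, a, b)
        assert math.sqrt(abs(blk[0, 0, 0, 0])) < 1e-12


class TestFockBuild:
    def test_zero_density(self, scf_h2):
        F = build_fock_2e(scf_h2.basis, np.zeros((2, 2)))
        assert np.abs(F).max() == 0.0

    def test_exchange_fraction_against_tensor(self, scf_h2):
        basis = scf_h2.basis
        D = scf_h2.D / 2
        g = full_eri_tensor(basis)
        diff = build_fock_2e(basis, D, c_x=0.0) - build_fock_2e(basis, D, c_x=1.0)
        ref = np.einsum("mstn,ts->mn", g, D)
        assert np.abs(diff - ref).max() < 1e-12

    def test_two_electron_energy_identity(self, scf_h2o):
        basis = scf_h2o.basis
        Dh = scf_h2o.D / 2
        G = build_fock_2e(basis, Dh, 1.0)
        g = full_eri_tensor(basis)
        e_ref = (np.einsum("mnts,mn,ts->", g, Dh, Dh) * 2
                 - np.einsum("mstn,mn,ts->", g, Dh, Dh))
        assert abs(np.einsum("mn,mn->", Dh, G) - e_ref) < 1e-10

    def test_quartet_and_dense_paths_agree(self, scf_h2o):
        basis = scf_h2o.basis
        rng = np.random.default_rng(0)
        X = rng.normal(size=(basis.n_ao, basis.n_ao))  # non-symmetric
        cache = ERICache(basis)
        F_q = build_fock_2e(basis, X, 0.7, cache=cache, method="quartets")
        F_d = build_fock_2e(basis, X, 0.7, cache=cache, method="auto")
        assert np.abs(F_q - F_d).max() < 1e-11

    def test_shape_mismatch(self, scf_h2o):
        with pytest.raises(ValueError):
            build_fock_2e(scf_h2o.basis, np.zeros((3, 3)))

    def test_negative_diagonal_rejected(self, h2o):
        # a healthy basis must never trip the integrity check
        basis = load_basis("sto-3g", h2o)
        schwarz_bounds(basis)  # no NumericalIntegrityError
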