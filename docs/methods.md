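# Methods

`molhess` computes harmonic infrared spectra of closed-shell molecules
from fully analytic derivatives of the self-consistent-field energy. This
note records the models, conventions, numerical choices and limitations;
every empirical statement here is reproduced by the test suite or by
`scripts/acceptance.py`.

## Electronic structure model

The reference state is restricted closed-shell SCF over contracted
spherical Gaussian basis functions: Hartree–Fock by default, and a
hybrid-DFT-ready variant through an exact-exchange fraction `c_x` and a
pluggable exchange–correlation functional evaluated on a molecular grid.
Only even-electron, spin-restricted systems are treated. The total
density convention is `D = 2 C_occ C_occ^T`; the two-electron operator
used everywhere is

    G[D/2]_mn = sum_ts (D/2)_ts [ 2(mn|ts) − c_x (ms|tn) ],

so `F = h + G[D/2] (+ V_xc)` and `E_2e = tr((D/2) G[D/2])`. DIIS on the
`FDS−SDF` commutator (subspace ≤ 10) accelerates convergence; the start
guess is the core Hamiltonian; orthogonalization is symmetric `S^{-1/2}`
with a canonical fallback when the smallest overlap eigenvalue drops
below 1e-8. Convergence demands both the energy change and the max norm
of the commutator below the threshold (default 1e-6; the tests use
tighter values when feeding finite-difference oracles).

## Integral engine

Electron-repulsion integrals are evaluated per shell quartet by the
Obara–Saika scheme in nine steps: auxiliary integrals from pairwise
overlaps and the Boys function; vertical recurrences building angular
momentum on the ket (D) and bra (B) centers of the primitive Cartesian
integrals; early contraction; a horizontal recurrence transferring
angular momentum from D to C; an early transformation of the ket side to
real solid harmonics; the mixed-representation horizontal recurrence from
B to A; the final bra transformation; and distribution into Fock-type
targets. Cartesian components are ordered lexicographically
(xx, xy, xz, yy, yz, zz); spherical components run m = −l..+l in the
standard real-harmonic convention (generated symbolically and verified
against scipy's spherical harmonics). Shells up to l = 4 are supported;
contractions are segmented and renormalized to unit self-overlap on
load.

The Boys function uses an order-selected scheme: a tabulated grid
(step 0.02 on [0, 80]) with a seven-term downward Taylor expansion, a
convergent power series with downward recursion as the general fallback,
and the asymptotic closed form beyond the table. Absolute accuracy is
~5e-15 against the incomplete-gamma reference.

Screening follows the Cauchy–Schwarz bound `|(ij|kl)| ≤ Q_ij Q_kl` with
`Q_ij = sqrt(max (ij|ij))` per shell pair (default drop threshold
1e-12). Fock builds iterate canonical shell quartets (i ≥ j, k ≥ l,
ij ≥ kl), distributing every distinct index permutation; for systems
with up to 48 AOs the distributed tensor is cached once and repeated
builds (SCF iterations, response solves) contract it directly — an
identical-result amortization, with the per-quartet path retained and
tested.

## Geometric derivatives of integrals

All derivatives rest on one rule: differentiating a primitive Cartesian
Gaussian with respect to its center raises the target component with
`2·alpha` and lowers it with the Cartesian quantum number. For
electron-repulsion integrals the rule is applied before contraction
(derivative vertical recurrence); every horizontal transfer whose
interatomic distance involves a differentiated center is replaced by its
differentiated variant, which couples in the lower-derivative integral
tables through Kronecker deltas. Derivatives are generated directly on
the B and D centers; bra/ket shell swaps provide A and C; the remaining
mixed pairs follow from the exact blockwise translational invariance
(the same-component first derivatives over the four centers sum to
zero). The second-order derivative operator contains delta cross terms
(`N_j(b+1_i) = N_j(b)+delta_ij`) that are easy to drop when transcribing;
the implementation derives the operator from first principles and the
suite arbitrates it against finite differences of the plain quartets
(agreement ~1e-9 and better on randomized l ≤ 2 suites).

Two-electron gradient and Hessian contributions are accumulated quartet
by quartet as double contractions of the derivative integrals with two
density matrices; no derivative integral is stored globally. One-electron
integrals (overlap, kinetic, nuclear attraction, fixed-origin dipole) use
Hermite/McMurchie–Davidson expansions with the same shift-relation
derivatives; operator-center derivatives of the nuclear attraction follow
from translational invariance of each single-nucleus term.

## Response equations and Hessian assembly

For each of the 3N nuclear perturbations the occupied-virtual response
U_ai solves

    (eps_i − eps_a) U_ai − G_ai[U] = F^(xi)_ai − eps_i S^(xi)_ai + G_ai[D^S],

where `F^(xi)` is the frozen-density derivative Fock matrix,
`D^S = −2 C_o S^(xi)_oo C_o^T` is the occupied-occupied relaxation fixed
by orthonormality (U_ij = −1/2 S^(xi)_ij), and G contracts the
symmetrized response density (plus the XC kernel under DFT). All 3N
systems share one reduced space: block-Krylov vectors preconditioned by
the orbital-energy-difference diagonal, converged systems frozen,
default residual tolerance 1e-6 (1e-8 inside Hessian assembly). A dense
direct solve built from the full MO integral tensor serves as the test
oracle, never as the production path.

The Hessian is assembled as frozen-density second-derivative terms
(nuclear repulsion, one-electron, two-electron, energy-weighted overlap,
XC) plus the orbital-relaxation cross term
`tr(D^xi F^(zeta)) − tr(W^xi S^(zeta))`. The perturbed energy-weighted
density uses the gauge-invariant form `W = 1/2 D F D` differentiated
directly; the per-orbital expression is not invariant under the
occupied-occupied gauge chosen for the response density. Correctness of
the whole grouping is defined against central finite differences of the
analytic gradient (elementwise agreement ≤ 1e-5 hartree/bohr² on the
bundled water and ammonia fixtures, observed ~5e-7). The dipole-moment
gradient combines the nuclear delta term, the derivative dipole
integrals with the frozen density, and the response density contracted
with the dipole matrices; it satisfies the total-charge sum rule
(Σ_A ∂mu_x/∂x_A = q_total) for neutral and charged systems.

## Exchange–correlation layer

The molecular grid is Gauss–Chebyshev (second kind) radial shells under
the Becke map `r = R(1+x)/(1−x)` with per-element radial scales, times a
product angular rule — Gauss–Legendre in cos(theta) × uniform phi —
exact for spherical harmonics up to degree 2·n_theta − 1, with Becke
fuzzy-cell partitioning (three smoothing iterations, no size
adjustment). The product rule was chosen over tabulated spherical
designs because its accuracy is provable at every preset and it needs no
embedded weight tables. Presets: coarse (30×8), medium (60×16), fine
(75×18), veryfine (95×24); "fine" is the default production level.
The converged-density electron count integrates to n_el within 1e-6
from medium upward (observed 1.1e-7 at fine for water).

Functionals are providers returning pointwise first and second
derivatives in all spin-resolved channels (f_rho_alpha, f_sigma_alpha_alpha,
f_rho_rho, f_rho_sigma, f_sigma_sigma, ...). Built-ins: Dirac/Slater LDA
exchange with closed-form derivatives, and two analytic test functionals
(c·rho², c·sigma) whose exact derivatives make the chain-rule assemblies
testable to tight tolerances. Production GGA/hybrid functionals can be
supplied through the same interface; they are not bundled.

Three assemblies implement the XC derivative theory at frozen density
matrix: the second-derivative energy term, the perturbed XC matrix
entering the response right-hand sides, and the kernel contraction of a
trial density. Every term is individually toggleable (`rho_rho`,
`rho_sigma`, `rho_second_deriv`, `sigma_*`, `grad_*`; `kernel_*`,
`moved_basis_*`, `perturbed_gradient`), and the suite checks both that
the full sums match finite differences and that dropping terms breaks
the match. Geometric derivatives of the quadrature weights are excluded
(fixed-weight approximation); all analytic formulas and their FD oracles
share that convention, and a numeric strict mode for the gradient adds
the quadrature-motion correction by rebuilding the grid. At the fine
grid the fixed-weight error observed on H2 gradients is ~2e-7
hartree/bohr.

## Vibrational analysis and spectra

The mass-weighted Hessian `M^{-1/2} H M^{-1/2}` is diagonalized;
translations and rotations are projected out via mass-weighted Eckart
vectors (rotations about principal axes, a vanishing-inertia axis —
threshold 1e-8 amu·bohr² — dropped for linear molecules), and exactly
3N−6 (or 3N−5, or 3N−3 for atoms) modes are returned. Imaginary
frequencies are encoded as negative wavenumbers. Masses default to the
most-abundant-isotope table and are overridable per atom.

IR intensities are Napierian integrated attenuation coefficients,

    A_k = (1/(4 pi eps0)) (N_A pi / 3 c²) |d mu/d Q_k|²,

with `|d mu/dQ|²` in e²/amu and the unit prefactor evaluated from CODATA
constants at run time (974.88 km/mol·amu/e²). Spectra are sums of
Lorentzians `(gamma/pi)/((w0−w)² + gamma²)` (HWHM gamma, default
10 cm⁻¹; each line integrates to A_k), on a 1 cm⁻¹ grid spanning the
sticks ±10 gamma by default; a Gaussian shape with matched HWHM sits
behind a flag. A single multiplicative frequency scaling factor can be
applied before broadening (default 1.0 — fitting such factors to
experiment is out of scope).

Partial-Hessian analysis extracts the subblock of the full Hessian for
an atom subset, analyzes it with the subset masses and the matching rows
of the full-system dipole gradient (no re-derivation), and projects the
subset's own rigid-body space. Mode localization reports, per mode, the
fraction of mass-weighted displacement norm² inside each subset of a
disjoint partition; over a full partition the fractions sum to 1.

## Synthetic large-system fixture

`synthetic_protein_hessian` emulates only the *bookkeeping* of a
protein-scale normal-mode problem: a reproducible random geometry and
isotope-mass mixture for 1152 atoms and a symmetric-positive-definite
mass-weighted Hessian constructed on the exact rigid-body complement
(low-rank random part plus a positive diagonal, assembled without any
O(n³) product). It makes mode counting, projection and subsystem
splitting testable at full dimension (3456); it does not emulate force
constants, sparsity patterns or spectral densities of real proteins, so
passing those tests says nothing about chemical accuracy at that scale —
that burden is carried by the small-molecule FD oracles.

## Fixtures and problem sizes

Bundled geometries: H2, H2O, NH3 and formamide at HF/STO-3G stationary
points prepared with this package's own analytic gradients (gradient
max-norm ≤ 2e-7 hartree/bohr; formamide is the symmetry-broken
pyramidal-N minimum), and a hydrogen-bonded water dimer at a
literature-style geometry that is deliberately not a stationary point.
Basis sets bundled as text: STO-3G (H, He, C, N, O) and def2-SV(P)
(H, C, N, O), both segmented, parsed from a Gaussian-94-style dialect or
an equivalent JSON structure and renormalized on load.

Finite-difference oracles use central differences with steps 1e-4 bohr
(integral first derivatives), 1e-3 bohr (energies/gradients; 4-point
stencil for the gradient check) and two-step central or Richardson
step-halving for second derivatives — chosen to balance truncation
against round-off at double precision. Randomized recursion suites use
seeded generators with mixtures of s/p/d shells and 1–2 primitives.

## Known limitations

- Closed-shell only; no ECPs, no general contractions, no l > 4.
- No meta-GGA/range-separated functionals; grid-weight derivatives only
  via the numeric strict mode; B3LYP-class production functionals must be
  supplied externally through the provider interface.
- The dense-tensor Fock amortization caps at 48 AOs; beyond that every
  build pays the full quartet loop (fine at fixture scale, slow beyond).
- No thermochemistry, Raman intensities, anharmonic corrections, or
  fragment capping for partial-Hessian production use.
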