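"""Bundled fixture systems.

Small molecules at their HF/STO-3G stationary geometries (prepared with
this package's own analytic gradients and Hessians, gradient max-norm
below 1e-7 hartree/bohr), a hydrogen-bonded water dimer at a standard
literature-style geometry (not a stationary point of any method here),
and a synthetic 1152-atom system with a reproducible random
symmetric-positive-definite Hessian whose rigid-body null space is
projected exactly -- the desk-scale stand-in for a protein-sized
normal-mode problem.
"""

from __future__ import annotations

import numpy as np

from .molecule import Molecule, parse_xyz

FIXTURE_XYZ = {
    "h2": """2
H2, HF/STO-3G stationary geometry
H      0.000000000000     0.000000000000     0.013885073578
H      0.000000000000     0.000000000000     0.726114926422
""",
    "h2o": """3
water, HF/STO-3G stationary geometry
O      0.000000000000     0.000000000000     0.150168163280
H      0.000000000000     0.758080671110    -0.485634081715
H      0.000000000000    -0.758080671152    -0.485634081565
""",
    "nh3": """4
ammonia, HF/STO-3G stationary geometry
N      0.000000000027    -0.000073921325     0.142852504548
H      0.000000000036     0.940551044388    -0.282973474385
H      0.814548635780    -0.470288561570    -0.283189515151
H     -0.814548635842    -0.470288561493    -0.283189515012
""",
    "formamide": """6
formamide, HF/STO-3G minimum (pyramidal N at this level)
C      0.020956824240     0.442531683260    -0.048346133897
O      1.138892628040     0.902244625692     0.080774368928
N     -1.155157963316     1.240563573929    -0.255250851838
H     -0.203698153960    -0.638002492173    -0.081115890795
H     -1.981750796436     0.835830735713     0.199311982440
H     -1.019242538505     2.206831873633     0.065290714258
""",
    "water_dimer": """6
water dimer, hydrogen-bonded arrangement (literature-style geometry)
O     -1.551007  -0.114520   0.000000
H     -1.934259   0.762503   0.000000
H     -0.599677   0.040712   0.000000
O      1.350625   0.111469   0.000000
H      1.680398  -0.373741  -0.758561
H      1.680398  -0.373741   0.758561
""",
}

FIXTURE_NAMES = tuple(FIXTURE_XYZ) + ("synthetic_hessian_1152",)


def fixture_molecule(name: str) -> Molecule:
    if name not in FIXTURE_XYZ:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return parse_xyz(FIXTURE_XYZ[name])


def synthetic_protein_hessian(n_atoms: int = 1152, seed: int = 7):
    """Reproducible synthetic normal-mode problem of a large nonlinear
    system: random geometry and masses, Cartesian Hessian built SPD on
    the complement of the exact rigid-body space.

    Returns (coords bohr, masses amu, H hartree/bohr^2).  A projected
    vibrational analysis yields exactly 3*n_atoms - 6 modes.
    """
    from .vibrations import _rigid_body_vectors

    rng = np.random.default_rng(seed)
    coords = rng.uniform(-20.0, 20.0, size=(n_atoms, 3))
    masses = rng.choice([1.00782503207, 12.0, 14.003074004, 15.994914620,
                         31.972070999], size=n_atoms,
                        p=[0.5, 0.3, 0.09, 0.1, 0.01])
    n3 = 3 * n_atoms
    B = _rigid_body_vectors(coords, masses)
    # SPD mass-weighted Hessian on the rigid-body complement,
    # Hmw = P (A A^T + D) P, assembled without any O(n^3) product:
    # P A is cheap (A is n3 x 40) and P D P expands into rank-6 updates.
    A = rng.standard_normal((n3, 40)) / np.sqrt(n3)
    d = rng.uniform(1e-4, 0.5, n3)
    PA = A - B @ (B.T @ A)
    Hmw = PA @ PA.T
    BtD = B.T * d[None, :]                     # (6, n3)
    Hmw += np.diag(d)
    Hmw -= B @ BtD
    Hmw -= BtD.T @ B.T
    Hmw += B @ (BtD @ B) @ B.T
    sq = np.repeat(np.sqrt(masses), 3)
    H = Hmw * sq[:, None] * sq[None, :]
    return coords, masses, 0.5 * (H + H.T)
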