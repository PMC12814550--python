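"""Density-functional gradient of H2 with the built-in LDA exchange.

Runs a Kohn-Sham SCF (Slater exchange, no exact exchange), evaluates
the analytic nuclear gradient including the grid XC term, and verifies
it against central finite differences of the total energy.
"""

import numpy as np

from molhess.basis import load_basis
from molhess.hessian import analytic_gradient
from molhess.molecule import parse_xyz
from molhess.scf import run_scf
from molhess.xc import SlaterExchange, build_grid

mol = parse_xyz("2\nstretched H2\nH 0 0 0\nH 0 0 0.80\n")


def scf(m):
    basis = load_basis("sto-3g", m)
    grid = build_grid(m, "fine")
    return run_scf(m, basis, method="hybrid", c_x=0.0,
                   functional=SlaterExchange(), grid=grid, conv=1e-9)


state = scf(mol)
g = analytic_gradient(state).g
h = 1e-3
fd = (scf(mol.displaced(1, 2, h)).E_total
      - scf(mol.displaced(1, 2, -h)).E_total) / (2 * h)
print(f"LDA-exchange energy:     {state.E_total:.8f} hartree")
print(f"analytic dE/dz(H2):      {g[1, 2]: .8f} hartree/bohr")
print(f"finite-difference check: {fd: .8f} hartree/bohr")
print(f"difference:              {abs(fd - g[1, 2]):.2e} "
      "(fixed-weight grid approximation + FD truncation)")
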