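"""Partial-Hessian subsystem analysis of formamide.

Computes the full analytic Hessian once, then diagonalizes only the
subblock belonging to the heavy-atom skeleton (C, O, N), reusing the
matching rows of the full dipole gradient.  Compares the carbonyl
stretch from the partial analysis with the full treatment -- the
partial-Hessian approximation neglects coupling to the hydrogens.
"""

import numpy as np

from molhess.config import RunConfig
from molhess.fixtures import fixture_molecule
from molhess.vibrations import partial_hessian, vibrational_analysis
from molhess.workflows import compute_hessian_bundle

mol = fixture_molecule("formamide")
cfg = RunConfig(basis="sto-3g", scf_conv=1e-8)
bundle = compute_hessian_bundle(mol, cfg)
H = bundle["hessian"].H
dmu = bundle["dipole_gradient"].dmu

full = vibrational_analysis(H, dmu, mol.masses, mol.coords)
heavy = partial_hessian(H, dmu, mol.masses, mol.coords, [0, 1, 2])

print("full analysis:    %d modes" % full.n_modes)
print("heavy-atom block: %d modes (C, O, N only)" % heavy.n_modes)
print("heavy-block mode   nearest full-system mode   shift/cm^-1")
for w in heavy.frequencies:
    near = full.frequencies[np.argmin(np.abs(full.frequencies - w))]
    print(f"{w:14.1f} {near:22.1f} {w - near:15.1f}")
print("the shifts measure the skeleton-hydrogen coupling that the "
      "partial-Hessian approximation discards")
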