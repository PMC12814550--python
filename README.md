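# molhess

Analytic molecular Hessians and harmonic infrared spectra for
closed-shell molecules, built on Obara–Saika electron-repulsion
integrals and their first- and second-order geometric derivatives.

Predicting an IR spectrum requires the second derivatives of the
electronic energy with respect to nuclear positions (the Hessian) and
the derivatives of the dipole moment along the normal modes. Computing
these analytically — rather than by displacing every atom and repeating
the energy calculation — is what makes vibrational analysis of larger
systems practical, and it is the part of a quantum chemistry code where
most of the machinery lives. This package implements that machinery at
desk scale, in plain scientific Python, for people who want a complete,
transparent, test-anchored reference implementation: students of
analytic derivative theory, method developers prototyping against an
independent check, and anyone who needs harmonic IR spectra of small
closed-shell molecules with every intermediate inspectable.

## What is inside

- **Integrals.** Shell-quartet electron-repulsion integrals (ij|kl) over
  contracted spherical Gaussians by the nine-step Obara–Saika scheme:
  Boys-function auxiliaries, vertical recurrences on the ket and bra,
  early contraction, horizontal transfers with an early switch to the
  spherical representation, Cauchy–Schwarz screening. One-electron
  integrals via Hermite expansions.
- **Geometric derivatives.** First and second derivatives of all
  integrals from the primitive shift relation
  d/dA_i = 2·alpha·(raise i) − N_i·(lower i), with differentiated
  horizontal recurrences carrying the Kronecker-delta couplings, and
  direct double contraction with density matrices into gradient and
  Hessian contributions.
- **Reference state and response.** Restricted SCF (Hartree–Fock, or
  hybrid-DFT-ready via an exact-exchange fraction and a pluggable
  XC functional on a Becke-partitioned molecular grid), and the
  coupled-perturbed HF/KS equations

      (eps_i − eps_a) U_ai − G_ai[U] = F^(xi)_ai − eps_i S^(xi)_ai + G_ai[D^S]

  solved for all 3N nuclear perturbations in one shared reduced space.
- **Spectroscopy.** Mass-weighted normal-mode analysis with exact
  rigid-body projection, IR intensities as Napierian integrated
  attenuation coefficients

      A_k = (1/(4 pi eps0)) (N_A pi / 3 c²) |d mu/d Q_k|²

  (unit prefactor 974.88 km/mol·amu/e², evaluated from CODATA constants
  at run time), Lorentzian broadening with a chosen HWHM, optional
  frequency scaling, partial-Hessian subsystem analysis and quantitative
  mode localization.

## Worked example

```python
from molhess.config import RunConfig
from molhess.fixtures import fixture_molecule
from molhess.workflows import compute_ir

mol = fixture_molecule("h2o")
bundle = compute_ir(mol, RunConfig(basis="sto-3g", scf_conv=1e-9))
vib = bundle["vibrations"]
for w, a in zip(vib.frequencies, vib.intensities):
    print(f"{w:10.1f} cm^-1   {a:8.2f} km/mol")
```

prints the three fundamentals of water at HF/STO-3G:

```
    2170.0 cm^-1       7.24 km/mol
    4140.0 cm^-1      44.29 km/mol
    4391.1 cm^-1      29.97 km/mol
```

The bend (2170) and the symmetric/asymmetric stretches (4140/4391) are
the classic harmonic values for this model chemistry; harmonic
minimal-basis frequencies sit far above experiment, which is what a
single multiplicative scaling factor applied before broadening would
compensate. `bundle["spectrum"]` holds the Lorentzian-broadened
absorption profile on a 1 cm⁻¹ grid.

The same pipeline is scriptable from the shell:

```sh
molhess ir water.xyz --out spectrum.csv --sticks-out sticks.tsv
molhess hessian water.xyz --out hessian.npz
molhess partial-hessian hessian.npz --subset 0,1,2
```

and `examples/` contains one short narrative script per capability
(SCF, IR pipeline, partial Hessians, mode localization, protein-scale
mode bookkeeping on a synthetic Hessian, DFT gradients).

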