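"""Broadened IR spectra from stick data.

sigma(omega) = sum_k A_k f(omega; omega_k0, gamma) with a Lorentzian
line shape f = (1/pi) gamma / ((omega_k0 - omega)^2 + gamma^2) (HWHM
gamma); each line integrates to A_k over the full axis.  A Gaussian
shape with the same HWHM is available behind a flag.  Harmonic
frequencies may be scaled by a single multiplicative factor before
broadening.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class StickSpectrum:
    frequencies: np.ndarray          # cm^-1
    intensities: np.ndarray          # km/mol
    labels: list | None = None

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.frequencies.shape != self.intensities.shape:
            raise ValueError("frequency/intensity length mismatch")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensity")


@dataclass
class BroadenedSpectrum:
    grid: np.ndarray                 # cm^-1, strictly increasing
    sigma: np.ndarray                # km/mol per cm^-1
    gamma: float                     # HWHM, cm^-1
    scale_factor: float = 1.0
    shape: str = "lorentzian"


def apply_scaling(sticks: StickSpectrum, factor: float) -> StickSpectrum:
    """Multiply all stick frequencies by a common scaling factor."""
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    return StickSpectrum(sticks.frequencies * factor,
                         sticks.intensities.copy(), sticks.labels)


def default_grid(sticks: StickSpectrum, gamma: float,
                 spacing: float = 1.0) -> np.ndarray:
    if len(sticks.frequencies) == 0:
        return np.arange(0.0, 1.0, spacing)
    lo = max(0.0, sticks.frequencies.min() - 10 * gamma)
    hi = sticks.frequencies.max() + 10 * gamma
    return np.arange(lo, hi + spacing, spacing)


def broaden(sticks: StickSpectrum, gamma: float,
            grid: np.ndarray | None = None,
            shape: str = "lorentzian",
            scale_factor: float = 1.0) -> BroadenedSpectrum:
    """Broadened absorption spectrum on a wavenumber grid."""
    if gamma <= 0:
        raise ValueError("gamma (HWHM) must be positive")
    if scale_factor != 1.0:
        sticks = apply_scaling(sticks, scale_factor)
    if grid is None:
        grid = default_grid(sticks, gamma)
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if len(sticks.frequencies) == 0:
        warnings.warn("empty stick spectrum")
        return BroadenedSpectrum(grid, np.zeros_like(grid), gamma,
                                 scale_factor, shape)
    d = sticks.frequencies[:, None] - grid[None, :]
    if shape == "lorentzian":
        f = (gamma / math.pi) / (d * d + gamma * gamma)
    elif shape == "gaussian":
        s = gamma / math.sqrt(2 * math.log(2))   # same HWHM
        f = np.exp(-0.5 * (d / s) ** 2) / (s * math.sqrt(2 * math.pi))
    else:
        raise ValueError(f"unknown line shape {shape!r}")
    sigma = sticks.intensities @ f
    return BroadenedSpectrum(grid, sigma, gamma, scale_factor, shape)


def write_spectrum(spec: BroadenedSpectrum, path, fmt: str = "csv") -> None:
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["wavenumber_cm-1", "sigma"])
            for x, y in zip(spec.grid, spec.sigma):
                w.writerow([f"{x:.12g}", f"{y:.12g}"])
    elif fmt == "jcamp":
        with open(path, "w") as fh:
            fh.write("##TITLE=simulated IR spectrum\n##JCAMP-DX=4.24\n"
                     "##DATA TYPE=INFRARED SPECTRUM\n"
                     "##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n")
            fh.write(f"##FIRSTX={spec.grid[0]:.10g}\n"
                     f"##LASTX={spec.grid[-1]:.10g}\n"
                     f"##NPOINTS={len(spec.grid)}\n##XYDATA=(XY..XY)\n")
            for x, y in zip(spec.grid, spec.sigma):
                fh.write(f"{x:.12g}, {y:.12g}\n")
            fh.write("##END=\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_spectrum_csv(path) -> BroadenedSpectrum:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    data = np.array([[float(a), float(b)] for a, b in rows[1:]]) \
        if len(rows) > 1 else np.zeros((0, 2))
    return BroadenedSpectrum(data[:, 0], data[:, 1], gamma=float("nan"))


def write_sticks_tsv(sticks: StickSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("frequency_cm-1\tintensity_km_mol\tlabel\n")
        labels = sticks.labels or [""] * len(sticks.frequencies)
        for w, a, lab in zip(sticks.frequencies, sticks.intensities, labels):
            fh.write(f"{w:.10g}\t{a:.10g}\t{lab}\n")
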