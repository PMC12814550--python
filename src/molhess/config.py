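"""Run configuration: defaults, flat key-value config files, and
per-atom mass overrides.

The defaults mirror common production settings for this kind of
calculation: SCF convergence 1e-6 (energy change and FDS-SDF commutator),
ERI screening 1e-12, grid level 'fine', Lorentzian HWHM 10 cm^-1, no
frequency scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    method: str = "hf"                 # 'hf' or 'hybrid'
    basis: str = "sto-3g"
    c_x: float = 1.0
    functional: str | None = None      # name in molhess.xc.FUNCTIONALS
    total_charge: int = 0
    scf_conv: float = 1e-6
    eri_screen: float = 1e-12
    grid_level: str = "fine"
    cphf_tol: float = 1e-6
    gamma: float = 10.0                # Lorentzian HWHM, cm^-1
    scale_factor: float = 1.0
    line_shape: str = "lorentzian"
    project_tr: bool = True
    subsets: dict = field(default_factory=dict)   # name -> list of atoms
    mass_overrides: dict = field(default_factory=dict)  # atom index -> amu
    intensity_label_threshold: float = 500.0      # km/mol

    def __post_init__(self):
        for name in ("scf_conv", "eri_screen", "cphf_tol", "gamma"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.scale_factor <= 0:
            raise ConfigError("scale_factor must be positive")
        if self.method not in ("hf", "hybrid"):
            raise ConfigError(f"unknown method {self.method!r}")

    def header(self) -> str:
        """All settings, printed into every output for reproducibility."""
        lines = ["# run configuration"]
        for f in fields(self):
            lines.append(f"#   {f.name} = {getattr(self, f.name)}")
        return "\n".join(lines)


def parse_config(text: str) -> RunConfig:
    """Flat ``key = value`` text; '#' starts a comment.  Atom subsets are
    comma-separated index lists under keys ``subset.<name>``; mass
    overrides use ``mass.<atom_index> = <amu>``."""
    kwargs: dict = {}
    subsets: dict = {}
    masses: dict = {}
    casts = {"c_x": float, "total_charge": int, "scf_conv": float,
             "eri_screen": float, "cphf_tol": float, "gamma": float,
             "scale_factor": float, "project_tr": _parse_bool,
             "intensity_label_threshold": float}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key.startswith("subset."):
            subsets[key[7:]] = [int(x) for x in val.split(",") if x.strip()]
        elif key.startswith("mass."):
            masses[int(key[5:])] = float(val)
        elif key in casts:
            kwargs[key] = casts[key](val)
        elif key in {f.name for f in fields(RunConfig)}:
            kwargs[key] = val if val.lower() != "none" else None
        else:
            raise ConfigError(f"unknown config key {key!r}")
    return RunConfig(subsets=subsets, mass_overrides=masses, **kwargs)


def _parse_bool(s: str) -> bool:
    if s.lower() in ("1", "true", "yes", "on"):
        return True
    if s.lower() in ("0", "false", "no", "off"):
        return False
    raise ConfigError(f"not a boolean: {s!r}")


def read_config(path) -> RunConfig:
    with open(path) as fh:
        return parse_config(fh.read())
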