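"""Simulation configuration: dataclasses plus key=value file round-trip.

The configuration file is an INI-style text file whose sections mirror
the panes of the original interactive tool: beam, geometry, window,
primary_foil, secondary_foil, calculation, xray, flatness.  All
defaults are the simulator's standard calculation options (30 cm
half-range, 100 integration points in radius and angle, 60 profile
points, 3.65 cm secondary-foil radius, 2 cm calculation depth,
+-14.6 cm / 3% flatness).
"""

from __future__ import annotations

import configparser
from dataclasses import asdict, dataclass, field, fields


class ConfigError(ValueError):
    """Raised when a configuration file has invalid or unknown keys."""


@dataclass
class BeamConfig:
    energy: float = 13.0  # MeV
    mode: str = "incident_mean"  # or "surface_ep0"
    ep0_offset: float = 0.0  # display-only Ep0 - E0bar offset, MeV


@dataclass
class GeometryConfig:
    window_to_primary: float = 5.0  # cm
    primary_to_secondary: float = 12.0  # cm
    secondary_to_iso: float = 88.0  # cm
    sad: float = 100.0  # cm
    calc_depth: float = 2.0  # cm past isocenter


@dataclass
class WindowConfig:
    material: str = "nickel"
    thickness_cm: float = 0.0125


@dataclass
class PrimaryFoilConfig:
    material: str = "tantalum"
    thickness_cm: float = 0.008


@dataclass
class SecondaryFoilConfig:
    mode: str = "gaussian"  # gaussian | file | none
    material: str = "aluminum"
    t0_cm: float = 0.6
    sigma_cm: float = 1.44
    n_segments: int = 16
    file: str = ""


@dataclass
class CalculationConfig:
    half_range_cm: float = 30.0
    n_rho: int = 100
    n_theta: int = 100
    n_profile: int = 60
    foil_r_max_cm: float = 3.65
    kernel: str = "conditional"  # or "uncorrelated"
    secondary_mean_thickness: str = "fluence_weighted"  # or "cax"
    substep: bool = True


@dataclass
class XrayConfig:
    include: bool = True
    a: float = -0.035  # % per MeV
    b: float = 15.77  # %
    c: float = 0.016  # per MeV


@dataclass
class FlatnessConfig:
    range_cm: float = 14.6
    criterion_pct: float = 3.0


@dataclass
class SimulationConfig:
    beam: BeamConfig = field(default_factory=BeamConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    primary_foil: PrimaryFoilConfig = field(default_factory=PrimaryFoilConfig)
    secondary_foil: SecondaryFoilConfig = field(default_factory=SecondaryFoilConfig)
    calculation: CalculationConfig = field(default_factory=CalculationConfig)
    xray: XrayConfig = field(default_factory=XrayConfig)
    flatness: FlatnessConfig = field(default_factory=FlatnessConfig)

    def validate(self) -> None:
        problems = []
        if self.beam.energy <= 0:
            problems.append("beam.energy must be > 0")
        if self.beam.mode not in ("incident_mean", "surface_ep0"):
            problems.append("beam.mode must be incident_mean or surface_ep0")
        for key in ("window_to_primary", "primary_to_secondary", "secondary_to_iso", "sad"):
            if getattr(self.geometry, key) <= 0:
                problems.append(f"geometry.{key} must be > 0")
        if self.geometry.calc_depth < 0:
            problems.append("geometry.calc_depth must be >= 0")
        if self.window.thickness_cm < 0:
            problems.append("window.thickness_cm must be >= 0")
        if self.primary_foil.thickness_cm <= 0:
            problems.append("primary_foil.thickness_cm must be > 0")
        sf = self.secondary_foil
        if sf.mode not in ("gaussian", "file", "none"):
            problems.append("secondary_foil.mode must be gaussian, file or none")
        if sf.mode == "gaussian":
            if sf.t0_cm <= 0:
                problems.append("secondary_foil.t0_cm must be > 0")
            if sf.sigma_cm <= 0:
                problems.append("secondary_foil.sigma_cm must be > 0")
            if sf.n_segments < 1:
                problems.append("secondary_foil.n_segments must be >= 1")
        if sf.mode == "file" and not sf.file:
            problems.append("secondary_foil.file required in file mode")
        calc = self.calculation
        for key in ("n_rho", "n_theta", "n_profile"):
            if getattr(calc, key) < 2:
                problems.append(f"calculation.{key} must be >= 2")
        if calc.half_range_cm <= 0:
            problems.append("calculation.half_range_cm must be > 0")
        if calc.foil_r_max_cm <= 0:
            problems.append("calculation.foil_r_max_cm must be > 0")
        if calc.kernel not in ("conditional", "uncorrelated"):
            problems.append("calculation.kernel must be conditional or uncorrelated")
        if calc.secondary_mean_thickness not in ("fluence_weighted", "cax"):
            problems.append(
                "calculation.secondary_mean_thickness must be fluence_weighted or cax"
            )
        if self.flatness.range_cm <= 0:
            problems.append("flatness.range_cm must be > 0")
        if self.flatness.criterion_pct <= 0:
            problems.append("flatness.criterion_pct must be > 0")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))


_SECTIONS = {
    "beam": BeamConfig,
    "geometry": GeometryConfig,
    "window": WindowConfig,
    "primary_foil": PrimaryFoilConfig,
    "secondary_foil": SecondaryFoilConfig,
    "calculation": CalculationConfig,
    "xray": XrayConfig,
    "flatness": FlatnessConfig,
}


def _parse_value(text: str, typ):
    if typ is bool:
        low = text.strip().lower()
        if low in ("true", "yes", "on", "1"):
            return True
        if low in ("false", "no", "off", "0"):
            return False
        raise ValueError(f"not a boolean: {text!r}")
    return typ(text)


def load_config(path) -> SimulationConfig:
    """Read a configuration file, filling unspecified keys with defaults."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise ConfigError(f"cannot read configuration file {path}")
    cfg = SimulationConfig()
    problems = []
    for section in parser.sections():
        if section not in _SECTIONS:
            problems.append(f"unknown section [{section}]")
            continue
        target = getattr(cfg, section)
        known = {f.name: f.type for f in fields(target)}
        types = {f.name: type(getattr(target, f.name)) for f in fields(target)}
        for key, raw in parser.items(section):
            if key not in known:
                problems.append(f"unknown key {section}.{key}")
                continue
            try:
                setattr(target, key, _parse_value(raw, types[key]))
            except ValueError:
                problems.append(f"bad value for {section}.{key}: {raw!r}")
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))
    cfg.validate()
    return cfg


def save_config(cfg: SimulationConfig, path) -> None:
    """Write a configuration file (round-trips losslessly)."""
    parser = configparser.ConfigParser()
    for section, _cls in _SECTIONS.items():
        target = getattr(cfg, section)
        parser[section] = {
            f.name: repr(getattr(target, f.name))
            if isinstance(getattr(target, f.name), float)
            else str(getattr(target, f.name))
            for f in fields(target)
        }
    with open(path, "w") as fh:
        parser.write(fh)


def config_as_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
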