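"""Material definitions and the built-in material registry.

A material is characterised by an (effective) atomic number Z, atomic
mass A, mass density and mean excitation energy I.  Compounds are
represented by a single effective element, exactly as a physicist would
enter them into the simulator, but a material may additionally carry an
atomic-oscillator table (sub-shell occupancies and binding energies)
used by the exact Sternheimer density-effect evaluation; without one, a
single-oscillator model is used.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence


@dataclass(frozen=True)
class Oscillator:
    """One Sternheimer oscillator: `n` electrons bound at `energy_ev`.

    ``energy_ev == 0`` marks conduction electrons of a metal.
    """

    n: float
    energy_ev: float


@dataclass(frozen=True)
class Material:
    """Single (effective) element with the properties the transport needs.

    Parameters
    ----------
    name:
        Registry key, lower case.
    Z:
        Atomic number; an effective (non-integer) value is allowed for
        compounds such as water or air.
    A:
        Atomic mass in g/mol (effective for compounds).
    density:
        Mass density in g/cm^3.
    I:
        Mean excitation energy in eV.
    oscillators:
        Optional Sternheimer sub-shell table (per Z electrons) used for
        the exact density-effect evaluation.
    """

    name: str
    Z: float
    A: float
    density: float
    I: float
    oscillators: tuple[Oscillator, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        for attr in ("Z", "A", "density", "I"):
            if getattr(self, attr) <= 0.0:
                raise ValueError(f"Material {self.name!r}: {attr} must be > 0")

    @property
    def Z_over_A(self) -> float:
        return self.Z / self.A

    @property
    def electron_density(self) -> float:
        """Electrons per cm^3 times 1/N_A, i.e. mol of electrons per cm^3."""
        return self.density * self.Z / self.A


# Sub-shell occupancies and nominal binding energies (eV).  The
# Sternheimer adjustment rescales all bound energies to reproduce the
# mean excitation energy I, so only the ratios matter; nominal atomic
# values are sufficient.  Metals carry conduction electrons (energy 0).
_OSC = {
    "water": (  # per H2O molecule, Z = 10
        Oscillator(2, 13.6),    # H 1s
        Oscillator(2, 538.0),   # O 1s
        Oscillator(2, 28.5),    # O 2s
        Oscillator(4, 13.6),    # O 2p
    ),
    "air": (  # effective molecule scaled to Z = 7.36 (N/O weighted)
        Oscillator(1.47, 425.0),   # K shell
        Oscillator(1.47, 23.0),    # L1
        Oscillator(4.42, 14.0),    # L2,3
    ),
    "aluminum": (
        Oscillator(2, 1559.6),
        Oscillator(2, 117.8),
        Oscillator(6, 72.95),
        Oscillator(3, 0.0),     # conduction band
    ),
    "nickel": (
        Oscillator(2, 8333.0),
        Oscillator(2, 1008.6),
        Oscillator(6, 858.0),
        Oscillator(2, 110.8),
        Oscillator(6, 68.0),
        Oscillator(8, 10.0),    # 3d
        Oscillator(2, 0.0),     # 4s conduction
    ),
    "tantalum": (
        Oscillator(2, 67416.0),
        Oscillator(2, 11682.0),
        Oscillator(6, 10300.0),
        Oscillator(2, 2708.0),
        Oscillator(6, 2285.0),
        Oscillator(10, 1760.0),
        Oscillator(2, 563.4),
        Oscillator(6, 422.0),
        Oscillator(10, 230.0),
        Oscillator(14, 22.3),   # 4f
        Oscillator(2, 69.7),
        Oscillator(6, 36.0),
        Oscillator(3, 5.7),     # 5d
        Oscillator(2, 0.0),     # 6s conduction
    ),
}


def _builtin_registry() -> dict[str, Material]:
    registry: dict[str, Material] = {}
    with resources.files("foilsim.data").joinpath("materials.csv").open() as fh:
        for row in csv.DictReader(_strip_comments(fh)):
            name = row["name"].strip().lower()
            registry[name] = Material(
                name=name,
                Z=float(row["Z"]),
                A=float(row["A_g_mol"]),
                density=float(row["density_g_cm3"]),
                I=float(row["I_eV"]),
                oscillators=_OSC.get(name, ()),
            )
    return registry


def _strip_comments(lines):
    for line in lines:
        if not line.lstrip().startswith("#"):
            yield line


_REGISTRY: dict[str, Material] | None = None

_ALIASES = {"ta": "tantalum", "al": "aluminum", "ni": "nickel", "h2o": "water"}


def registry() -> dict[str, Material]:
    """Built-in material registry (nickel, tantalum, aluminum, air, water)."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _builtin_registry()
    return _REGISTRY


def get_material(name: str) -> Material:
    """Look a material up by name (case-insensitive, common symbols allowed)."""
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    reg = registry()
    if key not in reg:
        raise KeyError(
            f"unknown material {name!r}; registry contains: {', '.join(sorted(reg))}"
        )
    return reg[key]


def load_materials_file(path) -> dict[str, Material]:
    """Read a user materials file (CSV: name,Z,A_g_mol,density_g_cm3,I_eV)."""
    out: dict[str, Material] = {}
    with open(path) as fh:
        for row in csv.DictReader(_strip_comments(fh)):
            name = row["name"].strip().lower()
            out[name] = Material(
                name=name,
                Z=float(row["Z"]),
                A=float(row["A_g_mol"]),
                density=float(row["density_g_cm3"]),
                I=float(row["I_eV"]),
            )
    return out
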