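"""Bremsstrahlung contamination dose model.

The X-ray fluence produced by the scattering elements is modelled in
the Schiff small-angle style: each element i (exit window, primary
foil, secondary foil) radiates an energy dE_rad_i and the photons
inherit the multiple-scattering angular spread of the electrons inside
it, giving an off-axis dose shape built from differences of the
exponential integral E1 evaluated at (r/z)^2 scaled by the entrance
zeroth moment A0_i and by A0_i + T_i t_i.

The absolute central-axis level is tied to Monte Carlo calibration via
the statistic

    X(E) = [sum_i dE_rad_i/(T_i t_i) ln(1 + T_i t_i / A0_i)]
           / [(SAD + Rp + 2)^2  phi_e(0, 0, E)]

and the fitted curve  %D_cax = a X + b (1 - exp(-c X))  with the
calibration constants a = -0.035 %/MeV, b = 15.77 %, c = 0.016 /MeV.
The incident-beam moment A0_0 is the empirical 0.05 E^-1.6.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import exp1

from .beamline import BeamlineGeometry
from .profiles import Profile

log = logging.getLogger("foilsim")


def exp_integral_E1(x):
    """Exponential integral E1(x) for x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("E1 requires x > 0")
    out = exp1(x)
    return out if out.ndim else float(out)


def a00_empirical(E: float) -> float:
    """Empirical zeroth scattering moment of the incident beam: 0.05 E^-1.6."""
    if E <= 0.0:
        raise ValueError("energy must be > 0")
    return 0.05 * E ** (-1.6)


@dataclass(frozen=True)
class XrayElement:
    """Per-element radiative budget entry."""

    name: str
    dE_rad: float  # MeV radiated per incident electron
    T: float  # rad^2/cm at the element's entrance energy
    t: float  # mean thickness, cm
    A0_entry: float  # entrance zeroth moment, rad^2

    def __post_init__(self) -> None:
        for attr in ("dE_rad", "T", "t", "A0_entry"):
            if getattr(self, attr) < 0.0:
                raise ValueError(f"{attr} must be >= 0")


@dataclass(frozen=True)
class XrayBudget:
    """Radiative budget of the beamline: elements in beam order plus A0,0."""

    elements: tuple[XrayElement, ...]
    A00: float

    def __post_init__(self) -> None:
        A0 = self.A00
        for el in self.elements:
            if abs(el.A0_entry - A0) > 1e-9 * max(A0, 1e-30):
                raise ValueError(
                    f"A0 chain broken at {el.name!r}: entry {el.A0_entry:g} != {A0:g}"
                )
            A0 = A0 + el.T * el.t


@dataclass(frozen=True)
class XrayCalibration:
    """Fit constants of the central-axis percent-dose calibration curve."""

    a: float = -0.035  # % per MeV
    b: float = 15.77  # %
    c: float = 0.016  # per MeV


def build_xray_budget(
    entries: Sequence[tuple[str, float, float, float]], E_incident: float
) -> XrayBudget:
    """Assemble the budget from (name, dE_rad, T, mean thickness) entries.

    Entries must be in beam order; the entrance moment of each element
    is chained from the empirical incident moment via A0_{i+1} = A0_i +
    T_i t_i.  Zero-thickness entries are kept (they contribute nothing).
    """
    A0 = a00_empirical(E_incident)
    elements = []
    for name, dE, T, t in entries:
        elements.append(XrayElement(name=name, dE_rad=dE, T=T, t=t, A0_entry=A0))
        A0 = A0 + T * t
    return XrayBudget(elements=tuple(elements), A00=a00_empirical(E_incident))


def _bracket_sum(budget: XrayBudget, x: np.ndarray) -> np.ndarray:
    """sum_i dE_i/(T_i t_i) [E1(x/(A0_i + T_i t_i)) - E1(x/A0_i)] for x=(r/z)^2.

    At x = 0 each bracket has the logarithmic limit ln(1 + T_i t_i/A0_i).
    """
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    for el in budget.elements:
        tt = el.T * el.t
        if tt <= 0.0 or el.dE_rad <= 0.0:
            continue
        zero = x <= 0.0
        xs = np.where(zero, 1.0, x)
        bracket = exp1(xs / (el.A0_entry + tt)) - exp1(xs / el.A0_entry)
        bracket = np.where(zero, math.log1p(tt / el.A0_entry), bracket)
        total += el.dE_rad / tt * bracket
    return total


def offaxis_xray_relative(budget: XrayBudget, z: float, r):
    """Off-axis X-ray relative dose D(z,r)/D(z,0); 1 at r = 0, non-increasing."""
    if z <= 0.0:
        raise ValueError("z must be > 0")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0.0):
        raise ValueError("r must be >= 0")
    denom = float(_bracket_sum(budget, np.array(0.0)))
    if denom <= 0.0:
        raise ValueError("X-ray budget radiates nothing (all dE_rad or T*t zero)")
    out = _bracket_sum(budget, (r / z) ** 2) / denom
    return out if out.ndim else float(out)


def practical_range(Ep0: float) -> float:
    """Practical range in water, Rp = Ep0 / 2 cm (2 MeV/cm falloff)."""
    if Ep0 <= 0.0:
        raise ValueError("Ep0 must be > 0")
    return Ep0 / 2.0


def x_statistic(
    budget: XrayBudget, cax_fluence_per_electron: float, Rp: float, SAD: float = 100.0
) -> float:
    """Calibration statistic X(E) in MeV (see module docstring)."""
    if cax_fluence_per_electron <= 0.0:
        raise ValueError("central-axis fluence must be > 0")
    bracket = float(_bracket_sum(budget, np.array(0.0)))
    return bracket / ((SAD + Rp + 2.0) ** 2 * cax_fluence_per_electron)


def cax_xray_percent(X: float, cal: XrayCalibration = XrayCalibration()) -> float:
    """Central-axis X-ray percent dose at depth Rp+2: a X + b (1 - e^(-c X)).

    The fit passes through the origin; a negative extrapolation at very
    large X is clamped to zero with a warning.
    """
    if X < 0.0:
        raise ValueError("X must be >= 0")
    pct = cal.a * X + cal.b * (1.0 - math.exp(-cal.c * X))
    if pct < 0.0:
        log.warning(
            "central-axis X-ray fit extrapolated negative (X = %.4g MeV); clamping to 0",
            X,
        )
        return 0.0
    return pct


def cax_xray_percent_at_depth(
    pct_at_Rp2: float, Rp: float, d: float, SAD: float = 100.0
) -> float:
    """Inverse-square rescaling of the Rp+2 percent dose to depth d.

    Photon attenuation between the two depths is deliberately ignored
    (it is absorbed into the calibration).
    """
    if d < 0.0:
        raise ValueError("d must be >= 0")
    return pct_at_Rp2 * ((SAD + Rp + 2.0) / (SAD + d)) ** 2


def offaxis_xray_percent_profile(
    budget: XrayBudget,
    cal: XrayCalibration,
    geometry: BeamlineGeometry,
    Ep0: float,
    cax_fluence_per_electron: float,
    r_grid: np.ndarray,
) -> tuple[Profile, float, float]:
    """Off-axis X-ray percent dose profile at the calculation depth.

    Returns ``(profile, pct_cax_at_d, X)`` where the profile values are
    percent of the central-axis dose maximum.
    """
    Rp = practical_range(Ep0)
    X = x_statistic(budget, cax_fluence_per_electron, Rp, geometry.SAD)
    pct_rp2 = cax_xray_percent(X, cal)
    pct_d = cax_xray_percent_at_depth(pct_rp2, Rp, geometry.calc_depth, geometry.SAD)
    rel = offaxis_xray_relative(budget, geometry.SAD + geometry.calc_depth, r_grid)
    return Profile(r_grid, rel * pct_d, "percent_of_dmax"), pct_d, X
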