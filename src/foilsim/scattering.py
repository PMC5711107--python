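"""Multiple Coulomb scattering powers (Moliere, reduced-Gaussian).

The Gaussian core of the Moliere angular distribution after a slab of
thickness t has full-plane mean-square angle ``chi_c^2 * B``, where the
characteristic angle chi_c and the logarithmic parameter B follow the
ICRU-35/Bethe presentation of Moliere theory:

    chi_c^2 = 0.1569 MeV^2 * Z(Z+1)/A * rho t / (p beta)^2
    chi_a^2 = chi_0^2 (1.13 + 3.76 (alpha Z / beta)^2)
    Omega_0 = chi_c^2 / (1.167 chi_a^2)           (effective collision count)
    B - ln B = ln Omega_0                          (B > 1 branch)

The "reduced Gaussian" scattering power applies the core-width
correction factor (1 - 1.330/B) to the Moliere-Gaussian value, which
narrows the Gaussian to better match the core of the full Moliere
distribution.  Scattering power T is defined throughout as the growth
rate of the *full-plane* mean-square angle per unit length (rad^2/cm);
the per-axis variance rate is T/2.

Conventions for the constant relating Omega_0 to chi_c^2/chi_a^2 differ
in the literature (the 1.167 = exp(2 gamma_E - 1) factor); this module
uses the Bethe value consistently, and every consumer goes through this
single implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .materials import Material
from .stopping import ALPHA, MC2, beta2_of, pbeta_of

CHI_C2_COEFF = 0.1569  # 4 pi N_A r_e^2 (mc^2)^2, MeV^2 cm^2/mol
A0_BOHR = 0.529177e-8  # cm
HBARC = 197.3269804e-13  # MeV cm
OMEGA0_CONST = 1.167  # exp(2*gamma_Euler - 1)
REDUCED_GAUSSIAN_COEFF = 1.330


@dataclass(frozen=True)
class ScatterPowerResult:
    """Scattering power T (rad^2/cm, full-plane) and the Moliere B used."""

    T: float
    B: float


def chi_c2(material: Material, thickness: float, E: float) -> float:
    """Moliere characteristic angle squared (rad^2) for the whole slab."""
    pb = pbeta_of(E)
    return (
        CHI_C2_COEFF
        * material.Z
        * (material.Z + 1.0)
        / material.A
        * material.density
        * thickness
        / (pb * pb)
    )


def chi_a2(material: Material, E: float) -> float:
    """Screening angle squared (rad^2)."""
    beta2 = beta2_of(E)
    gamma = 1.0 + E / MC2
    p = math.sqrt(gamma * gamma - 1.0) * MC2  # momentum * c in MeV
    chi0 = HBARC * material.Z ** (1.0 / 3.0) / (0.885 * A0_BOHR * p)
    return chi0 * chi0 * (1.13 + 3.76 * (ALPHA * material.Z) ** 2 / beta2)


def omega0(material: Material, thickness: float, E: float) -> float:
    """Effective number of scattering collisions in the slab."""
    return chi_c2(material, thickness, E) / (OMEGA0_CONST * chi_a2(material, E))


def moliere_B(material: Material, thickness: float, E: float) -> float:
    """Solve B - ln B = ln Omega_0 on the B > 1 branch (residual < 1e-10)."""
    if thickness <= 0.0:
        raise ValueError("thickness must be > 0")
    if E <= 0.0:
        raise ValueError("energy must be > 0")
    om = omega0(material, thickness, E)
    ln_om = math.log(om) if om > 0 else -math.inf
    if ln_om < 1.0:
        raise ValueError(
            f"Moliere regime violated: Omega_0 = {om:.3g} < e for "
            f"{material.name} thickness {thickness:g} cm at {E:g} MeV"
        )
    f = lambda B: B - math.log(B) - ln_om
    B = brentq(f, 1.0 + 1e-12, max(10.0 * ln_om, 10.0), xtol=1e-13, rtol=8.9e-16)
    assert abs(f(B)) < 1e-10
    return B


def moliere_gaussian_scattering_power(
    material: Material, thickness: float, E: float
) -> ScatterPowerResult:
    """Moliere-Gaussian T = chi_c^2 B / t (rad^2/cm, full-plane)."""
    B = moliere_B(material, thickness, E)
    T = chi_c2(material, thickness, E) * B / thickness
    return ScatterPowerResult(T=T, B=B)


def reduced_gaussian_scattering_power(
    material: Material, thickness: float, E: float
) -> ScatterPowerResult:
    """Reduced-Gaussian T = T_MoliereGaussian * (1 - 1.330/B).

    Raises if B <= 1.330, where the correction factor is non-positive.
    """
    mg = moliere_gaussian_scattering_power(material, thickness, E)
    if mg.B <= REDUCED_GAUSSIAN_COEFF:
        raise ValueError(
            f"reduced-Gaussian correction undefined: B = {mg.B:.4g} <= "
            f"{REDUCED_GAUSSIAN_COEFF} for {material.name} "
            f"thickness {thickness:g} cm at {E:g} MeV"
        )
    return ScatterPowerResult(T=mg.T * (1.0 - REDUCED_GAUSSIAN_COEFF / mg.B), B=mg.B)
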