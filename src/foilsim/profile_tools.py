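"""Total-dose synthesis, flatness evaluation and objective refinement.

The total relative dose profile combines the electron and X-ray
components, normalized to 100% on the central axis:

    D_T(r) = %Dgamma(r) + (100% - %Dgamma_cax) * De(r)/De(0)

Flatness is judged against an objective (or comparison) profile as the
maximum deviation above and below it inside a stated off-axis range,
by default +-14.6 cm (2 cm inside the diagonal edge of a 25x25 cm^2
applicator) with a 3% criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import Profile


@dataclass(frozen=True)
class FlatnessReport:
    """Extremes of the deviation from the objective, in percent of CAX."""

    max_over: float
    max_under: float
    eval_range: float = 14.6
    criterion: float = 3.0

    def __post_init__(self) -> None:
        if self.max_over < 0.0 or self.max_under < 0.0:
            raise ValueError("deviation extremes must be >= 0")

    @property
    def passed_over(self) -> bool:
        return self.max_over <= self.criterion

    @property
    def passed_under(self) -> bool:
        return self.max_under <= self.criterion

    @property
    def passed(self) -> bool:
        return self.passed_over and self.passed_under


def _as_relative(p: Profile) -> Profile:
    """Express a CAX-normalized profile on the CAX=1 scale."""
    if p.normalization == "cax_100":
        return p.rescaled("cax_1")
    return p


def total_dose_profile(
    electron: Profile, xray_pct: Profile, cax_xray_pct_at_d: float
) -> Profile:
    """Combine electron and X-ray components into the total dose profile.

    ``electron`` must be CAX-normalized; ``xray_pct`` carries percent of
    dose maximum on the same radial grid.  The result is normalized to
    exactly 100 at r = 0.
    """
    if electron.r.shape != xray_pct.r.shape or not np.allclose(
        electron.r, xray_pct.r, rtol=0.0, atol=1e-12
    ):
        raise ValueError("electron and X-ray profiles must share one radial grid")
    e = _as_relative(electron)
    v = xray_pct.v + (100.0 - cax_xray_pct_at_d) * e.v / e.at(0.0)
    return Profile(electron.r, v, "cax_100")


def flatness_report(
    profile: Profile,
    objective: Profile,
    eval_range: float = 14.6,
    criterion: float = 3.0,
) -> FlatnessReport:
    """Maximum deviations of ``profile`` above/below ``objective``.

    Both profiles are compared on the CAX=1 relative scale and the
    extremes are reported in percent.  Evaluation points are the
    profile's own grid points inside ``|r| <= eval_range`` (the
    objective is linearly interpolated onto them; the objective must
    cover the range).
    """
    if eval_range <= 0.0:
        raise ValueError("eval_range must be > 0")
    p = _as_relative(profile).mirrored()
    o = _as_relative(objective)
    if eval_range > p.r[-1] + 1e-12:
        raise ValueError(
            f"eval_range {eval_range:g} cm beyond profile support {p.r[-1]:g} cm"
        )
    mask = np.abs(p.r) <= eval_range + 1e-12
    r_eval = p.r[mask]
    dev = p.v[mask] - o.at(r_eval)  # raises if objective does not cover the range
    return FlatnessReport(
        max_over=100.0 * max(float(dev.max()), 0.0),
        max_under=100.0 * max(float(-dev.min()), 0.0),
        eval_range=eval_range,
        criterion=criterion,
    )


def refine_objective(
    objective: Profile, simulated: Profile, reference: Profile
) -> Profile:
    """Shift the objective by the simulator-vs-reference discrepancy.

    Pointwise ``objective - (reference - simulated)`` on a common grid:
    designing to the refined objective compensates for the physics the
    analytic model does not capture (large-angle and collimator
    scatter seen by the reference calculation or measurement).
    """
    for other in (simulated, reference):
        if objective.r.shape != other.r.shape or not np.allclose(
            objective.r, other.r, rtol=0.0, atol=1e-12
        ):
            raise ValueError("objective, simulated and reference must share one grid")
    o = _as_relative(objective)
    s = _as_relative(simulated)
    ref = _as_relative(reference)
    return Profile(objective.r, o.v - (ref.v - s.v), o.normalization)
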