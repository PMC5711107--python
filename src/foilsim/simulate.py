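"""End-to-end dual-foil simulation: the glue over the physics modules.

``run_simulation`` takes a :class:`~foilsim.config.SimulationConfig` and
produces the off-axis electron, X-ray and total relative dose profiles
together with the energy schedule, Fermi-Eyges moments and X-ray
budget — everything the command-line tools report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .beamline import (
    BeamlineGeometry,
    GaussianFoilSpec,
    SegmentedFoil,
    load_secondary_foil_file,
    segment_gaussian_foil,
)
from .config import SimulationConfig
from .materials import Material, get_material
from .profiles import Profile
from .profile_tools import total_dose_profile
from .scattering import reduced_gaussian_scattering_power
from .stopping import (
    mean_energy_after,
    radiative_mass_stopping_power,
    secondary_exit_mean_energy,
)
from .transport import (
    ScatteringMoments,
    TransportElement,
    accumulate_moments,
    analytic_gaussian_profile,
    electron_dose_profile,
    electron_fluence_profile,
    fluence_to_dose_constant,
    incident_fluence_z1,
)
from .xray import (
    XrayBudget,
    XrayCalibration,
    cax_xray_percent,
    offaxis_xray_percent_profile,
    practical_range,
    build_xray_budget,
)

log = logging.getLogger("foilsim")

MAX_RECOMMENDED_DEPTH = 2.0  # cm; beyond this the in-air == in-water assumption degrades


@dataclass
class EnergySchedule:
    """Mean kinetic energies along the beamline (MeV)."""

    E_incident: float  # entering the vacuum exit window (== Ep incident)
    E_primary: float  # entering the primary foil
    E_secondary_in: float  # entering the secondary foil
    E_secondary_out: float  # fluence-weighted mean exiting the secondary foil
    E_secondary_scatter: float  # energy used for the secondary scattering power
    E_iso: float  # mean energy at isocenter (E0bar)
    Ep0: float  # most probable energy at the surface (display)


@dataclass
class SimulationResult:
    config: SimulationConfig
    geometry: BeamlineGeometry
    schedule: EnergySchedule
    moments_z1: ScatteringMoments
    foil: SegmentedFoil | None
    electron_profile: Profile  # cax_1, half-grid
    cax_fluence_per_electron: float  # 1/cm^2 at z2
    Ke: float  # MeV cm^2/g
    Rp: float  # cm
    xray_profile: Profile | None  # percent_of_dmax
    pct_xray_cax_rp2: float | None  # %D_cax at depth Rp+2
    pct_xray_cax_d: float | None  # %D_cax at the calculation depth
    x_stat: float | None  # MeV
    budget: XrayBudget | None
    total_profile: Profile  # cax_100


def geometry_from_config(cfg: SimulationConfig) -> BeamlineGeometry:
    g = cfg.geometry
    return BeamlineGeometry(
        d_window_primary=g.window_to_primary,
        d_primary_secondary=g.primary_to_secondary,
        d_secondary_iso=g.secondary_to_iso,
        SAD=g.sad,
        calc_depth=g.calc_depth,
    )


def secondary_foil_from_config(cfg: SimulationConfig) -> SegmentedFoil | None:
    sf = cfg.secondary_foil
    if sf.mode == "none":
        return None
    if sf.mode == "file":
        return load_secondary_foil_file(sf.file)
    spec = GaussianFoilSpec(
        material=get_material(sf.material),
        t0=sf.t0_cm,
        sigma=sf.sigma_cm,
        n_segments=sf.n_segments,
        r_max=cfg.calculation.foil_r_max_cm,
    )
    return segment_gaussian_foil(spec)


def _air() -> Material:
    return get_material("air")


def _chain_energies(
    cfg: SimulationConfig, geometry: BeamlineGeometry, E_incident: float
) -> tuple[float, float, float]:
    """Energies entering the window->air->primary->air chain up to z1."""
    substep = cfg.calculation.substep
    window = get_material(cfg.window.material)
    primary = get_material(cfg.primary_foil.material)
    E_after_window = mean_energy_after(
        window, cfg.window.thickness_cm, E_incident, substep
    )
    E_primary = mean_energy_after(
        _air(), geometry.d_window_primary, E_after_window, substep
    )
    E_after_primary = mean_energy_after(
        primary, cfg.primary_foil.thickness_cm, E_primary, substep
    )
    gap2 = geometry.z1 - cfg.primary_foil.thickness_cm
    E_secondary_in = mean_energy_after(_air(), gap2, E_after_primary, substep)
    return E_primary, E_after_primary, E_secondary_in


def _upstream_elements(
    cfg: SimulationConfig,
    geometry: BeamlineGeometry,
    E_incident: float,
    E_primary: float,
    E_after_window: float | None = None,
    E_after_primary: float | None = None,
) -> list[TransportElement]:
    """Window, both air gaps and the primary foil, with T at entrance energies."""
    window = get_material(cfg.window.material)
    primary = get_material(cfg.primary_foil.material)
    t_w = cfg.window.thickness_cm
    t_p = cfg.primary_foil.thickness_cm
    substep = cfg.calculation.substep
    if E_after_window is None:
        E_after_window = mean_energy_after(window, t_w, E_incident, substep)
    if E_after_primary is None:
        E_after_primary = mean_energy_after(primary, t_p, E_primary, substep)
    gap2 = geometry.z1 - t_p
    els = []
    if t_w > 0.0:
        T_w = reduced_gaussian_scattering_power(window, t_w, E_incident).T
        els.append(TransportElement("window", T_w, t_w, geometry.z_window - t_w))
    T_a1 = reduced_gaussian_scattering_power(
        _air(), geometry.d_window_primary, E_after_window
    ).T
    els.append(
        TransportElement(
            "air_window_primary", T_a1, geometry.d_window_primary,
            geometry.z_window, extended=True,
        )
    )
    T_p = reduced_gaussian_scattering_power(primary, t_p, E_primary).T
    els.append(TransportElement("primary", T_p, t_p, 0.0))
    T_a2 = reduced_gaussian_scattering_power(_air(), gap2, E_after_primary).T
    els.append(
        TransportElement("air_primary_secondary", T_a2, gap2, t_p, extended=True)
    )
    return els


def surface_mean_energy(cfg: SimulationConfig, E_incident: float) -> float:
    """Forward transport of the mean energy to the isocenter surface (E0bar)."""
    geometry = geometry_from_config(cfg)
    E_primary, _, E_sec_in = _chain_energies(cfg, geometry, E_incident)
    foil = secondary_foil_from_config(cfg)
    substep = cfg.calculation.substep
    if foil is None:
        E_out = E_sec_in
    else:
        els = _upstream_elements(cfg, geometry, E_incident, E_primary)
        moments_z1 = accumulate_moments(els, geometry.z1)
        grid = np.linspace(0.0, foil.r_max, 257)
        fluence = incident_fluence_z1(moments_z1, grid)
        E_out = secondary_exit_mean_energy(foil, fluence, E_sec_in)
    return mean_energy_after(_air(), geometry.d_secondary_iso, E_out, substep)


def resolve_incident_energy(cfg: SimulationConfig) -> float:
    """Incident mean energy for either beam-energy input mode.

    ``incident_mean`` takes the configured value directly.  In
    ``surface_ep0`` mode the configured value is the most probable
    surface energy; the incident energy is found by root-finding the
    forward transport so that E0bar + ep0_offset matches it.
    """
    if cfg.beam.mode == "incident_mean":
        return cfg.beam.energy
    target = cfg.beam.energy - cfg.beam.ep0_offset  # required E0bar
    f = lambda Ei: surface_mean_energy(cfg, Ei) - target
    lo, hi = target, target + 1.0
    while f(hi) < 0.0:
        hi += 1.0
        if hi > target + 30.0:
            raise ValueError("cannot bracket incident energy for surface_ep0 mode")
    return brentq(f, lo, hi, xtol=1e-6)


def mean_secondary_thickness(
    foil: SegmentedFoil, fluence: Profile, mode: str = "fluence_weighted"
) -> float:
    """Mean thickness of the secondary foil for the X-ray budget."""
    if mode == "cax":
        return float(foil.local_thickness(0.0))
    r = fluence.r
    w = fluence.v * 2.0 * math.pi * r
    t = np.asarray(foil.local_thickness(r))
    total = float(np.trapezoid(w, r))
    if total <= 0.0:
        raise ValueError("incident fluence is identically zero on the foil support")
    return float(np.trapezoid(w * t, r)) / total


def run_simulation(cfg: SimulationConfig) -> SimulationResult:
    """Run the full analytic dual-foil simulation for one configuration."""
    cfg.validate()
    geometry = geometry_from_config(cfg)
    if geometry.calc_depth > MAX_RECOMMENDED_DEPTH:
        log.warning(
            "calculation depth %.2f cm exceeds the recommended %.0f cm; the "
            "in-air fluence == in-water dose equivalence degrades with depth",
            geometry.calc_depth, MAX_RECOMMENDED_DEPTH,
        )
    calc = cfg.calculation
    substep = calc.substep
    foil = secondary_foil_from_config(cfg)

    E_incident = resolve_incident_energy(cfg)
    E_primary, E_after_primary, E_sec_in = _chain_energies(cfg, geometry, E_incident)
    els = _upstream_elements(cfg, geometry, E_incident, E_primary)
    moments_z1 = accumulate_moments(els, geometry.z1)

    if foil is not None:
        grid = np.linspace(0.0, foil.r_max, 257)
        fluence_z1 = incident_fluence_z1(moments_z1, grid)
        E_sec_out = secondary_exit_mean_energy(foil, fluence_z1, E_sec_in)
        E_sec_scatter = 0.5 * (E_sec_in + E_sec_out)
    else:
        fluence_z1 = None
        E_sec_out = E_sec_in
        E_sec_scatter = E_sec_in
    E_iso = mean_energy_after(_air(), geometry.d_secondary_iso, E_sec_out, substep)
    Ep0 = E_iso + cfg.beam.ep0_offset
    schedule = EnergySchedule(
        E_incident=E_incident,
        E_primary=E_primary,
        E_secondary_in=E_sec_in,
        E_secondary_out=E_sec_out,
        E_secondary_scatter=E_sec_scatter,
        E_iso=E_iso,
        Ep0=Ep0,
    )
    log.info(
        "energy schedule (MeV): incident %.3f -> primary %.3f -> secondary "
        "%.3f/%.3f -> isocenter %.3f (Ep0 %.3f)",
        E_incident, E_primary, E_sec_in, E_sec_out, E_iso, Ep0,
    )

    # electron fluence at the calculation plane
    L_air3 = geometry.z2 - geometry.z1
    T_air3 = reduced_gaussian_scattering_power(_air(), L_air3, E_sec_out).T
    if foil is None:
        els_z2 = _upstream_elements(cfg, geometry, E_incident, E_primary)
        # air continues uninterrupted from the primary foil to the plane
        els_z2[-1] = TransportElement(
            "air_primary_plane",
            els_z2[-1].T,
            geometry.z2 - cfg.primary_foil.thickness_cm,
            cfg.primary_foil.thickness_cm,
            extended=True,
        )
        moments_z2 = accumulate_moments(els_z2, geometry.z2)
        electron, cax_fluence = analytic_gaussian_profile(
            moments_z2, calc.n_profile, calc.half_range_cm
        )
    else:
        electron, cax_fluence = electron_fluence_profile(
            moments_z1, foil, geometry, E_sec_scatter, T_air3,
            n_rho=calc.n_rho, n_theta=calc.n_theta,
            n_profile=calc.n_profile, half_range=calc.half_range_cm,
            rho_max=foil.r_max, kernel=calc.kernel,
        )
    log.info("CAX planar fluence per electron at z2: %.4e cm^-2", cax_fluence)

    Rp = practical_range(Ep0)
    electron_dose = electron_dose_profile(electron, Ep0, geometry.calc_depth)
    Ke = fluence_to_dose_constant(Ep0, geometry.calc_depth)

    if cfg.xray.include:
        cal = XrayCalibration(a=cfg.xray.a, b=cfg.xray.b, c=cfg.xray.c)
        window = get_material(cfg.window.material)
        primary = get_material(cfg.primary_foil.material)
        entries = []
        t_w = cfg.window.thickness_cm
        if t_w > 0.0:
            entries.append(
                (
                    "window",
                    radiative_mass_stopping_power(window, E_incident)
                    * window.density * t_w,
                    reduced_gaussian_scattering_power(window, t_w, E_incident).T,
                    t_w,
                )
            )
        t_p = cfg.primary_foil.thickness_cm
        entries.append(
            (
                "primary",
                radiative_mass_stopping_power(primary, E_primary)
                * primary.density * t_p,
                reduced_gaussian_scattering_power(primary, t_p, E_primary).T,
                t_p,
            )
        )
        if foil is not None:
            t_bar = mean_secondary_thickness(
                foil, fluence_z1, calc.secondary_mean_thickness
            )
            if t_bar > 0.0:
                entries.append(
                    (
                        "secondary",
                        radiative_mass_stopping_power(foil.material, E_sec_in)
                        * foil.material.density * t_bar,
                        reduced_gaussian_scattering_power(
                            foil.material, t_bar, E_sec_in
                        ).T,
                        t_bar,
                    )
                )
        budget = build_xray_budget(entries, E_incident)
        xray_profile, pct_d, X = offaxis_xray_percent_profile(
            budget, cal, geometry, Ep0, cax_fluence, electron.r
        )
        pct_rp2 = cax_xray_percent(X, cal)
        log.info(
            "X-ray: X = %.2f MeV, %%D_cax(Rp+2) = %.2f%%, %%D_cax(d) = %.2f%%",
            X, pct_rp2, pct_d,
        )
        total = total_dose_profile(electron_dose, xray_profile, pct_d)
    else:
        budget = None
        xray_profile = None
        pct_rp2 = pct_d = X = None
        total = Profile(electron.r, 100.0 * electron_dose.v, "cax_100")

    return SimulationResult(
        config=cfg,
        geometry=geometry,
        schedule=schedule,
        moments_z1=moments_z1,
        foil=foil,
        electron_profile=electron,
        cax_fluence_per_electron=cax_fluence,
        Ke=Ke,
        Rp=Rp,
        xray_profile=xray_profile,
        pct_xray_cax_rp2=pct_rp2,
        pct_xray_cax_d=pct_d,
        x_stat=X,
        budget=budget,
        total_profile=total,
    )
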