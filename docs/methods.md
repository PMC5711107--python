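# Methods

This note documents the physics implemented in `foilsim`, the numerical
choices behind it, and what the test suite does and does not establish.

## Scope and geometry

The simulator models the *in-air* off-axis dose of an electron beamline
consisting of a vacuum exit window, a primary scattering foil, air gaps,
and an axisymmetric secondary scattering foil. The axial coordinate is
zero at the top of the primary foil; the secondary foil top sits at
`z1 = primary_to_secondary`, the isocenter at `z1 + secondary_to_iso`,
and the calculation plane at depth `d` past isocenter (`z2`). Electron
scatter from jaws, applicators and other collimation is not modelled;
neither is backscatter or a polyenergetic source (the incident beam is
monoenergetic, so the incident mean and most probable energies
coincide). The nominal distances shipped as defaults (5 / 12 / 88 cm)
are representative of a clinical accelerator head but are **not** the
geometry of any specific machine; quantitative comparison with a given
accelerator requires entering its measured distances.

## Materials

Materials are single (effective) elements with `Z`, `A`, density and
mean excitation energy `I`; compounds are represented by effective
values, matching how a designer enters them. The registry ships nickel,
tantalum, aluminum, air (effective Z = 7.36, A = 14.6 g/mol, density
1.205e-3 g/cm³) and liquid water (Z = 10, A = 18.0153, I = 75 eV, which
preserves Z/A and hence all per-electron quantities). Registry
materials also carry a sub-shell oscillator table used by the
density-effect evaluation.

One known consequence of the effective-element representation: cross
sections scaling with Z(Z+1)/A (scattering, bremsstrahlung) are exact
for elements, good for air (4.21 vs. 4.18 true), but high by ~45% for
water treated as Z = 10. Water is used as the dose medium (stopping
powers only), never as a foil, so this does not affect the simulator's
outputs; it would matter only if a user modelled a water-equivalent
scatterer through the effective-element route.

## Stopping powers

*Collision* mass stopping power is the Bethe/Moller closed form in the
ICRU-35 presentation with the Sternheimer density-effect correction.
The density effect is evaluated **exactly** from the Sternheimer
oscillator model: sub-shell oscillators (occupancy, nominal binding
energy, plus conduction electrons for the metals) are adjusted by a
common scale factor so the model reproduces `ln I` (with the 2/3·f
plasma-broadening term), the dispersion equation is solved for each
energy by bracketing, and delta follows in closed form. Materials
without an oscillator table fall back to a single oscillator at `I`.
The exact evaluation matters here: over 4–16 MeV the water values span
1.870–2.021 MeV g⁻¹ cm², consistent at the 0.1% level with the standard
tabulations, whereas the popular fitted-coefficient delta parameteriza-
tion is ~0.3% high at the top of that range. The supported kinetic
energy window is 0.1–50 MeV (no shell corrections, which matter only
well below it).

*Radiative* mass stopping power integrates the Schiff
intermediate-screening bremsstrahlung spectrum (Born approximation with
a single Thomas-Fermi screening parameter) over the photon energy with
96-point Gauss-Legendre quadrature, with the Davies-Bethe-Maximon
Coulomb correction applied to the screened logarithm and
electron-electron bremsstrahlung through a Z(Z+1) scaling. For the
elemental foils this lands within a few percent of the standard
tabulations over the clinical range, which is adequate because the
radiative losses only set the X-ray budget, whose absolute scale is
re-anchored by the empirical central-axis calibration.

*Mean-energy transport* multiplies the total linear stopping power by
the path length; when the single-step loss exceeds 1% of the energy the
slab is integrated with ≥ 10 RK4 sub-steps, making successive slabs
composable to better than 1e-6 relative. The secondary foil's exit
energy is the fluence-weighted mean over the incident z1 fluence of the
per-radius exit energies, and its scattering power is evaluated at the
average of the entrance and exit means.

## Scattering powers

The full-plane mean-square scattering angle of a slab is the Gaussian
core of Moliere theory, `chi_c^2 B`, with `B - ln B = ln Omega_0` and
`Omega_0 = chi_c^2/(1.167 chi_a^2)`; `chi_c^2` uses Z(Z+1) to include
scattering off atomic electrons. The *reduced Gaussian* scattering
power applies the factor `(1 - 1.330/B)`, which narrows the Gaussian to
match the core of the full Moliere distribution. Conventions for the
`Omega_0` constant differ across the literature (the 1.167 =
exp(2·gamma_E − 1) Bethe value versus variants absorbing the 1.13
screening factor); the Bethe convention is used consistently and every
consumer goes through the single implementation in
`foilsim.scattering`. Solutions require `Omega_0 > e` ("Moliere regime")
and the reduced factor requires `B > 1.330`; both are enforced with
explicit errors rather than silent extrapolation. For the thin outer
segments of a secondary foil the Moliere `B` is evaluated at the
segmentation's minimum positive thickness (a floor), and zero-thickness
radii contribute no scatter.

Throughout the package the scattering power `T` is the **full-plane**
mean-square-angle growth rate (rad²/cm); per-axis variances are `T/2`,
and the z1 fluence Gaussian is `exp(-r²/A2)/(pi A2)`.

## Transport and the pencil-beam convolution

Fermi-Eyges moments `A_n = ∫ T (z - z')^n dz'` are accumulated with thin
solid elements lumped at their midpoints and air columns integrated in
closed form (the exact `(z-z')^n` integral; for the ~90 cm drift to the
calculation plane the exact `L³/3` second moment differs from a
midpoint lump by a third, so the closed form is used everywhere an
extended element appears).

Pencil mean positions project from the top of the primary foil: a
pencil at radius rho in the z1 plane is centred at `(z2/z1)·rho` at z2.
Its Gaussian kernel variance is

```
sigma² = (A0 − A1²/A2)(z2−z1)² + T_sec(t(rho))·t(rho)·(z2−z1)² + T_air·(z2−z1)³/3
```

The first term is the *conditional* angular variance — the
position-angle covariance already expressed in the spatial spread at z1
is removed. Whether the original interactive tool used the conditional
or the uncorrelated kernel is not documented; both are implemented
(`calculation.kernel = conditional | uncorrelated`) and conditional is
the default because it reproduces the exact Fermi-Eyges second moment
at the plane when the scatter is concentrated at the primary foil, the
geometry the projection rule assumes. The difference is second order
for thin upstream scatterers.

The convolution integral uses midpoint quadrature with (by default) 100
radial nodes on `[0, rho_max]` (`rho_max` = the secondary-foil radius,
3.65 cm) and 100 angular nodes on `[0, pi]` doubled by symmetry, with
the profile evaluated on a 60-point half-grid to 30 cm and mirrored.
After each profile the central-axis value is recomputed on a doubled
quadrature grid and a warning is logged if it moves by more than 0.5%.
Note that fluence falling outside `rho_max` at z1 is excluded by
construction; for heavily scattered low-energy beams this truncates a
few percent of the electrons, which mildly depresses the far tail of
the relative profile. With no secondary foil the profile is computed
analytically as the projected Gaussian.

Electron fluence is converted to dose with a constant `Ke`, the water
collision stopping power at `Ed = Ep0 − 2d` MeV (the 2 MeV/cm
depth-scaling rule, which also gives the practical range `Rp = Ep0/2`);
under central-axis normalization the constant cancels, so the relative
dose profile equals the relative fluence profile, and `Ke` is computed
only to validate the depth and for the log. Calculation depths beyond
2 cm trigger a warning (the in-air = in-water equivalence degrades).
The most probable surface energy `Ep0` is display-only bookkeeping: it
equals the transported mean `E0bar` plus a configurable offset (default
0), and an input given as `Ep0` is inverted to the incident energy by
root-finding on the forward transport.

## X-ray model

Per element (window, primary, secondary) the budget holds the radiative
loss `dE_rad` (radiative linear stopping power at the element's
entrance mean energy x thickness; no sub-stepping needed at foil
thicknesses), the scattering power `T` at the entrance energy, the mean
thickness, and the entrance zeroth moment chained from the empirical
incident moment `A0,0 = 0.05 E^-1.6` (units rad², on the same scale as
`T·t`; the power law is an empirical fit and carries no printed units).
The secondary foil's mean thickness is fluence-weighted over the
incident z1 fluence, consistent with the fluence-weighted exit-energy
treatment (a `cax` switch uses the central-axis thickness instead).

The off-axis relative shape is the ratio of summed E1 brackets at
`(r/z)²` to the analytic r = 0 logarithmic limit `ln(1 + T t/A0)`. The
central-axis percent dose at depth `Rp + 2` cm follows the calibrated
curve `aX + b(1 − e^(−cX))` (a = −0.035 %/MeV, b = 15.77 %, c = 0.016
/MeV, fitted against Monte Carlo and forced through the origin);
because the fit is empirical, a negative extrapolation at extreme X is
clamped to zero with a warning rather than trusted. Depth rescaling to
the calculation depth is pure inverse square — photon attenuation in
water (~9%) is deliberately ignored, consistent with the calibration.
The calibration constants are exposed in the configuration; re-fitting
them requires Monte Carlo or measured data and is out of scope.

## Flatness and objective refinement

Profiles are compared on the CAX = 1 relative scale; deviations are
reported in percentage points as the maxima above and below the
objective inside ±`range_cm` (default 14.6 cm, i.e. 2 cm inside the
diagonal edge of a 25x25 cm² applicator), evaluated at the profile's
grid points with the objective linearly interpolated. There is no
extrapolation: an objective that does not cover the range is an error.
The refinement rule is pointwise `objective − (reference − simulated)`
on a common grid. IEC-style flatness/symmetry indices and penumbra
metrics are not implemented.

## Foil segmentation

A Gaussian secondary foil `t0·exp(−r²/2σ²)` is approximated by
`n_segments` equally spaced annuli (half-open `[r_k, r_{k+1})`,
boundary radii belonging to the inner annulus). The midpoint rule —
each descending step edge crosses the true Gaussian at its midpoint —
fixes only differences of adjacent thicknesses, so the stack is
anchored by setting the innermost segment to the area-weighted mean of
the true Gaussian over the central annulus and propagating outward,
clamping at zero. This makes the segmentation unique, monotone for
Gaussian designs, and L1-convergent to the true profile as the segment
count grows. The default of 16 segments is a typical machining choice;
the segment count is a free design parameter.

## Configuration, determinism, performance

The configuration file is INI-style key=value text mirroring the panes
of an interactive tool; it round-trips losslessly through
`save_config`/`load_config`. All defaults are the standard calculation
options: 30 cm profile half-range, 100 radial and 100 angular
integration points, 60 profile points, 3.65 cm secondary-foil radius,
2 cm calculation depth, ±14.6 cm / 3% flatness. There is no random
number generator anywhere in the production path: repeated runs are
bit-identical, and a default simulation takes well under a second on a
single CPU (the performance contract in the tests is 2 s).

## What the tests show — and what they do not

The suite verifies the implementation against *independent* numerical
oracles: a second, test-local coding of the Bethe and bremsstrahlung
formulas; a power-series/continued-fraction E1; seeded Gaussian
random-walk transport for the Fermi-Eyges widths and the conditional
kernel; and a dense Cartesian brute-force convolution against the polar
quadrature (agreement within 0.5% of the central-axis value). Property
tests cover the stated invariants (stopping-power band, reduced-factor
bounds, normalization identities, monotone sensitivity directions of
primary thickness, secondary thickness and sigma).

These checks validate the *mathematics* of the model, not its clinical
accuracy for a specific accelerator: the headline experimental
agreements (percent-level match of profiles with full Monte Carlo, and
sub-percent central-axis X-ray agreement with commissioning data)
depend on proprietary beamline geometry and on Monte Carlo engines that
are outside this package. The random-walk oracle is Gaussian by
construction — it validates the moment bookkeeping, and cannot detect
the physical error of the Gaussian core approximation itself, which is
known to underestimate large-angle scatter at the highest energies.
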