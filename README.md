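# foilsim

An analytical, real-time simulator for designing **electron dual scattering
foil systems** on radiotherapy accelerators.

Clinical electron beams are flattened by a pair of scattering foils: a thin
high-Z *primary* foil that broadens the narrow accelerator beam into a
roughly Gaussian fluence at isocenter, and a shaped low-Z *secondary* foil
(typically a stepped approximation of a Gaussian cross-section) that
flattens it. Designing such a system with Monte Carlo alone is slow;
`foilsim` computes the off-axis electron relative fluence/dose profile, the
central-axis and off-axis bremsstrahlung ("X-ray") contamination dose, and
the combined total relative dose profile in well under a second, so foil
parameters can be swept and optimized interactively, with Monte Carlo or
measurement reserved for the final verification step.

`foilsim` is aimed at medical physicists and accelerator engineers; it is
also a compact teaching tool for Fermi-Eyges transport and beam-flattening
physics.

## Model

**Electron component.** The beam is transported with Fermi-Eyges
small-angle multiple-scattering theory. Scattering powers are the Gaussian
core of Moliere theory with the reduced-Gaussian correction,

$$T = \frac{\chi_c^2\,B}{t}\Bigl(1 - \frac{1.330}{B}\Bigr),
\qquad B - \ln B = \ln\Omega_0 ,$$

evaluated at the beam's **mean** energy at each element (mean energies are
obtained from ICRU-35-style collision + radiative stopping powers). The
planar fluence at the secondary-foil plane $z_1$ is the Gaussian
$\Phi_e(z_1,\rho) = e^{-\rho^2/A_2}/(\pi A_2)$ with
$A_n(z_1)=\sum_i T_i t_i (z_1-\bar z_i)^n$, and the fluence at the
calculation plane $z_2$ is the polar convolution

$$\Phi_e(z_2,\vec r) = \int_0^{2\pi}\!\!\int_0^{\rho_{\max}}
\Phi_e(z_1,\vec\rho)\, \Phi_e(z_2-z_1,\vec r,\vec\rho)\,\rho\,d\rho\,d\Theta ,$$

where each pencil is centred at the projection $(z_2/z_1)\vec\rho$ and
carries a Gaussian kernel whose variance combines the residual
(conditional) angular spread of the upstream stack, the local
secondary-foil scatter $T(t(\rho))\,t(\rho)$, and the air column to $z_2$.
At shallow depths the relative fluence profile in air equals the relative
dose profile in water.

**X-ray component.** Each element radiates $\Delta E_{rad,i}$; the
off-axis X-ray dose shape is a sum of exponential-integral brackets
$E_1\!\bigl(\theta_r^2/(A_{0,i}+T_i t_i)\bigr)-E_1\!\bigl(\theta_r^2/A_{0,i}\bigr)$
with the empirical incident moment $A_{0,0}=0.05\,E^{-1.6}$. The absolute
central-axis level at depth $R_p+2$ cm is the calibrated curve
$\%D_{\gamma,\mathrm{CAX}} = aX + b(1-e^{-cX})$ with
$a=-0.035\,\%/\mathrm{MeV}$, $b=15.77\,\%$, $c=0.016\,/\mathrm{MeV}$, where
$X$ folds the radiative budget, an inverse-square factor and the
central-axis electron fluence. The total profile is

$$D_T(d,r) = \%D_\gamma(d,r) + \bigl[100\% - \%D_{\gamma,\mathrm{CAX}}(d)\bigr]
\frac{D_e(d,r)}{D_e(d,0)} .$$

Flatness is reported as the maximum deviation above/below an objective
profile inside ±14.6 cm (3% criterion by default), and objective profiles
can be refined by the simulator-vs-reference discrepancy,
$D^{obj,ref} = D^{obj} - (D^{ref}-D^{sim})$.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Write the default configuration (13 MeV beam; 0.0125 cm nickel exit
window; 80 µm tantalum primary; aluminum Gaussian secondary foil with
`t0 = 0.6` cm, `sigma = 1.44` cm in 16 segments; nominal 5/12/88 cm
window–primary–secondary–isocenter spacing) and simulate:

```
python -c "from foilsim.config import SimulationConfig, save_config; \
           save_config(SimulationConfig(), 'example.cfg')"
foilsim simulate example.cfg -o out
```

which prints

```
E_incident_mean_MeV   13.0000
E_mean_isocenter_MeV  10.6734
Ep0_MeV               10.6734
Ke_MeV_cm2_per_g      1.9229
Rp_cm                 5.3367
cax_fluence_per_e_cm2 2.270872e-04
moments_z1_A0_rad2    3.755525e-02
moments_z1_A1_rad2cm  5.005949e-01
moments_z1_A2_cm2     6.879992e+00
X_statistic_MeV       13.9523
pct_xray_cax_Rp2      2.6668
pct_xray_cax_depth    2.9532
```

The beam loses about 2.3 MeV between the exit window and the isocenter
surface; the electron-to-dose constant `Ke` is the water collision
stopping power at the depth-scaled energy; and the bremsstrahlung
contamination from the foil stack is 2.67% of the dose maximum at depth
`Rp + 2` cm (2.95% rescaled to the 2 cm calculation depth). The profile
files in `out/` hold the electron (CAX = 1), X-ray (% of dose maximum)
and total (CAX = 100) off-axis profiles.

A slider-style sweep of the primary-foil thickness,

```
foilsim sweep example.cfg primary.thickness 0.005 0.008 0.011 -o sweep
# primary.thickness  flatness_over_pct  flatness_under_pct  cax_xray_pct_Rp2
0.005  0.0000  6.9065  2.3111
0.008  0.0000  3.7728  2.6668
0.011  0.0000  1.5975  3.0498
```

shows the characteristic design trade-off: a thicker primary foil fills
in the profile shoulders (smaller under-deviation from a flat objective)
at the price of more X-ray contamination. `foilsim design-check`
evaluates a design against an objective profile and, given a reference
(Monte Carlo or measured) profile, writes the refined objective.

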