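# Methods

## The quantities

The underwater light field is represented by quad-averaged spectral radiance
`L(z, theta_band, phi_bin, lambda)` on a fixed discretization of the downward
hemisphere: polar bands {0–5° (cap), 5–15°, …, 75–85°, 85–90°} and 24 azimuth
bins of 15° (the cap is a single quad). Theta is measured from the downward
vertical. Two irradiances are derived per depth and wavelength:

* **Planar downward irradiance** `Ed = sum L * mu_band * Omega_quad`, with the
  exact band mean cosine `mu = (cos theta_lower + cos theta_upper)/2`. This
  weighting makes the closed forms exact: an isotropic unit radiance gives
  `Ed = pi` and the cosine-weighted hemisphere closure `sum mu*Omega = pi`
  holds to machine precision.
* **Annular irradiance** `Ea(theta_i) = sum_j L(theta_i, phi_j) dtheta_i
  dphi_j` for the eight measurement bands `theta_i = 10 … 80°` — no cosine
  factor, because the ring sensor is normal to the theta direction. Its units
  follow the definition as written: radiance × solid angle, W m⁻² nm⁻¹ per
  band.

Broadband quantities integrate over the photosynthetically active range with
rectangle-rule band sums, `PAR = sum E * dlambda * lambda/(h c N_A)` in
mol quanta s⁻¹ m⁻². The wavelength grid is the 60 band centers 402.5–697.5 nm
(5 nm bands; a 30-band 10 nm mode exists for fast scenario sweeps — the source
quantities are band averages, so rectangle sums, not trapezoids).

Attenuation coefficients come from the two-depth formula
`K = ln(E(z1)/E(z2))/(z2 - z1)` or from unweighted OLS of `ln E` on `z`
(`K = -slope`, r² reported). Both are scale invariant and agree exactly on a
pure exponential. Depth ranges "0–z" use every grid depth ≤ z; the grid
starts at 0.02 m, so the surface itself is never a sample. Broadband K is
regressed on PAR-integrated irradiance, not averaged over spectral K.

## The synthetic scenario grid

Seven optical water classes (ultra clear → brown) carry {low, high} ranges
for chlorophyll (mg m⁻³), CDOM absorption at 380 nm (m⁻¹) and mineral load
(g m⁻³); scenarios use only the 8 low/high corners of each class. (The
published "ultra clear" row prints its Max/Min columns swapped; the pair is
treated as an unordered set.) Lighting spans solar zenith 0–80° in 10° steps
and cloud cover 0–100 % in 20 % steps: 7 × 8 × 9 × 6 = 3024 scenarios; the
near-surface case study restricts zenith to ≤ 60° (2352). The depth grid
refines toward the surface (2 cm steps to 0.5 m, coarsening to 5 m steps by
20 m); water is homogeneous and effectively infinitely deep, the surface flat.

Constituents map to IOPs with standard-magnitude case-2 parameters:
double-Gaussian chlorophyll-specific absorption (0.05 m² mg⁻¹ at 440 nm,
secondary peak at 675 nm), CDOM slope 0.014 nm⁻¹ from 380 nm, mineral
absorption 0.03 m² g⁻¹ at 443 nm with slope 0.011 nm⁻¹, particle scattering
with a (550/λ) shape (0.30 m² mg⁻¹ chlorophyll, 0.50 m² g⁻¹ mineral at
550 nm), particulate backscatter ratio 0.018, pure-water absorption from the
standard published visible table and pure-water scattering ∝ λ⁻⁴·³². Exact
values matter for realism, not for any ratio or correlation statistic.

## The radiance generator

Each scenario's field is a sum of two components, built on the quad grid:

* **Direct lobe.** The sun (azimuth fixed at 0 — every derived quantity
  integrates over azimuth) refracts to `theta_sw = asin(sin(zenith)/1.34)`.
  Radiance is Gaussian in the great-circle angle from that direction with
  width σ = 5°, renormalized at every depth so the lobe's *planar* irradiance
  decays exactly as `exp(-K_dir z)` with `K_dir = (a + b_b)/cos(theta_sw)`.
* **Diffuse background.** An azimuth-independent cardioid `(1 + 2 cos
  theta)/3`, multiplied by a soft Snell's-window transmission factor (sigmoid
  roll-off at 48.27°, width 5°, scattered-light floor 0.05), decaying as
  `K_dif = (a + b_b)/0.83`. The window factor reflects that *all*
  above-surface light — sky as well as sun — refracts into the 48.3° cone;
  radiance outside it is only the weak scattered residue. Without it the
  65–90° bands would carry implausibly large irradiance and the
  optimal-angle analysis would not show the observed collapse of Ea60–Ea80.

The surface partition is `(1 - f_dif) : f_dif` of a 5800 K blackbody
reference spectrum (unit value at 550 nm; the absolute scale cancels
everywhere), with diffuse fraction `f_dif = cloud + 0.15 (1 - cloud)` —
monotone in cloud cover with a nonzero clear-sky skylight floor — and
diffuse mean cosine 0.83. Optional multiplicative log-normal noise is applied
per quad under an explicit per-scenario seed (derived from the base seed by a
fixed counter); default pipelines are noise free and fully deterministic.

The generator's reference ("ground truth") attenuation is the two-stream
value `Kd_gen = (a + b_b) / [(1 - f_dif) cos(theta_sw) + f_dif * 0.83]`.

### Design choices and their reasons

* **Static lobe width.** A depth-growing Gaussian width (emulating
  multiple-scattering broadening) was implemented and evaluated first; it
  was rejected because the Gaussian tail `exp(-psi²/2σ(z)²)` then *grows*
  with depth at lobe-edge bands — annular irradiance at those bands
  increases with depth, its log-profile is far from linear, and the derived
  Ka loses all relation to Kd, unlike real radiative-transfer fields in
  which every band decays near-exponentially while the angular distribution
  relaxes slowly. With a static lobe every band's irradiance is an exact
  two-exponential direct/diffuse mixture, which is precisely the structure
  the annular-attenuation method assumes. The width machinery
  (`SIGMA0_DEG`, `K_SIGMA_DEG`, `SIGMA_MAX_DEG`) remains in place with the
  growth rate set to 0.
* **Per-depth lobe normalization.** The lobe amplitude is renormalized
  against its quad-integrated planar irradiance at every depth, so any
  angular redistribution conserves energy and `Ed` recovery against
  `Kd_gen` holds by construction for both components.
* **Two-stream reference vs regression.** The regression K of a
  direct/diffuse mixture is a depth-weighted value between `K_dir` and
  `K_dif`, while `Kd_gen` uses the harmonic-mean cosine; the gap grows with
  `f_dif (1 - f_dif)` and with optical depth over the regression window. It
  is negligible for clear sky or overcast conditions and reaches a few
  percent at mid cloud fractions in the most turbid classes — an inherent
  property of defining a single "true" K for a non-exponential profile.
* **Broadband K is not a spectral average.** `K(Ed_PAR)` lies below the
  surface spectral mean of `Kd_gen(lambda)` because strongly absorbed red
  wavelengths leave the PAR mixture first; comparisons against the reference
  attenuation are therefore made per wavelength.

## Assessment

For a scenario set the package computes: the mean and standard deviation of
`log10(Ea(theta_i)/Ed)` (PAR band) per annular angle at the analysis depths
0.2–10 m; Pearson r and slope m of the OLS regression of Ka (response) on Kd
(predictor) — that orientation makes the reconstruction `Kd_hat = Ka/m`
exact when the relation is — pooled and per (zenith × cloud) lattice cell
(each cell pools the 56 water points; significance p-values are reported, no
filtering applied); the cell-averaged slope per band and depth range; and
the relative error `eps_K = (Kd_hat - Kd)/Kd * 100`, summarized as the mean
absolute value — as a fraction in the band × depth-range error table, and in
percent per lighting cell and per water class. Heat-maps are evaluated at
1.5 m, the focal near-surface depth.

## What the synthetic tests do and do not show

The generator reproduces the *mechanisms* the method relies on —
near-exponential decay, Snell's-window confinement, the direct/diffuse
partition controlled by zenith angle and cloud cover — and on it the method
behaves as reported on full radiative-transfer data: the Ea/Ed curve peaks
at 30–40° and collapses beyond 60°, Kd–Ka correlations exceed 0.99 pooled,
per-cell regression slopes span ≈1.00–1.13 (the deposited-data analysis
spans 0.81–1.18), and worst-cell reconstruction errors stay within the
20 % / 30 % envelopes for Ka40 / Ka50.

It does **not** contain Raman scattering or chlorophyll/CDOM fluorescence
(red-band radiances are therefore cleaner than in nature), surface waves,
vertical stratification, or the slow angular relaxation of multiple
scattering. Consequently some second-order geographic details of the
full-physics analysis do not reproduce: per-cell correlations stay ≈1
everywhere rather than dipping at the zenith-equals-band-angle cells, and
the per-water-type error maps peak in the clear-sky column at low zenith for
every class instead of shifting toward the 40° column for turbid classes.
Passing the synthetic suite validates the pipeline's mathematics and the
method's first-order behaviour, not sensor performance in real water.

## Problem sizes and numerics

Scenario-set analyses run the 3024-scenario grid at 10 nm spectral
resolution over the depth grid truncated at 1.5 m (the deepest range the
assessments use); single-scenario analyses use the full 5 nm / 20 m grids.
Regressions require ≥ 3 positive samples; constant profiles return K = 0
with the fit flagged degenerate (r² = None). Zero planar irradiance makes
the log-ratio undefined and raises. Solid angles close to 2π within 1e−12;
quad solid angles agree with dense numerical integration to 1e−9. All CSV
artifacts carry a provenance header (config hash over the scientific
parameters, base seed); radiance fields persist to NetCDF with the scenario
parameters as attributes.
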