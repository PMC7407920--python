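# Methods

This note documents the models implemented in `osadose`, the parameters
that matter, the numerical choices behind them, and what the synthetic
data — and therefore the passing tests — do and do not demonstrate.

## Scene model

The physical scene is a regular, isotropic voxel grid (default 0.5 mm;
most bundled runs use 1 mm). From bottom to top: an optional thick
"backscatter" phantom slab (default 15 mm when present), the applicator
layer (one layer of 10-mm silicone spheres on a square touching lattice,
air between beads), an optional thin phantom slab standing in for
overlying tissue (3 or 5 mm), and an air headspace (default 3 mm). The
scoring plane — where a 96-well plate would rest — is the top surface of
the stack. A voxel grid was chosen over a surface/tetrahedral mesh: it is
simple, fully reproducible (labeling is a pure function of the
configuration), and adequate for planar dosimetry at the millimetre scale
of interest. The well plate itself is not modelled.

The air headspace exists so that the stack's top surface is an internal
material boundary: the phantom–air index step there carries Fresnel
internal reflection, which raises the fluence at the scoring plane by tens
of percent and would be silently lost if the surface coincided with the
grid edge (grid edges are vacuum escape surfaces).

Material constants (absorption µ_a and reduced scattering µ_s′ in cm⁻¹):

| material | µ_a | µ_s′ | g | n | notes |
|---|---|---|---|---|---|
| phantom @532 nm | 0.24 | 7.05 | 0.9 | 1.37 | measured recipe values |
| phantom @630 nm | 0.26 | 7.00 | 0.9 | 1.37 | measured recipe values |
| silicone | 0.01 | 0 | – | 1.41 | transparent, slightly absorbing |
| air | 0 | 0 | – | 1.00 | vacuum for transport |

Anisotropy and refractive indices are not part of the phantom
characterization; g = 0.9 is the standard tissue-optics default with
µ_s = µ_s′/(1−g), and a *reduced* mode (g = 0, µ_s = µ_s′) is provided for
diffusion-regime work, where the similarity relation makes the two
equivalent beyond one transport mean free path (verified to within 10% in
the tests). The applicator's exact bead interconnection geometry is not
documented anywhere; the square touching lattice is a stated default, and
the bead layer's voxelized volume is checked against the sphere-volume
formula (within 5% at ≤1 mm voxels).

## Transport kernel

Photon-packet Monte Carlo with the standard variance-reduced rules:

- **Free paths** `s = −ln ξ / µ_t` of the current material; in
  non-interacting media (air) packets fly voxel-to-voxel without consuming
  optical depth.
- **Scoring**: track-length estimator — every voxel traversal deposits
  weight × path length (weight·mm). This is required here because the
  scoring plane usually lies in weakly or non-absorbing media; an
  absorbed-weight (collision) estimate is kept as a cross-check and agrees
  with the track-length integral of µ_a·Φ to well under 0.5%.
- **Absorption**: continuous weight attenuation by the albedo µ_s/µ_t at
  each interaction (lower variance than discrete absorption).
- **Scattering**: Henyey–Greenstein sampling of the deflection cosine; the
  g = 0 limit is uniform on [−1, 1] (KS-tested).
- **Boundaries**: unpolarized Fresnel reflection / Snell refraction at
  axis-aligned voxel faces between media of different n; total internal
  reflection handled; grid edges are escape surfaces.
- **Russian roulette** below weight 10⁻⁴ with survival factor 10; the
  ledger records roulette losses and gains separately so closure can be
  verified exactly (launched = absorbed + escaped + forced + net-roulette
  to machine precision) and statistically (absorbed + escaped ≈ launched
  to <10⁻³ relative).
- **RNG**: one splitmix64 counter stream per packet index derived from an
  explicit integer seed, so a run is bit-reproducible regardless of
  scheduling, and packets are statistically independent.

Sources are isotropically emitting line segments — the standard
abstraction of cylindrical/radial diffuser fibers, characterized by linear
power density (mW/cm). Two 2-cm fibers 3 cm apart, 5 mm below the
applicator surface, are the default arrangement. The delivery schedule is
parameterized as the *total* linear power across both fibers (default
200 mW/cm, i.e. 100 mW/cm per fiber, 400 mW total; 55.6 J/cm over 278 s);
a per-fiber reading is available via `per_fiber=True`. Packets are
allocated to sources in proportion to their power so one global
`P_total/N` normalization applies.

Validation oracles: Beer–Lambert transmission through a pure absorber
(exact limit, tested statistically); diffusion-approximation agreement for
a point source in an index-matched medium,
Φ(r) = P·e^(−µ_eff r)/(4πDr) with D = 1/(3(µ_a+µ_s′)), within 5% over
1 ≤ µ_eff·r ≤ 4 at both wavelengths; mirror symmetry for mirrored sources;
exact linearity in source power (rescaling is applied post hoc, never by
re-simulation).

## Dose maps

Irradiance (used throughout as fluence rate) of a voxel layer:
`E = S/V · P_total/N · 100` mW/cm², where S is the accumulated weight·mm
in the voxel, V the voxel volume in mm³, and the factor 100 converts
mm⁻² to cm⁻². Fluence is `F = E·t/1000` J/cm². The map plane is the single
voxel layer containing the requested z, with a plane that coincides with a
layer boundary assigned to the layer *below* it — a plate resting on the
surface sees the medium underneath. No smoothing is applied.

One estimator subtlety is worth recording: inside a turbid layer the local
fluence is inflated by diffusive buildup (light crosses the layer several
times), so comparing "with 3-mm phantom" to "without phantom" *at the
in-medium plate plane* does not show the attenuation one might expect —
the buildup almost exactly offsets e^(−µ_eff·d) at d = 3 mm. The
attenuation comparison in the tests is therefore made in the air layer
just above the stack (transmitted light), where it holds strictly. Whether
a plane fluence rate or a cosine-weighted surface irradiance better
matches a measured viability map is an open question of the original
experiment description; plane fluence rate is implemented.

## Dose–response layer

The 4-parameter Hill (log-logistic) model
`v(C) = bottom + (top−bottom)/(1+(C/EC50)^h)` is fitted on log₁₀
concentration with `scipy.optimize.curve_fit`, multi-started over a grid
of EC50 and slope initials (28 starts), bounds 0 ≤ bottom ≤ top ≤ 1.2
(assay ceiling above 1 allows normalization overshoot), 0.05 ≤ h ≤ 20.
All replicate points are fitted jointly; the EC50 standard error comes
from the covariance by the delta method. Noiseless Hill data is recovered
to six significant digits, and the fit is exactly equivariant under
concentration-unit rescaling.

Censoring: a curve whose fitted EC50 exceeds the highest tested
concentration — or that shows no response at all (mean per-concentration
drop < 0.05) — is flagged censored and its EC50 reported as the highest
tested concentration, a lower bound. This is the standard situation for a
dark-toxicity curve. The phototherapeutic index (dark/light EC50) is then
itself a lower bound; a censored light curve admits no index.

Over 200 synthetic triplicate datasets at noise σ = 0.03 the fitted EC50
shows <1% bias and ~0.72 one-sigma interval coverage (the tests require
|bias| < 5% and coverage in [0.6, 0.8]).

Irradiance dependence is represented only as grouped condition comparisons
(datasets carry their irradiance and fluence as metadata); no mechanistic
rate or reciprocity-failure model is implemented because none is
established for this photosensitizer.

## Kill model and plate prediction

The dose metric is the product of photosensitizer concentration and
fluence (µM·J/cm²), matching the EC50-dose-product potency summaries. The
kill curve `v(F) = 1/(1+(c·F/dp50)^h_k)` is calibrated in closed form from
two thresholds: dp50 = c·f50, and h_k = ln(1/floor − 1)/ln(f_kill/f50).
With the defaults (c = 10 µM, f50 = 5 J/cm², f_kill = 20 J/cm²,
floor = 0.01) this gives dp50 = 50 µM·J/cm² and h_k = ln 99/ln 4 ≈ 3.31.
"Complete kill" is operationalized as ≤1% residual viability, since an
exact zero is unreachable under a Hill form.

Plates use the standard 96-well geometry (9-mm pitch, 6.4-mm well
diameter); per-well dose is the *footprint mean* fluence over the well
disc (not a center-point sample). The default placement centers the plate
on the applicator with a one-column overhang beyond its right edge, so the
last column probes the region just outside the treated field. Predictions
are equivariant under joint translation of plate and field.

## Synthetic data

Generators are pure functions of (truth, seed): dose–response datasets are
Hill curves plus additive Gaussian noise (σ = 0.03 by default,
triplicates, clipped at 0) on the experimental concentration grids
(0.01–0.5 µM green, 2–40 µM red, 0.1–60 µM dark); ground-truth EC50s
default to the measured potencies (0.099 and 20.9 µM) so recovery tests
are anchored to realistic values. Synthetic measured plates are model
predictions plus per-well Gaussian noise (σ = 0.05, clipped to [0, 1]).
A closed-form two-line fluence pattern (superposed K₀(µ_eff r) line
kernels) exercises the plate stages without a transport run.

What this does *not* show: the noise model is additive Gaussian, whereas
real resazurin viability has heteroscedastic, occasionally skewed errors
and plate-position effects; the synthetic plates share the exact kill
model used for prediction, so plate-comparison tests verify the machinery
and noise floor, not biological model adequacy.

## Problem sizes and runtime

Defaults were chosen for desk-scale reproducibility on one CPU: most test
simulations use 2×10⁴–2×10⁵ packets on 1-mm voxels (seconds each); the
diffusion oracle uses 1.5×10⁵ packets in a 70-mm cube; the acceptance
script's applicator run uses 2×10⁵ packets. Monte Carlo uncertainty at
these sizes is far below every tolerance asserted (well-footprint averages
pool hundreds of voxels). Full-resolution runs (10⁶ packets, 0.5-mm
voxels) take under a minute and change the plate-plane fluences by less
than the Monte Carlo noise of the smaller runs.

## Known limitations

- The simulated plate-plane fluence beneath the diffusers in the
  backscatter configuration is ~8–12 J/cm² per well (peak pixel ~15 J/cm²)
  under the default total-200 mW/cm source reading — of the right order
  but below the 20 J/cm² full-kill threshold that the original experiment
  associated with its measured kill regions. The delivery description is
  internally ambiguous (per-fiber vs total linear power differ by 2×; the
  per-fiber reading doubles these numbers), and the reference simulation's
  anisotropy, refractive indices and boundary conditions are unpublished,
  so only order-of-magnitude agreement is attainable. The corresponding
  acceptance test asserts the >20 J/cm² claim as stated and is expected to
  fail under the default reading; the surrounding physics properties
  (backscatter enhancement, attenuation monotonicity, conservation,
  diffusion agreement) all hold.
- Polarization, fluorescence re-emission, time-resolved transport, oxygen
  depletion and irradiance-rate (reciprocity-failure) effects are out of
  scope.
- Real diffuser fibers have some angular anisotropy; sources here are
  ideal isotropic lines.
- The applicator's bead interconnections and channel cross-sections are
  idealized; silicone optical constants are assumed, not measured.
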