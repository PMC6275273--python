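# Methods

## Transport model and geometry

The culturing channel is modelled as a straight rectangular duct
(1000 μm × 160 μm cross-section, defaults from the device mask design)
flanked by 250 μm microgrooves numbered 1..20 along flow.  The solute
enters from one wall and is carried downstream while diffusing across the
channel.  We use the plug-flow approximation: a uniform mean speed
`v = Q/(w·h)` (208 μm·s⁻¹ at 2 μL·min⁻¹) rather than the parabolic
Poiseuille profile, because the erfc fit already absorbs transverse
dispersion into its spread coefficient β — the fitted model *is* the
effective 1-D description, and the full 3-D hydrodynamics are out of
scope.  Under plug flow the steady state is

    C(x, y) = ½ C₀ erfc((x − x_i) / (2√(D y / v)))

so every cross-section is an erfc profile with α = x_i and
β = 2√(Dy/v).  The finite-difference cross-check marches
`v ∂C/∂y = D ∂²C/∂x²` downstream (forward Euler, central differences)
with the diffusion number fixed at r = 1/6, which cancels the leading
spatial truncation term; at Δx = 2 μm the solver and the closed form agree
to better than 10⁻⁴ of the source level, and the gap shrinks monotonically
under refinement.

Neither the solute diffusivity nor the interface position is identifiable
from the published device description, so both are free parameters:
D defaults to 50 μm²·s⁻¹ (order-of-magnitude literature value for a
~40 kDa dextran) and x_i to 450 μm.  The rendered device image places the
stream junction 5 mm upstream of the imaged area (`inlet_offset_um`), so
per-groove profiles vary mildly (β ≈ 71→119 μm across grooves) as they do
in a developed gradient, instead of changing violently near y = 0.

## Synthetic images and what they do and do not emulate

Gradient images are `flatfield(x,y)·C_norm(x) + N(0, σ_noise)` with a
paired reference image `flatfield + noise`; the flat field is a smooth
mean-1 bowl (amplitude 10%).  Bead z-stacks render each bead as a fixed-σ
2-D Gaussian whose peak decays as `a·e^{bΔz} + c` (defaults 0.645, −0.200,
0.352, the published calibration values); defocus blur is deliberately not
modelled because the calibration consumes only the intensity-decay curve,
not spot shape.  Two-channel cell images hold Gaussian chromosome blobs
(one for metaphase, two separated by 30 px for postmetaphase) and an LRP6
patch displaced 20 px along the gradient axis, with noise set by the
requested SNR (patch amplitude / noise sd).  Time series share one profile
with independent per-frame noise and an optional multiplicative
random-walk drift whose planted ΔC1 series (and its σ) is stored as ground
truth.

None of these emulate real segmentation difficulty, spectral bleed-through,
photobleaching, uneven cell density or 3-D cell shape; passing tests
demonstrate that the *quantification chain* is correct and calibrated, not
that it would be robust to every pathology of real microscopy data.

All generators are pure functions of (parameters, seed).  Child random
streams derive from the master seed via `SeedSequence(seed, spawn_key)`
with one fixed key per dataset type, so each dataset is independently
reproducible.

## Fitting choices

The erfc fit is unweighted nonlinear least squares with all four
coefficients free (plateaus included): freeing the plateaus makes the fit
robust to imperfect normalization.  A constrained mode pinning
C_max/C_min to the observed ROI extremes is provided, since the original
description can be read either way.  Initialization: plateaus from the
95th/5th percentiles, α at the half-range crossing, β as half the 16–84%
span; β is bounded positive; non-convergence returns the best iterate
flagged.  The decay fit initializes c at the minimum intensity, a at
I(0) − c, and b from a log-linear regression of I − c; constant data
returns the b = 0 solution flagged degenerate rather than raising.

ΔC1 is the end-to-end difference `C(x − d/2) − C(x + d/2)` with no extra
factor ½; the halved reading of the garbled published formula is a config
switch (`halved_dc1`), as is the grouping of the ΔC2 scale factor
(`halved_dc2`, default on: `(C_up − C_down)/2 · d/w`).  ΔC2 uses the two
fitted ROIs bracketing the cell's groove channel.  Molar conversion:
`grad = ΔC_norm · C_source[nM] / d` with
`C_source[nM] = (ng/mL · 10⁻⁶ / (kDa · 10³)) · 10⁹` — 100 ng/mL of a
38 kDa ligand is 2.632 nM.

The valid-region rule (include an ROI iff median|ΔC2| ≤ 0.5·median|ΔC1|)
is implemented and tested on constructed fixtures with planted along-flow
differences.  For the end-to-end synthetic demo the pipeline defaults to
the explicit override list 1–15 (the analysed area of the original study):
with uniformly placed cells, most positions sit on the profile plateaus
where both differences are near zero and the fitted-profile noise floor —
not the field — dominates |ΔC2|, so the data-driven medians are not
meaningful there.  Data-driven mode is one config switch away
(`roi_override: null`).

## Statistics

The two-sided exact binomial test uses the point-probability convention:
the p-value sums all outcomes no more likely than the observed one.  At
p₀ = ½ this is computed in exact integer arithmetic (binomial coefficients
against 2ⁿ) and equals twice the smaller tail capped at 1; 39/56 gives
0.004562, printing as 0.0046.  Other p₀ use exact rationals.  No
multiple-testing correction is applied across exposure bins — a deliberate
mirror of the original analysis design, recorded here rather than silently
"fixed".

Equal-count binning stably sorts cells by exposure and cuts groups of
⌊n/k⌋ or ⌈n/k⌉ (remainder to the lowest bins).  Published edge values are
printed without a defining rule, so edges here are data-range boundaries:
the minimum, midpoints between adjacent sorted groups, and the maximum.
The sensitivity threshold is the lower edge of the lowest-exposure bin
whose toward fraction exceeds ½ with p < α (default 0.05); if no bin
qualifies the threshold is undefined.

Angles: 0 points toward the ligand-source wall, −π/2 upstream, wrapped to
(−π, π]; the toward-gradient half-plane is −π/2 ≤ θ < π/2 and the
toward-upstream half-plane −π ≤ θ < 0 (half-open exactly as in the
original convention; θ = π is treated as −π).  Synthetic angles are von
Mises (κ default 2) *conditioned on the chosen half-plane*, so the planted
`p_toward` is exactly the probability of a toward classification.  The
response is a step at the threshold by default (a logistic ramp is a
config option), matching how bin-wise significance is reported.

## The planted threshold and the recovery study

The synthetic device defaults (profile (C_max, C_min, α, β) =
(1, 0, 450 μm, 90 μm), source 30 ng/mL, d = 30 μm) put the maximum
per-cell exposure at ≈ 4.9×10⁻³ nM·μm⁻¹, matching the exposure range of
the original experiments.  The default planted response threshold is
1.0×10⁻³ nM·μm⁻¹.  This value was chosen by a design-stage power analysis
of the four-bin equal-count layout: with uniformly placed cells roughly a
quarter of the cohort lies above 1.0×10⁻³, so the top exposure bin is
nearly pure above-threshold cells and a 70% toward-bias yields ~97% power
per cohort; a threshold placed higher in the exposure range leaves the top
bin diluted with sub-threshold cells and the binned design cannot resolve
it reliably at n = 400.  Recovery is scored as the estimate falling within
one width of the qualifying bin; the study reports ≈ 90–98% success over
50 seeded cohorts, and null cohorts (threshold = ∞) reject at 2–7% over
200 runs, consistent with the exact test's sub-nominal size.

## LRP6 localization

The activated position is the centre of the 11×11 px window with the
highest mean signal over all fully contained placements, computed with an
integral image (exact int64 arithmetic for integer inputs); ties go to the
smallest row-major index.  The cell centre is the intensity-weighted
chromosome centroid (metaphase) or the midpoint of the two chromosome
centroids (postmetaphase).  Side calls take the sign of the displacement
component along the reference axis; an exactly zero component is flagged
indeterminate and excluded from counts rather than randomized
(conservative).  Chromosome masks come from Gaussian smoothing + Otsu +
largest-component selection.

## Calibration

Correction divides each plane by `I(Δz)/I(0)` — a normalized,
multiplicative correction anchored at the reference plane, matching the
relative-intensity framing of the calibration; the reference plane is
unchanged and a b = 0 model is the identity.  z-steps default to 0.1 μm
for calibration stacks and 0.5 μm for cell stacks.  Projection after
correction is maximum-intensity by default with sum-projection available.
The decay fit is unweighted; the number of beads/heights used originally
is unstated, so the simulation study uses 30 heights over 0–20 μm.
Bead intensities are read as 3×3 patch means at the detected positions —
unbiased under noise and consistent across planes, unlike a max-pixel
reading.

## Problem sizes

Default study sizes: 400-cell cohorts (50 recovery runs, 200 null runs),
100-fit recovery studies for profile and decay parameters, 10-frame time
series at three evaluation positions (200/400/600 μm), 200 synthetic LRP6
cells, full-channel images at 2.7 μm/px (370×3704).  These sizes give
percent-level Monte-Carlo precision on every reported rate while keeping a
complete run of the analysis scripts and acceptance script in the
single-digit-minute range on one core.

## Known limitations

- The plug-flow/erfc description ignores Taylor dispersion, the finite
  microgroove geometry and any pre-steady-state loading dynamics.
- The synthetic downstream disturbance (mixing toward the well-mixed
  level) is a stand-in for whatever made downstream channels unusable in
  the real device; it reproduces the *decision structure* (exclude
  downstream ROIs), not the physics.
- σ is evaluated from per-frame erfc fits; at positions far outside the
  graded region ΔC1 is near zero and the stability ratio σ/ΔC1 is
  undefined in practice — evaluation positions should sit on the graded
  part of the profile, as they do in the defaults.
- The exact binomial implementation caps at n = 10⁴ (exact summation);
  larger cohorts are out of scope.
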