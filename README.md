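# wntgrad

Quantitative analysis of how a microfluidic Wnt3a concentration gradient
orients the pole-to-pole axis of mitotic cells.

In a microgroove-fed culturing channel, a ligand diffusing from one wall
forms a steady cross-channel gradient.  Mitotic neuroblastoma-like cells
exposed to that gradient orient the axis running from their dimmer to their
brighter ODF2/cenexin centriole toward the high-concentration side once the
local gradient exceeds a sensitivity threshold.  This package implements
the full quantification chain needed to measure that effect — and, because
no raw imaging data are publicly deposited, a synthetic-data module that
generates every input with known ground truth, so the whole pipeline is
testable end to end.

## What it computes

**Gradient model.** The cross-channel concentration profile is the
one-dimensional diffusion solution

    C(x) = 1/2 (C_max − C_min) erfc((x − α)/β) + C_min

with `x` the distance from the ligand-source wall (μm), `α` the
mid-concentration position and `β = 2√(Dy/v)` the diffusive spread.
Profiles are fitted by nonlinear least squares to flat-field-normalized
fluorescence images (15 μm ROI bands per groove channel); a finite-
difference plug-flow solver provides an independent numerical cross-check.

**Per-cell exposure.**  For a cell of diameter `d` (default 30 μm) at
position `x`, the normalized difference across its ends along the gradient
axis is `ΔC1 = C(x − d/2) − C(x + d/2)`; along the flow axis,
`ΔC2 = (C_up(x) − C_down(x))/2 · d/w` from the two ROI fits bracketing the
cell (`w` = 250 μm microgroove width).  Mass concentrations convert to
molar gradients via the ligand molecular weight (Wnt3a ≈ 38 kDa).
Temporal stability of a gradient is summarized by the fluctuation
statistic `σ = mean |ΔC1_i − median(ΔC1)|` over an image time series.

**Orientation statistics.**  Pole-to-pole angles use the device frame
(0 = toward the source wall, −π/2 = upstream, wrapped to (−π, π]).  Cells
are classified toward/against each reference half-plane and tested with a
two-sided *exact* binomial test at p₀ = 0.5, implemented in exact integer
arithmetic.  Cells are then split into equal-count gradient-exposure bins
(default k = 4); the sensitivity threshold is the lower edge of the
weakest-exposure bin with a significant toward bias.

**Calibration.**  Before quantification, z-stacks are corrected for
objective-height intensity decay, `I(Δz) = a·exp(b·Δz) + c`, fitted on
fluorescent-bead stacks and applied by dividing each plane by its
normalized predicted attenuation.

## Worked example

```bash
python analysis/04_orientation_statistics.py --seed 1
python analysis/05_sensitivity_threshold.py --seed 1
```

prints (seed 1):

```
          all vs gradient: 229/400 (0.57) p=0.0043 *
          all vs upstream: 196/400 (0.49) p=0.7264
    metaphase vs gradient: 122/203 (0.60) p=0.0049 *
...
bin 3: [1.48e-03, 4.90e-03] nM/um  75/100 (0.75) p=0.0000 *
estimated sensitivity threshold: 1.48e-03 nM/um (planted 1.00e-03)
threshold within one bin width of truth in 98% of 50 seeded cohorts
```

Reading: a 400-cell synthetic cohort with a planted step response
(threshold 1.0×10⁻³ nM·μm⁻¹, 70% toward-bias above it) shows a significant
orientation bias toward the gradient (exact binomial p < 0.01) but none
along the flow axis; equal-count binning localizes the planted threshold
to the lower edge of the only significant exposure bin.  As a cross-check
on the test itself, 39 toward-oriented cells out of 56 give p = 0.0046.

The same computations are available as a CLI (`wntgrad simulate`,
`wntgrad calibrate fit/apply`, `wntgrad fit-gradient`, `wntgrad
orientation-test`, `wntgrad bin-sensitivity`, `wntgrad run`, ...) and as a
single orchestrated run:

```bash
wntgrad run --seed 1 --out-dir runs/demo
```

which writes per-stage CSV/JSON outputs, the serialized configuration and
a provenance-stamped report under `runs/demo/`.

## Layout

- `src/wntgrad/` — library: `synthdata`, `calibration`, `gradientfit`,
  `axisstats`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing tables to `results/`
- `tests/` — pytest suite (unit, property and end-to-end checks)
- `docs/methods.md` — model assumptions, parameter choices, limitations
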