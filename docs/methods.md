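# Methods

This note documents the models, parameter choices, and numerical decisions
behind `mdr-hcs`, and what the validation suite does and does not establish.

## Assay model

The pipeline targets a three-channel immunofluorescence readout of 384-well
plates: a nuclear stain defining the total cell count, a cytokeratin 8/18
channel separating carcinoma (epithelial) cells from stromal fibroblasts, and
one MDR-transporter channel (ABCB1, ABCC1 or ABCG2) per plate. Every scored
cell is cross-classified into one of four populations — cancer/stromal ×
marker-positive/negative. Two derived statistics drive all downstream
analysis:

* **viability** of a population in a treated well: its cell count as a
  percentage of the mean count in same-culture vehicle-control wells;
* **percent marker-positive** within a population (not of the well total),
  the induction observable.

A cell is "nuclear-stain positive" by virtue of being segmented; there is no
second nuclear intensity gate. Positivity on the cytoplasmic channels
compares the mean cytoplasmic intensity (cell region minus nucleus) to a
per-channel threshold; ties score positive (deterministic); an integrated
(summed) statistic is available via `intensity_statistic="integrated"`
because vendor protocols are ambiguous on this point. Cells whose region has
no cytoplasmic pixels fall back to the whole-cell mean.

## Segmentation

Global threshold (absolute, or Otsu's between-class-variance maximizer when
set to `"auto"`), hole filling, optional distance-transform watershed to
split touching nuclei, then a size gate keeping objects whose equivalent
diameter (diameter of the equal-area circle — rotation-invariant, and equal
to "width" for round nuclei) lies in `[nucleus_min_width,
nucleus_max_width]`. Border-touching nuclei are removed because their
intensity statistics are truncated. Fully overlapped nuclei are not resolved
and count as one object; this is a known limitation of threshold-based
nuclear segmentation generally.

Cell regions grow from each nucleus by nearest-nucleus Euclidean expansion
(computed with a single distance transform), bounded per nucleus by
`(cell_max_width − d_eq)/2` so that a circular region's equivalent diameter
cannot exceed `cell_max_width`. Regions are disjoint, split contested zones
on the equidistant boundary, and always contain their nucleus. For markedly
non-circular nuclei the equivalent-diameter bound is approximate.

Default widths (nucleus 6–25 µm, cell ≤ 30 µm at 1.7 µm/px) are
**assay-calibration parameters**, chosen to bracket typical NSCLC nuclei
imaged with a 4x objective; they are not universal constants and should be
re-tuned per staining batch, as they would be in any cell-scoring protocol.

## Synthetic plate simulator

The simulator emulates the *statistical* structure of the assay, not its
optics. Per well at dose c:

* surviving count ~ Poisson(`n_cells_mean` · f(c)) per population, with Hill
  survival f(c) = 1/(1 + (c/IC50_kill)^h); `n_cells_mean` defaults to 1000,
  the standard seeding density for this plate format;
* each survivor is marker-positive with p(c) = p0 + (pmax − p0)·c^h/(c^h +
  EC50^h). Induction and selective survival of positive cells are
  *observationally equivalent* in an endpoint assay, so the simulator models
  only the net positive fraction;
* nuclei are placed by a sequential hard-core process (minimum separation
  0.8 × mean nucleus diameter, one-cell-radius border margin) and rendered as
  flat disks; cytoplasm as annuli up to the cell diameter; per-cell
  brightness is lognormal (σ = 0.15) around class means with a 10-fold
  positive/negative separation; Gaussian PSF blur (σ = 1 px), constant
  background, Poisson shot noise and additive Gaussian read noise.

Default field: 2048×2048 px at 1.7 µm/px (a 4x-objective widefield view);
presets use a 512×512 field with ~150 cells so that rendering-based tests
run in seconds while keeping the same densities per area. The mixed-culture
preset uses a 1:1 cancer:stromal ratio, mirroring the standard co-culture
design.

What passing on simulated data does **not** show: robustness to illumination
gradients, focus drift, staining heterogeneity, debris, apoptotic-body
artifacts, or dense clumping beyond the hard-core regime — real images are
harder than these renders, and the segmentation thresholds in particular
must be validated on real data per batch.

## Dose-response

The 4PL `R(c) = bottom + (top − bottom)/(1 + (c/x50)^h)` is fitted on log10
dose by bounded trust-region least squares (bounds: 0 ≤ bottom, top ≤ 120 %,
h ∈ [10⁻³, 10]; x50 within ±4 decades of the panel), initialized from the
data (top = max response, bottom = min, x50 = dose nearest 50 %, h = 1).
Replicates are fitted jointly as individual points, preserving the error
structure. The reported **IC50 is the 50 %-of-control crossing of the
fitted curve**, solved analytically from the 4PL parameters — not the x50
inflection, which equals it only when top + bottom = 100. When the fitted
curve never reaches 50 % within the tested range (or the crossing lies above
the top concentration), the IC50 is right-censored and reported `>c_max`.
Flat series are short-circuited without optimization: flat above 50 % is
censored; flat at/below 50 % is flagged degenerate (IC50 unidentifiable).
Fold-resistance propagates censoring as a lower bound and refuses a censored
denominator; selectivity calls are made only when the censoring intervals
are disjoint.

## Induction statistics

Each (marker, culture, population, drug) series is one Dunnett family:
every treated concentration vs the shared vehicle control, two-sided, pooled
variance across all groups in the family. This matches per-panel
per-concentration significance stars; the family is deliberately *not* the
whole plate (no cross-drug FDR). The multivariate-t tail probability uses
`scipy.stats.dunnett` (randomized QMC, exact unequal-n correlations) with a
caller-supplied generator, reproducible to ~3 decimals at a fixed seed; the
k = 1 family reduces analytically to the pooled two-sample t-test. A
two-factor (population × concentration) ANOVA is available as a diagnostic
for population-dependent dose effects.

The relevance gate defaults to a **relative** ≥ 20 % increase of the
percent-positive statistic over the control mean, switchable to absolute
percentage points (`induction_metric="absolute_points"`, threshold then
interpreted as `100·induction_threshold` points). The relative reading is
the default because the rule is phrased as a proportional change of the
plotted quantity; both are implemented since the phrasing is ambiguous.
"Increase" requires significance *and* relevance at ≥ 1 concentration;
decreases never trigger it. A control mean of 0 % makes the relative metric
undefined and raises with a pointer to the absolute metric.

## Validation design and problem sizes

The Monte-Carlo suites (IC50 recovery, Dunnett calibration, induction
operating characteristics) run on the simulator's counts layer
(`simulate_well_counts`) rather than rendered images: the imaging chain is
not under test there, and the counts layer is the identical population
model. Rendering is exercised by the segmentation/scoring tests (512×512
fields) and the end-to-end determinism check (256×256, ~60 cells/well).
Study sizes: 50 plates for IC50 recovery, 2000 null families for the
Dunnett type-I error, 100 runs for induction power, 20 × 8 null series for
specificity — sizes chosen to give stable estimates in about a minute of
CPU.

The induction power study uses a 30 % baseline positive fraction so that a
30 % relative induction (to 39 %) against a ~1-point per-well SEM at 1000
cells/well is a realistically detectable effect for an n = 4 design; at
much lower baselines the same relative change is within noise, which is a
property of the assay design, not of the implementation.

## Numerical and degenerate-input conventions

* Concentrations are molar internally; µM/nM appear only in formatted
  tables. Well indexing is 0-based row-major (A1 → (0,0)).
* Constant (e.g. fully saturated) nuclear images yield an empty mask with a
  warning; Otsu on a constant image is an error.
* Empty wells yield zero counts with NaN (flagged undefined) percentages;
  wells lacking a population are excluded from that population's induction
  groups with a warning.
* Zero pooled variance in a Dunnett family is flagged degenerate (p = 0 or 1
  by mean difference).
* The four-population counts must sum to the well total; this is enforced as
  a class invariant, so it cannot be silently violated anywhere downstream.
* `analyze` is deterministic at a fixed seed: per-well simulator streams are
  spawned from (plate seed, well index), and the Dunnett QMC generator is
  seeded from the analysis config, so repeated runs produce byte-identical
  tables (the manifest records wall-clock timings and is excluded from that
  guarantee).

## Known limitations

* No illumination-gradient correction beyond constant background; no learned
  segmentation. Heavily overlapping nuclei undercount.
* The 4PL assumes a monotone response; biphasic responses will fit poorly
  (inspect `rss` and the curve plots).
* Exposure time and treatment duration are metadata only; the pipeline does
  not model growth-rate effects on potency metrics.
* The simulator does not render stromal/cancer morphology differences; only
  intensity separates the classes, so classifier difficulty is controlled
  entirely by the intensity model.
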