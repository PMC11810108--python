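# Methods

## Scope and model

`ibscreen` measures punctate inclusion-body (IB) phenotypes in fluorescence
images of yeast-like cells.  The phenotype model is deliberately minimal and
matches how high-content aggregation screens are actually scored:

- a cell's state is its integer IB count;
- the count maps to a class — 0 → no-IB, 1 → Class 1, 2 → Class 2,
  ≥ 3 → Class 3;
- class shares are reported **over inclusion-bearing cells**, while
  *prevalence* (fraction of cells with ≥ 1 IB) uses all counted cells.  Both
  denominators are emitted in every summary so either convention can be
  reconstructed downstream.
- a mutant strain is a screen hit when its replicate Class-3 percentages
  differ from the wild-type reference with Student's pooled-variance
  *t*-test at p ≤ 0.05 (inclusive) **and** the difference of means is at
  least 20 percentage points in the configured direction (default:
  increase).  No multiple-testing correction is applied; at genome scale the
  effect-size gate, not the p-value, controls false positives (with
  replicate SD ≈ 5 points, a 20-point gate is a ≈ 5σ requirement on the
  effect estimate).

## Synthetic data generator

Because no raw screen images are publicly deposited, correctness is
established by planted-parameter recovery: the generator renders fields whose
population statistics are known exactly, and the pipeline must recover them
from pixels.

One field is rendered as follows.  Cells are non-overlapping ellipses (axis
ratio uniform in [1.0, 1.4], orientation uniform, radius Gaussian around the
preset's mean) placed by rejection sampling (≤ 100 retries per cell; an
impossible density raises with the achievable value).  Each cell is
IB-bearing with probability *prevalence*; bearing cells draw a count from the
preset's conditional count law.  IBs are 2-D Gaussian spots (σ = radius/2)
clipped to the owner cell, centres uniform in a shrunk copy of the ellipse
and pairwise separated by at least `ib_min_separation_px` (default 2× the
mean IB radius) so the planted count stays optically resolvable and ground
truth remains a fair oracle.  If a crowded cell cannot host its drawn count,
the surplus is dropped with a warning and the ground truth records what was
actually planted.  The organelle channel renders, for a Bernoulli-selected
fraction of IBs, an annulus at `shell_gap_px` outside the IB boundary with a
270–360° arc (uniform); shell-less IBs leave only background there.  Both
channels are multiplied by a separable quadratic illumination bowl (1 at the
centre, 1 − amplitude at the corners), given additive Gaussian noise, clipped
at zero and quantized to 16 bits.  A single seed feeds a hierarchical
`SeedSequence` stream, so any field is bit-reproducible independent of
generation order.

### Phase presets

Preset count laws are calibrated so their **analytic** class shares and
moments equal the population summaries the study conditions require; the
pipeline's job is to get those numbers back out of the pixels.

| preset | count law (conditional on ≥ 1) | prevalence | pinned statistic |
|---|---|---|---|
| lag | {1: .02, 2: .02, 3–6: .24 each} | 0.90 | Class-3 share 96 % |
| exponential | {1: .25, 2: .25, 3: .20, 4: .15, 5: .10, 6: .05} | 0.90 | Class-3 share 50 % |
| stationary | {1: .50, 2: .28, 3: .12, 4: .07, 5: .03} | 0.85 | Class-1 share 50 % |
| young | 1 + NegBinom, moments 2.64 ± 1.29 | 0.27 | prevalence, mean ± SD |
| old | 1 + NegBinom, moments 4.91 ± 3.32 | 0.61 | prevalence, mean ± SD |

The aging laws are shifted negative binomials solved from the printed
mean ± SD (the young law is nearly shifted-Poisson; the old law is strongly
overdispersed, r ≈ 2.1).  Upper truncation (resampling above 30) keeps counts
placeable; its effect is folded into the analytic pmf.  Young cells are drawn
slightly smaller (radius 11 px) than old cells (15 px), consistent with
generational growth; the time-course presets interpolate the three anchor
laws linearly in probability space.

Default geometry — 1024×1024 px fields with ~150 cells of radius ≈ 12 px and
IB radius ≈ 1.8 px — is a configurable choice of a plausible magnification,
not a claim about any particular instrument.  Default intensities
(background 500, cytoplasm 3000, IB 18000, noise SD 300) give a spot-to-
cytoplasm SNR ≈ 50 and a cytoplasm-to-background contrast of 6×, typical of
a well-exposed constitutively expressed marker.

The screen generator is tabular: per-mutant replicate Class-3 percentages,
normal around 50 % (baseline) or 80 % (planted hits, +30 points), SD 5,
clipped to [0, 100] with a warning.  The wild-type reference pools 48 control
replicates (one control well per ~16-plate round, three rounds), so its mean
is far better determined than any single mutant triplicate — standard
plate-design practice, and what makes exact recovery of a planted 84-hit set
statistically attainable at 5500 mutants.

### What the generator does *not* emulate

No 3-D structure, photobleaching, camera-specific (Poisson/EMCCD) noise,
budding morphology, debris, focus drift, or cell-to-cell expression
variability.  Passing recovery tests therefore demonstrates that the
measurement chain is correct and unbiased under the stated image model; it
does not certify performance on real microscope data, where segmentation
error modes are richer.

## Preprocessing

Per channel and in fixed order:

1. **Shading correction.**  Retrospective single-image flat-fielding: the
   illumination surface is a heavy Gaussian blur of the image itself
   (default scale 64 px ≳ 4× cell radius) computed with normalized
   convolution (dividing by the blurred indicator removes border bias),
   refined by three multiplicative passes (`s ← s · blur(I/s)`) that absorb
   residual low-frequency structure, floored at a tiny positive value and
   normalized to mean 1.  The image is divided by the surface.  No
   calibration frame is required; correction is near-idempotent (< 1 % RMS
   change on re-application).
2. **Background subtraction.**  Grayscale morphological opening by a disk
   (default radius 6 px = 3× mean IB radius), subtracted and clipped at 0.
   A disk larger than any spot but smaller than a cell makes the opening
   cancel the uniform cytoplasm of whole cells exactly, so the residual is a
   spot-enhanced image.

Both products are kept: cells are segmented on the shading-corrected image,
inclusions (and the organelle mask) on the residual.

## Segmentation

**Cells.**  Light Gaussian denoising (σ = 2 px), log transform with a
scale-adaptive offset (`log(I + 10⁻³·mean(I))`, which makes the whole chain
exactly invariant to multiplying the image by a positive constant), Otsu
threshold, hole filling, and a distance-transform watershed whose markers are
h-maxima (h = 2 px) of the smoothed distance map — h-maxima rather than raw
peaks because an elongated ellipse's distance ridge otherwise oversplits,
while genuinely touching cells keep distinct maxima.  A contrast guard
rejects fields where the two Otsu classes are closer than 4 robust
background SDs (on a cell-free field Otsu merely bisects the noise, ~1.6σ
apart).  Objects outside [200, 5000] px² are dropped; labels are relabelled
consecutively in raster order.

**Inclusions.**  Candidate pixels exceed a per-cell robust threshold
(median + 6 × MAD over that cell's residual pixels) and lie on cell
foreground; 4-connected components smaller than 4 px² are dropped; merged
puncta are split by a watershed seeded at local maxima (min distance 1 px on
the σ = 1 smoothed image; any plateau component without a peak gets its
brightest pixel as seed).

**Mask combination.**  Each inclusion is assigned to the cell covering the
majority of its pixels; ties break toward the smaller cell label
(deterministic); majority-on-background inclusions get owner 0 and are
reported but excluded from counts.  Assignment never creates or destroys
labels (conservation is asserted in tests).  Cells touching the field border
are flagged and excluded from summaries, since their IB complement may be
truncated.

## Encirclement score

The organelle channel is binarized by Otsu on the preprocessed residual with
a robust floor (background median + 6 × MAD) so a near-empty channel cannot
yield a noise mask.  An inclusion's score is the fraction of its perimeter
pixels (mask minus 4-connected erosion; a 1-px inclusion uses the pixel
itself) whose Euclidean distance to the nearest organelle-positive pixel is
≤ 3 px; *surrounded* means score ≥ 0.5.  The probe distance and threshold
are declared operationalizations of a judgement originally made by eye —
results are reported with the parameters so alternative thresholds are
reconstructable.  The score is monotone in probe distance and, operating on
masks, invariant to intensity rescaling of either channel.

## Statistical choices

- Pooled-variance Student's *t* (not Welch), matching the equal-n triplicate
  design; Welch would be the choice under variance heterogeneity and can be
  obtained by passing per-group values to scipy directly.
- Degenerate-variance limits are defined rather than left NaN: equal means
  give t = 0, p = 1; unequal means give p = 0 with a warning.
- p ≤ α is inclusive.
- Cohort and per-class comparisons use the field as the biological
  replicate (per-field summary values), not per-cell values; per-cell
  testing would overstate n by two orders of magnitude.
- Effect sizes are percentage *points* (0–100), i.e. the absolute difference
  of percentages, not a relative change.

## Problem sizes

The standing studies use 20 fields (~150 cells each) per culture phase,
500-cell cohorts per aging arm, ten replicate 5500-mutant screens, and ten
two-channel association fields — sizes chosen so every planted statistic is
estimated with a sampling SE several times smaller than its stated recovery
tolerance while a full run stays in the minutes range on one CPU.

## Known limitations

- Segmentation parameters are tuned for the synthetic image model's scale;
  real data would need the area bounds and smoothing scales revisited.
- The per-cell MAD threshold assumes inclusions occupy a minority of each
  cell's area; a cell that is mostly aggregate would inflate its own
  threshold and undercount.
- Encirclement is 2-D; a shell out of the focal plane is invisible to it.
- The screen generator draws replicate noise i.i.d. normal; plate effects,
  batch structure and count-based (binomial) noise at low cell numbers are
  not modelled.
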