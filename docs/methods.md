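# Methods

## Morphometry pipeline

The pipeline quantifies endocrine cell masses on dual-stained pancreas
sections: insulin marks beta cells in the green channel, somatostatin marks
delta cells in the red channel, and an optional blue (nuclear) channel is
carried but unused. Islet outlines are an input — hand-drawn perimeter
masks exported pixel-aligned to the section — because automated islet
detection is a different problem with different failure modes.

### Color correction

Slide-scanner exports carry a shared background offset and spectral
bleed-through between the red and green fluorophores. Both are removed by
mutual subtraction: `red' = max(red − green, 0)`, `green' = max(green −
red, 0)`, with both differences taken from the *original* arrays. The
directional phrasing "subtracting one from the other" admits a sequential
reading (overwrite one channel, then correct the other); the symmetric form
is used because only it leaves *both* channels containing just their own
signal, and it is the variant under which the separable-recovery guarantee
below holds. With equal background b in both channels, any pixel's
corrected value is exactly its channel-specific signal excess, so a flat
background cancels identically.

### Per-islet thresholding

Each islet region is segmented against its own intensity statistics: the
region's corrected pixels are histogrammed into 256 equal-width bins
spanning the region's min–max range (so behavior is invariant to bit depth
and to intensity shifts), and a single split of the histogram is chosen:

- **Insulin (green): Otsu's criterion.** Maximize the between-class
  variance σ²_B(t) = ω₀(t)ω₁(t)[μ₀(t) − μ₁(t)]², computed from bin centers.
  By the law of total variance this equals total minus within-class
  variance, which the test suite verifies to 1e-9 relative at every split.
- **Somatostatin (red): Kapur's criterion.** Maximize H₀(t) + H₁(t), the
  summed Shannon entropies of the two classes' renormalized bin
  probabilities, natural log, with 0·ln 0 := 0 and splits that leave a
  class empty excluded. (This criterion is sometimes loosely described as
  entropy *minimization*; the standard formulation, implemented here, is
  maximization of the summed class entropies.)

Conventions that change areas and are therefore fixed explicitly:

- The returned threshold is the **upper edge** of the last class-0 bin;
  foreground is **strictly greater** than that edge.
- Ties break to the **smallest** split (the more sensitive, larger
  foreground). Splits that differ only by trailing empty bins induce the
  same partition; the smallest-t representative is returned, so ranking is
  immune to floating-point rounding of mathematically tied objectives.
- A region whose channel is constant has no valid split: the threshold is
  null, the hormone-positive area is zero, and a degenerate flag is
  emitted. There is deliberately no fallback to a global threshold, since a
  global threshold is exactly what per-islet segmentation avoids.

Implementation is vectorized over cumulative sums; the test suite compares
it exhaustively (brute force over all splits) on 1,000 random histograms
with 8–256 bins and masses 10–10⁵, and cross-checks Otsu against
scikit-image with matched binning.

### Measurement and aggregation

Areas are pixel counts × (pixel size)², default 0.65 µm/px. The islet
diameter is the equivalent-circle diameter d = 2√(A/π) — deterministic and
orientation-free where a Feret diameter would depend on orientation
conventions. Islets are "small" when d < 100 µm, strict: d = 100 µm is
large. The cutoff is configurable.

Per-animal summaries pool all sections: the beta-cell percentage is
100·Σ insulin-positive area / Σ islet area (area-weighted), *not* the mean
of per-islet percentages — the two differ whenever islet sizes vary.
Mask regions must be disjoint; labeled masks whose labels are fragmented or
overlapping are rejected. Islets touching the image border are measured and
flagged (`touches_border`) rather than silently excluded, since no
exclusion rule is part of the protocol; users can filter on the flag.
Connected components use 8-connectivity by default (diagonal-touching
pixels are one islet, the common morphometry convention), with labels
assigned in raster-scan order of first pixels so outputs are reproducible.
Section spacing (250 µm between sections of a series) is carried as
metadata only; no stereological volume extrapolation is attempted.

## Assay normalizations

- **Fold over basal**: sample ÷ mean of the basal group; basal samples thus
  average to 1. Scale-invariant by construction.
- **Stimulation index**: 100·secreted/(secreted + residual content). The
  "total content" denominator includes the secreted fraction — the most
  literal reading of expressing secretion as a percentage of *total*
  hormone; the alternative 100·secreted/lysate is available as
  `mode="lysate"`.
- **ΔCt**: replicate Ct values are averaged *before* subtraction of the
  reference gene; relative expression is 2^(−ΔCt) and halves exactly per
  +1 cycle. A percent-of-control helper divides relative expressions.
- **Ca²⁺ delta ratio**: ratio_t = F340_t/F380_t on background-corrected
  traces (2 s sampling, 13 µm square ROIs as defaults carried in the trace
  object); delta ratio = mean over a response window − mean over a baseline
  window. The mean-based (not peak-based) summary is used. F380 must be
  strictly positive within the windows.
- **Dose–response**: four-parameter logistic
  r(d) = bottom + (top − bottom)/(1 + (EC50/d)^hill), least-squares fitted
  in log₁₀(EC50) with scipy's Levenberg–Marquardt; the bottom can be fixed
  at 1 when responses are on the fold-over-basal scale. The EC50 standard
  error comes from the covariance of log₁₀(EC50) via the delta method.
  `converged` reports whether optimization produced a finite positive EC50
  (constant responses short-circuit to a non-converged result), and
  `extrapolated` flags an EC50 outside the dose support.

**Known limitation.** The 4PL's top and EC50 are jointly weakly identified
when the dose range does not approach the upper plateau; with noisy data
the global least-squares optimum can then sit at a shallow-hill,
far-extrapolated EC50. The fit reports such solutions honestly (huge SE,
`extrapolated=True`) rather than constraining them away. Calibration
claims are therefore made for a bracketing design — 8 log-spaced doses from
10 µM to 30 mM, more than a decade either side of the 950 µM truth, 4
replicates, noise σ 0.1 fold units — under which 200 simulations show
mean EC50 bias ≈ 2% and ≈ 90–96% coverage of EC50 ± 1.96·SE (both
recomputed, not asserted, by the suite and `scripts/acceptance.py`).

Group-comparison statistics (two-tailed t test, one-way ANOVA, Holm–Šídák
multiple t tests) are thin pass-throughs to scipy/statsmodels, selected to
mirror common figure-legend usage; nothing is re-derived.

## Synthetic data generator

The generator emulates exactly the features the pipeline makes decisions
about, with known ground truth:

- **Geometry**: non-overlapping disk islets (rejection-sampled with a 3 px
  gap, bounded at 10,000 attempts), log-normal diameters (median 80 µm,
  σ_log 0.35 — spanning the 100 µm size-class boundary), a concentric
  interior insulin-positive disk covering 60% of islet area (typical of
  mouse islets), and peripheral somatostatin-positive blobs (radius 5 µm,
  8 per islet), mirroring the delta cells' peripheral location. Disks are
  idealized, but give exact pixel-count areas for oracle tests.
- **Optics**: observed_red = true_red + α·true_green + background + noise
  (and symmetrically for green), quantized to 16-bit integers. Defaults:
  background 20, hormone levels 180 above background, Gaussian noise σ 10
  (SNR ≈ 16, a well-exposed scan; scanner images at this scale are far from
  shot-noise-limited, and additive Gaussian noise keeps variance
  interpretable), bleed-through α 0.1.
- **Bookkeeping**: per-islet beta fractions and size-class counts are
  recomputed from the emitted rasterized masks, so ground truth is exact by
  construction, not approximated from the continuous geometry.
- **Assay tables**: log-normal secretion samples parameterized by their
  mean and CV around stated group means (defaults anchored at a basal of
  1.9 ng/ml and a 2.7-fold stimulated mean of 5.13 ng/ml); hormone content
  is generated jointly as content = secreted·(100/idx − 1) so each sample's
  stimulation index equals a stated truth exactly. Dose–response responses
  are 4PL plus Gaussian noise; Ca²⁺ traces carry a ratio step of known
  amplitude.

All randomness flows from one explicit integer seed through a single
`numpy.random.Generator`; identical parameters and seed reproduce every
output bit-for-bit.

What the generator does *not* emulate — PSF blur, uneven illumination,
autofluorescence texture, irregular islet shapes, touching islets —
bounds what passing tests show: they validate the algorithmic chain
(correction → per-region thresholding → morphometry → pooling) under
controlled violations (noise, bleed-through), not robustness to every
artifact of real microscopy. On real slides the hand-drawn masks and
staining quality remain the dominant error sources.

## Problem sizes and numerical choices

Recovery tests use 768×768 px sections (≈ 0.5×0.5 mm at 0.65 µm/px) with
five islets, 20 seeds for the noisy-recovery check, 1,000 histograms for
oracle equivalence, and 200 simulations for EC50 calibration — sizes chosen
so the full suite exercises every claim in well under a minute per
property. Determinism is asserted at the byte level on the pipeline's file
outputs (TIFF, CSV, JSON with fixed float formatting and sorted keys).
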