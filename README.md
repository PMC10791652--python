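# isletquant

Semiautomated quantification of pancreatic endocrine cell masses from
dual-channel immunofluorescence sections, together with the standard
normalizations used in islet physiology (hormone secretion, qPCR, fura-2
Ca²⁺ imaging, dose–response).

The package is aimed at labs that stain pancreas sections for insulin
(green) and somatostatin (red), hand-draw islet perimeters, and want
reproducible per-islet and per-animal morphometry: islet counts, islet
areas, beta-/delta-cell area percentages and islet size classes. Because
validating such a pipeline on real slides is hard, a seeded synthetic-data
generator renders sections with known ground truth, and the test suite
demonstrates exact recovery in the separable regime and bounded error under
realistic noise and spectral bleed-through.

## Method

For each section the red and green channels are mutually color-corrected by
subtracting each from the other (both differences taken from the original
arrays, clamped at zero), which cancels the shared background offset and
spectral cross-talk. Islet regions come from a pixel-aligned perimeter mask;
binary masks are split into 8-connected components labeled in raster-scan
order. **Per islet region**, intensities are histogrammed into 256
equal-width bins over the region's own min–max range, and:

- the insulin channel is thresholded with **Otsu's criterion** — choose the
  split t maximizing the between-class variance
  σ²_B(t) = ω₀ω₁(μ₀ − μ₁)²;
- the somatostatin channel is thresholded with **Kapur's criterion** —
  choose the split maximizing the summed class entropies H₀(t) + H₁(t),
  H_c = −Σᵢ (pᵢ/P_c) ln(pᵢ/P_c).

Hormone-positive foreground is every pixel strictly above the winning bin's
upper edge; ties break to the smallest split. Pixel counts convert to µm²
via the pixel size (default 0.65 µm/px); the islet diameter is the
equivalent-circle diameter d = 2√(A/π), and islets with d < 100 µm are
classed "small" (strict inequality). Per-animal beta-cell percentage is the
pooled, area-weighted ratio 100·Σ insulin-area / Σ islet-area.

Assay helpers implement fold over basal (sample / basal-group mean), the
stimulation index 100·secreted/(secreted + residual content), ΔCt relative
expression 2^(−ΔCt), background-corrected F340/F380 delta ratios, and a
four-parameter logistic fit
r(d) = bottom + (top − bottom)/(1 + (EC50/d)^hill)
with a delta-method standard error for the EC50.

## Worked example

```sh
python analysis/01_simulate_sections.py
python analysis/02_measure_morphometry.py
python analysis/03_assay_normalizations.py
python analysis/04_dose_response.py
```

Step 01 renders three synthetic sections (five islets each, beta cells 60%
of islet area, noise σ 10, bleed-through 0.1) under `scratch/`; step 02
measures them:

```
measured 15 islets (truth: 15)
pooled beta-cell area: 59.99% (per-section truths: 60.00%, 60.02%, 59.96%)
size classes: 13 small (<100 um), 2 large
mean islet area: 5801 um^2
```

i.e. the pipeline recovers every islet and the pooled beta-cell percentage
to within a few hundredths of a point of truth. Step 03 normalizes a
synthetic secretion table generated around a basal of 1.9 ng/ml and a
stimulated mean of 5.13 ng/ml (a true 2.7-fold effect):

```
basal: 1.96 ng/ml, fold 1.00, index 10.0% of total content
p116_2mM: 5.08 ng/ml, fold 2.59, index 10.0% of total content
```

Step 04 fits dose–response data simulated from bottom 1, top 2.7-fold,
EC50 950 µM, hill 1:

```
noise-free fit: EC50 950.0 uM, hill 1.000, bottom 1.000, top 2.700
200 noisy fits: mean EC50 972 uM (bias +2.3%), mean SE 129 uM, coverage 90.0%
```

The same functionality is scriptable through the `isletquant` CLI
(`simulate`, `measure`, `assay` subcommands driven by a YAML config; every
run writes a manifest echoing all parameters, and identical config + seed
give byte-identical outputs).

## Layout

- `src/isletquant/` — the library: `image_io`, `segmentation`,
  `morphometry`, `assays`, `synthetic`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers (the worked example above).
- `tests/` — pytest suite, including exhaustive-search threshold oracles.
- `docs/methods.md` — model, conventions, parameter choices, limitations.
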