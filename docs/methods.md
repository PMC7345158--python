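# Methods

## Scope and model

`chemotex` quantifies the optical texture of confluent cell monolayers and
scores how "resistant-like" a group of images is. The chain is:

1. grayscale image → quantize to G gray levels → non-overlapping square
   patches (`image_io`);
2. patch → gray-level co-occurrence matrix (GLCM) at offset (d, θ) → four
   Haralick features: contrast, energy, homogeneity, entropy (`glcm`);
3. feature-vs-distance sweep to locate the cell-scale inflection and
   justify the working offset (`sweep`);
4. Taguchi signal-to-noise fusion of the four features into one composite
   score per group or per image (`snr`);
5. one-way ANOVA group comparison with significance stars (`group_stats`).

The package takes no position on mechanism (EMT, piling, scattering
physics); it measures the image statistics those morphologies produce.

## GLCM conventions

* **Offset.** Distance d ≥ 1 px; angle ∈ {0°, 45°, 90°, 135°} with 0°
  pointing right along a row and 90° up a column. Default (10, 0°): 10 px
  sits at the lower edge of the 10–20 px cell-diameter band, where the
  distance sweep puts the feature inflection.
* **Symmetry.** Pairs are counted in both directions by default
  (`symmetric=True`), the common GLCM practice; asymmetric counting is
  retained for exactness experiments. All documented results use the
  symmetric form.
* **Normalization.** Counts are divided by the realized pair count, which
  shrinks as d grows — never by a fixed constant — so ΣC = 1 at every
  distance and features remain comparable across the sweep.
* **Entropy base.** Base 2 (bits) by default, configurable to natural log.
  The choice rescales entropy by ln 2 and shifts the larger-is-better S/N
  component accordingly; comparisons between groups are unaffected because
  both groups move together.
* **Quantization.** Fixed bit-depth rescaling `floor(p·G / levels_native)`,
  not per-image min–max, so absolute brightness differences between groups
  survive. Quantizing to the image's current level count is a no-op, which
  makes the operation idempotent.

## Patch extraction

The 150 × 150 px patch convention matches the acquisition setup the
pipeline was designed around (1392 × 1040 px frames, ~10–20 px cells).
Tiling is a deterministic top-left-anchored grid with no overlap: a
1392 × 1040 frame yields 9 × 6 = 54 patches. A foreground filter drops
blank tiles: the modal gray level of the frame estimates the background
(the culture protocol leaves a deliberately clear region), a pixel is
foreground when it differs from the mode by more than 5 gray levels, and a
tile needs a foreground fraction ≥ 0.2 by default. The synthetic study
uses a fully confluent canvas, so its pipeline configuration sets the
minimum fraction to 0 and keeps every tile.

## Inflection detection

The sweep records mean ± sd of each feature over patches at each distance
(default d = 1…40, unit steps, covering the cell scale with margin). The
inflection rule: smooth the mean curve with a 3-point moving average
(endpoints unsmoothed), take the discrete second difference, and scan from
small d; the first sign change wins. An exact zero flanked by opposite
signs reports the zero's own distance; a strict flip reports the later
distance. Curves with no curvature sign change (e.g. linear) have no
inflection — the distance of steepest slope is returned with a
`found=False` flag rather than a fabricated inflection.

Caveat observed while validating: at distances approaching the patch side,
the shrinking pair count biases the plug-in entropy/energy estimates
(≈ K/(2N ln 2) for K occupied cells and N pairs) even for white noise.
This is an estimator artifact, not spatial structure; sweeps should keep
d well below the patch side, as the defaults do (40 ≪ 150).

## Taguchi S/N combiner

Energy and homogeneity enter as smaller-is-better, contrast and entropy as
larger-is-better. How four features × n patches reduce to one group score
is a convention; the default **pooled** combiner evaluates

* larger-is-better S/N on the pooled multiset {contrastᵢ} ∪ {entropyᵢ},
* smaller-is-better S/N on {energyᵢ} ∪ {homogeneityᵢ},

and averages the two components in dB. This convention was chosen because,
applied to published group-mean feature values for a serous
ovarian-carcinoma line (contrast 0.54·10³/0.53·10³, entropy 6.36/7.70,
energy 3.80·10⁻³/0.83·10⁻³, homogeneity 1.99·10⁻¹/0.99·10⁻¹ for
wild-type/resistant), it reproduces the corresponding published group S/N
scores to within 0.2 dB (18.06 vs 17.93; 21.92 vs 21.76) — closer than the
alternatives tried. Exact reproduction is impossible without the
underlying per-image data, so this is a convention diagnostic, not a
validation. The raw (unrescaled) feature values enter the formulas; the
pooled form is dominated by each pool's smallest-magnitude members
(entropy on the larger side, homogeneity on the smaller side), which is
what makes the combination scale-stable. An alternative combiner — the
mean of four per-feature S/N values — is selectable (`combiner=
"per_feature"`).

Patches with non-positive values (a constant patch has contrast = entropy
= 0) cannot enter a logarithm; their offending values are dropped and the
affected patch count is reported on the result.

Group dispersion on the composite score is a leave-one-patch-out jackknife
standard error. Significance testing uses per-image combined scores (each
image's own patches pooled), so the ANOVA's exchangeable unit is the
image, not the patch.

## Statistics

Classic equal-variance one-way ANOVA (`scipy.stats.f_oneway`); for two
groups F = t² of the pooled-variance t-test, which the suite verifies.
Stars: \* p < 0.05, \*\* p < 0.01, \*\*\* p < 0.001. P values are reported
raw, without multiple-testing correction, matching the reporting
convention of the tables this layout follows; with only five quantities
per pair the worst-case inflation is modest, but users comparing many
groups should correct downstream.

## Synthetic monolayer generator

What it emulates — and what it does not. Each image is:

1. `n_cells` disks, centers uniform (overlap allowed, later cells
   overwrite earlier, as in a piling layer), radii uniform in 5–10 px so
   diameters span 10–20 px; density 0.0075 cells/px² oversamples the
   canvas ~1.4× for confluence;
2. disk interiors at `interior_level`, modulated by a multiplicative
   speckle field (low-pass-filtered unit-variance Gaussian noise,
   correlation length `speckle_scale` = 3 px — finer than a cell, placing
   the entropy inflection at the cell scale) with strength
   `roughness_amplitude` in gray levels;
3. a 2-px rim annulus brightened by `halo_gain` (the scattering/defocus
   margin heuristic);
4. Gaussian blur of `edge_softness` px, additive sensor noise `noise_sd`,
   clip to 8 bits.

Presets (gray levels on the 8-bit scale):

| parameter | wild type | resistant | why it differs |
|---|---|---|---|
| roughness_amplitude | 6 | 35 | rough 3-D interiors |
| halo_gain | 8 | 55 | scattering margins |
| edge_softness (px) | 1.2 | 0.6 | resistant margins stay sharp |
| noise_sd | 2 | 4 | higher scatter at the sensor |
| interior_level | 150 | 140 | slight absorbance of piled layers |
| background_level | 205 | 205 | shared illumination |

The presets were calibrated once so that, at offset (10, 0°), the group
means show the resistant signature in all four features; the first
parameter set written down already did, with large margins, and was
frozen. Per-image seeds derive from (master seed, group index, image
index) through a SplitMix64-style mix, so either group regenerates
independently, bit for bit.

**Not modeled:** real optics (no point-spread function, no defocus beyond
the rim heuristic), cell shape (no ellipticity, no packing interactions),
illumination gradients, debris, or line-to-line morphology differences.
Consequently, passing tests show the *pipeline* recovers a resistant-type
texture signature when one is present at the cell scale; they do not show
the signature's effect size in real cultures, which must be established on
real images per cell line.

## Problem sizes and numerical choices

The documented study runs 20 images per phenotype at 300 × 300 px (four
150 × 150 patches per image, 160 patches total) — enough for per-image
ANOVA with 38 degrees of freedom while keeping a full pipeline run under a
few seconds; the generator's default canvas for exported datasets is the
full 1392 × 1040 frame. GLCM accumulation is exact integer counting
(`numpy.bincount`); features are evaluated in double precision; the
0·log 0 = 0 convention handles empty cells. Degenerate inputs fail loudly:
offsets leaving no valid pairs, empty value lists, non-positive S/N
inputs, zero-variance ANOVA, and single-group comparisons all raise.

## Known limitations

* The composite score's absolute value depends on the feature units and
  the combiner convention; only within-convention comparisons are
  meaningful.
* The inflection rule is a fixed heuristic (3-point smoothing, first sign
  change); heavily oscillating curves may need wider smoothing.
* The foreground filter assumes the background is the modal gray level,
  which fails on images with no blank region and a dominant uniform
  foreground.
* RGB input is a Rec. 601 luminance convenience; quantitative work should
  start from the camera's native monochrome data.
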