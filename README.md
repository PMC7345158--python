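# chemotex

Texture-based optical identification of chemoresistant cell monolayers.

## The problem

Cisplatin-resistant ovarian-carcinoma cells are hard to tell from their
drug-sensitive (wild-type) parents under a plain bright-field microscope:
the individual cells look almost identical. At confluence, however,
resistant lines pile into rough, three-dimensional layers that scatter
light, drift out of a single focal plane and show enhanced cell margins.
Those are *texture* differences, and they are quantifiable. `chemotex`
implements the full quantification pipeline for anyone who can culture a
monolayer and photograph it: image in, chemoresistance score out — no
staining, no sequencing, no drug-challenge assay.

## The method

**GLCM texture features.** A grayscale patch (150 × 150 px at G = 256 gray
levels by convention) is summarized by its gray-level co-occurrence matrix
C(i, j): the probability that gray levels i and j co-occur at a fixed
displacement (distance d, angle θ). Four Haralick statistics describe it:

    contrast    = Σᵢⱼ C(i,j) (i − j)²
    energy      = Σᵢⱼ C(i,j)²
    homogeneity = Σᵢⱼ C(i,j) / (1 + |i − j|)
    entropy     = −Σᵢⱼ C(i,j) log₂ C(i,j)

Rough, scattering, resistant-type layers have **higher contrast and
entropy** and **lower energy and homogeneity** than flat wild-type layers.

**Working offset.** Feature-vs-distance curves inflect where d approaches
the dominant object scale — the 10–20 px cell diameter — so the working
offset is (d = 10, θ = 0°). `chemotex.sweep` computes the curves and finds
the inflection rather than taking the scale on faith.

**Taguchi S/N composite score.** The four features are fused with the
quality-engineering signal-to-noise ratios

    smaller-is-better: S/N = −10 log₁₀( (1/n) Σ yᵢ² )      (energy, homogeneity)
    larger-is-better:  S/N = −10 log₁₀( (1/n) Σ 1/yᵢ² )    (contrast, entropy)

pooling the larger-is-better feature values into one evaluation, the
smaller-is-better values into another, and averaging the two (in dB). A
higher combined S/N means "more resistant-like". Groups are compared
feature-by-feature and by per-image S/N with one-way ANOVA
(\*\*\* p < 0.001, \*\* p < 0.01, \* p < 0.05).

**Synthetic ground truth.** Real resistant/wild-type image pairs are not
distributable, so `chemotex.synth` renders seeded synthetic monolayers —
overlapping disks with speckled interiors, scattering rim halos, blur and
sensor noise — in two presets whose only differences are the optical
signatures above. Every pipeline stage is testable end-to-end from a seed.

## Worked example

The numbered scripts under `analysis/` run the whole study (the CLI
`chemotex simulate/features/sweep/score/compare` exposes the same steps
for your own images):

```
python analysis/01_simulate.py        # 20 + 20 synthetic images, seed 1
python analysis/02_texture_features.py
python analysis/03_distance_sweep.py
python analysis/04_snr_comparison.py
```

which prints, among other output:

```
Group means at offset (10, 0):
          contrast    entropy    energy  homogeneity
CP     2895.308660  13.534358  0.000143     0.076638
WT      685.672976  11.409537  0.000574     0.142563

WT: entropy inflection at d = 17
CP: entropy inflection at d = 19

group  n_patches  snr_combined   snr_sd
   WT         80     22.036279 0.028186
   CP         80     25.469635 0.037626

snr_combined  22.04 ± 0.0282   25.47 ± 0.0376   2.54e-48  ***
```

Reading it: the resistant-like group (CP) shows the full four-feature
signature (≈4× the contrast, +2.1 bits of entropy, ¼ the energy, half the
homogeneity), both groups' entropy curves inflect at the cell scale
(validating d = 10), and the combined S/N separates the groups by ≈3.4 dB
— overwhelmingly significant (ANOVA on per-image scores, p ≈ 2.5 × 10⁻⁴⁸).

## Layout

- `src/chemotex/` — library: `image_io`, `glcm`, `sweep`, `snr`,
  `group_stats`, `synth`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing tables to `results/`
- `tests/` — unit, property (hypothesis) and end-to-end suites
- `docs/methods.md` — model, parameter and design documentation
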