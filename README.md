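# matsig — material-attribute rating analysis

`matsig` is an analysis pipeline for crowdsourced *material attribute* rating
experiments in visual perception: observers judge depicted materials (wood,
metal, skin, …) on perceptual attributes (glossiness, hardness, hairiness, …)
with a 0–100 slider, and the analysis asks how consistent the observers are,
what the characteristic *signature* of each material class is, and how the
attribute space is structured.

The study layout it implements: **15 materials × 30 painting segments = 450
stimuli**, split into 5 balanced sets of 90; **10 attributes**; each
set × attribute cell rated by **10 raters** over **3 shuffled repetitions**
(270 trials per task, 135,000 judgments in all). Because no human ratings
are released with such studies, the package includes a first-class synthetic
observer model that generates rating tables with the statistical structure
the analysis assumes — per-material signatures, per-stimulus deviations,
stable rater idiosyncrasy, repetition noise, and sub-second "spammer" tasks —
so every downstream stage is testable end to end.

## What it computes

- **Quality control** (`matsig.qc`): per-task exclusion of raters with mean
  response time < 1 s; intra-observer correlation (mean Pearson *r* between a
  rater's repetition vectors) and inter-observer correlation (mean *r*
  between raters' repetition-averaged vectors) for each set × attribute cell;
  critical *r* lines via `r = t / sqrt(t² + df)`.
- **Signatures** (`matsig.signatures`): stimulus-mean and material × attribute
  mean tables; attribute–attribute and image-statistic–attribute Pearson
  matrices with Bonferroni-tiered stars (base α 0.05 / 0.005 / 0.0005 divided
  by the 45 attribute pairs or 40 statistic × attribute tests); Wilcoxon
  signed-rank comparison of two signature tables on shared cells.
- **Image statistics** (`matsig.imstats`): Michelson contrast
  `(P95 − P5)/(P95 + P5)` of segment luminance, luminance skewness (g1),
  colorfulness as the occupied-voxel ratio in a 16×16×16 RGB cube, and mean
  luminance — all over the segment mask only.
- **Stimulus preparation** (`matsig.stimprep`): the square *context box*
  around a segment, side = round(1.25 × max(width, height)), with
  out-of-painting overflow filled by the clipped-box mean RGB.
- **Attribute-space structure** (`matsig.structure`): global (450 × 10) and
  per-material (30 × 10) PCA; the *genericity* analysis, which maps each
  material's two-component scores onto its rows of the global score space by
  full Procrustes superimposition (translation, scale, rotation/reflection)
  and reports the standardized residual disparity, against a Monte-Carlo
  baseline of uniform-random 30-point configurations (≈ 0.95 at n = 30).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic data
and write their tables under `results/`:

```
python analysis/01_simulate.py
python analysis/02_quality_control.py
python analysis/03_signatures.py
python analysis/04_attribute_space.py
python analysis/05_image_statistics.py
```

Output of a run (seed 1):

```
calibrated truth: sigma_taste=10.60, sigma_noise=8.76; expected intra r=0.760, inter r=0.480
excluded 22 of 500 tasks for mean response time < 1 s (5940 records)
consistency over 50 cells: mean intra r = 0.759 (SD 0.059), mean inter r = 0.480 (SD 0.153)
critical r (one-sided 5%, df=88): 0.174
critical r (one-sided 5%, df=8): 0.549
explained variance: PC1-1 34%, PC1-2 51%, PC1-3 66%, PC1-4 74%, PC1-5 81%
grand-mean random baseline: 0.9488
most generic material: metal (residual 0.049); least generic: food (residual 0.558)
```

Reading this: raters agree with themselves (intra 0.76) far more than with
each other (inter 0.48) — stable personal "taste" rather than pure noise;
every cell's consistency clears the one-sided 5% significance lines; the
first two principal components carry about half the attribute variance; and
every material's internal structure maps onto the global attribute space far
better (residuals 0.05–0.56) than uniform random noise does (0.949),
i.e. all materials are to some degree "generic".

The same stages are available as a CLI
(`matsig simulate|stats|consistency|signatures|correlate|pca|genericity|run`)
for external rating CSVs with columns
`rater_id,stimulus_id,attribute,set_id,repetition,value,response_time_s`.

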