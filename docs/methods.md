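# Methods

## Study design

The design object fixes the combinatorial layout: `M = 15` material classes,
`A = 10` perceptual attributes, `S = 30` segments per material partitioned
into `K = 5` balanced sets (6 per material per set, stratified random
assignment from a single integer seed), `R = 10` raters per set × attribute
cell, `P = 3` repetitions per task, slider range 0–100. All printed counts
follow: 450 stimuli, 50 cells, 270 trials per task, 500 tasks, 135,000
judgments; with a pool of 198 participants, 500 tasks average ≈ 2.5 per
participant. Trial order within a task concatenates three Fisher–Yates
permutations of the set, so no stimulus repeats within a block.

Material and attribute labels are stored lowercase in a fixed order, which
gives stable row/column ordering in every matrix output.

## Synthetic observer model

A rating of stimulus *i* (material *m(i)*) on attribute *a* by rater *o* at
repetition *t* is

```
value = clip( mu[m(i),a] + delta[i,a] + gamma[o,i,a] + eps[o,i,a,t], 0, 100 )
```

- `mu` — the material × attribute signature matrix (rating units).
- `delta` — per-stimulus deviation, drawn once per stimulus from a 10 × 10
  covariance `stim_cov`. The covariance is anisotropic by default: real
  within-material variation shares the attribute correlations of the
  between-material variation (a harder-looking segment also looks less
  bendable), and an isotropic `sigma_stim² · I` remains available as a
  special case. This choice also makes the material-specific PCA axes
  meaningful rather than pure sampling noise, which is what the genericity
  analysis measures.
- `gamma` — rater × stimulus idiosyncrasy ("taste"), SD `sigma_taste`, fixed
  across repetitions. This is the term that separates intra- from
  inter-observer agreement.
- `eps` — fresh repetition noise, SD `sigma_noise`.

Out-of-range draws are **clipped**, not resampled — a bounded slider pins at
its ends. The analytic consistency formulas below ignore clipping; default
signatures are kept mid-scale (clipped to [12, 88]) so the bias is small
(observed ≲ 0.005 on recovered correlations).

Spammer behaviour is modelled per task: with probability 0.05 a task emits
i.i.d. uniform ratings on [0, 100] with lognormal response times of mean
0.5 s; honest tasks use mean 2.5 s (σ_log = 0.35). Only the sub-1-second
mean-RT phenomenon is prescribed by the exclusion rule; the response-time
distributions and the 5% rate are this package's choice of a realistic
contamination level.

A single seed expands into `numpy.random.SeedSequence` substreams keyed by
purpose, cell, and rater slot, so adding raters to one cell perturbs no other
records.

### Analytic consistency and calibration

With per-attribute signal variance `S_a = Var_materials(mu[:,a]) +
stim_cov[a,a]`, taste variance `T` and noise variance `N`:

- intra-observer r (two repetitions, one rater): `(S_a + T) / (S_a + T + N)`
- inter-observer r (two raters' P-repetition means): `S_a / (S_a + T + N/P)`

averaged over attributes. The default ground truth builds `mu` from a
3-dimensional latent attribute structure (deterministic, internally seeded)
and then solves `(T, N)` by root-finding so the attribute-averaged formulas
hit intra = 0.76 and inter = 0.48 exactly — the consistency level typical of
this kind of crowdsourced attribute-rating data. Tests verify the generator
recovers these values empirically within ±0.05. What passing recovery tests
shows is internal coherence of estimator and generator — not that real
observers behave like the model; in particular the model has no trial-order,
anchoring, or attention drift effects, and spammers are uniform rather than
merely careless.

## Quality control

Exclusion is per task: a rater whose mean response time over one task's
trials is strictly below 1.0 s loses that task's records only. Intra-observer
r is the mean of the three pairwise repetition-vector correlations per rater
(vectors over the 90 set stimuli, df = 88), averaged over raters;
inter-observer r is the mean Pearson r over the 45 rater pairs of
repetition-averaged vectors. A transposed estimator (length-`R` per-stimulus
vectors, df = 8) is provided as an option, since published significance lines
for the between-rater axis sometimes assume it; the length-90 construction is
the default. Zero-variance vectors are dropped from pair averages with a
logged warning rather than propagating NaN. Critical correlation lines use
`r = t / sqrt(t² + df)` with the one-sided t quantile.

## Signatures and correlations

Stimulus means average over raters and repetitions; signatures average
stimulus means within material. Attribute–attribute correlations are Pearson
over the 450 stimulus means with two-sided t-transform p-values (df = n − 2)
and Bonferroni tiers at 0.05/45, 0.005/45, 0.0005/45 (`*`, `**`, `***`);
statistic–attribute tables divide by 40. The Wilcoxon signed-rank comparison
of two signature tables drops zero differences, midranks ties, reports
W = the positive-rank sum, and uses the tie-corrected normal approximation
(two-sided, no continuity correction); the exact-enumeration null at n = 8
agrees with the approximation to < 0.05 in p. The cell pairing between two
studies' tables is an explicit argument, defaulting to the identity pairing
on shared (material, attribute) labels.

## Image statistics and stimulus preparation

Luminance is Rec.709 luma of linearly scaled 8-bit RGB (no gamma
linearisation) — the source analysis never defines its luminance, so the
weights are configurable and this default is documented rather than claimed.
Contrast uses 95th/5th percentiles with linear interpolation; skewness is the
population g1; colorfulness bins each channel as `floor(v/16)` into 4096
voxels and reports the occupied fraction; all statistics are computed over
the segment mask only, not the context box.

Context boxes use 0-based half-open pixel boxes; side = round-half-up of
1.25 × the larger bounding-box dimension, centred on the bounding-box centre
(the margin factor is applied to the maximum first, then the box squared).
Overflow is filled with the per-channel mean over painting ∩ box, rounded
half-up to 8-bit values.

## PCA and genericity

PCA standardizes columns by default (centre + unit variance): attributes
share the 0–100 scale but have heterogeneous variances, and a correlation
PCA keeps high-variance attributes from dominating; a covariance PCA is one
flag away. Components are ordered by explained variance; signs follow the
convention that each component's largest-magnitude loading is positive.

For the genericity analysis, each material's PCA is fitted to that material's
rows of the *globally standardized* data, re-centred within the material but
not re-scaled. Global and material score spaces are then orthogonal views of
the same points, which preserves the defining identity of the analysis: a
full-dimensional Procrustes mapping leaves a residual of exactly 0, so any
positive residual at k = 2 is attributable to the truncation, not to
preprocessing mismatch.

Procrustes disparity is the *standardized full* variant: both configurations
centred and scaled to unit total variation, optimal rotation with reflection
allowed and free scale, residual `1 − (Σ singular values)² ∈ [0, 1]`,
symmetric in its arguments. The Monte-Carlo baseline draws configurations
i.i.d. uniform on the 2-D unit square (location/scale of the square are
irrelevant under standardization) and maps them onto each material's global
scores, 10,000 repetitions per material by default; at n = 30 the grand mean
is ≈ 0.95. The baseline path is vectorized through the 2 × 2 closed form
`(σ1 + σ2)² = ‖M‖²_F + 2|det M|`; tests pin it to the SVD implementation.

## Problem sizes and determinism

Tests run the full 135,000-judgment simulation (sub-second), 20-seed
replicate suites for the ordering/recovery invariants, 10,000-repetition
baselines where the claim concerns the baseline itself and a few hundred
repetitions where only its mean matters (Monte-Carlo SE of the grand mean at
200 reps × 15 materials is ≈ 0.0007, far inside the tolerances used). All
randomness flows from explicit integer seeds; two pipeline runs with the same
config are byte-identical, and every output directory carries a manifest with
the config hash and seeds.

## Known limitations

- The generator emulates rating structure, not rating *content*: its default
  signature matrix is a seeded synthetic construct, so material-level outputs
  (which material is most glossy, etc.) are not statements about paintings.
- Clipping is unmodelled in the analytic consistency formulas (small bias,
  quantified above).
- The luminance definition, percentile method, PCA scaling, and Procrustes
  normalization are all points where the source analysis is silent; each is
  configurable and the default documented.
- The per-stimulus-vector inter-observer estimator (df = 8 construction) is
  implemented but its exact intended form is ambiguous; results using it
  should be labelled accordingly.
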