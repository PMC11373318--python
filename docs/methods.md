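# Methods

This note documents the models, algorithms and numerical choices behind the
package, the assumptions they make, and what the bundled simulator can and
cannot establish about real tissue data.

## The generative-predictive model

The core object is a conditional GAN linking two modalities of the same
tissue spot: a protein expression vector **p** (38 markers by default,
spot-level means of per-cell counts) and the H&E image patch **I** centred
on the spot.

**Generator.** `Î = G(p, z; θ_G)` maps `p` together with Gaussian noise
`z ~ N(0, I)` to an RGB patch in `[-1, 1]`. The concatenated `(z, p)` is
projected to a 4×4 feature grid and doubled by residual up-sampling blocks
until the configured patch size is reached (`4·2^s = patch_size`), so a
64 px model has 4 stages and a 256 px model has 6. `p` is re-injected at
every stage through conditional channel normalisation (per-channel scale
and shift predicted from `p` by zero-initialised linear maps), and one
non-local self-attention block sits at the quarter-resolution feature map.
Channel widths halve from a configurable base width (default 64 at the 4×4
seed) down to a floor (default 8).

**Discriminator/predictor.** A mirrored residual down-sampling trunk ends
in two heads on a shared pooled feature: an unbounded realism logit and an
`n_markers` regression `p̂ = D(I; θ_D)`. The discriminator consumes full
patches; spot-sized central crops are an evaluation-time operation only.

**Losses.** With `s` the logistic sigmoid:

* `L_I = MAE(I, Î)` — image reconstruction. `Î` is generated with a fresh
  `z` but compared against the ground-truth patch of the same spot.
* `L_r = MSE(p, D_pred(Î))` — expression reconstructed from the *generated*
  image. Gradients flow through `D` into `G` while `D`'s parameters are
  frozen, so this term shapes the generator without letting it corrupt the
  predictor.
* `L_p = MSE(p, D_pred(I))` — expression predicted from the *real* image;
  the supervised signal for the prediction head.
* `L_GAN` — the min-max loss `E[log s(D(I))] + E[log(1 − s(D(G(p,z))))]`,
  evaluated in log-sum-exp form on logits. The generator uses the
  non-saturating surrogate `−log s(D(Î))` by default (the original
  saturating form is selectable); both have gradients of the same sign in
  the logit.

The composite objective `L = L_I + λ₁L_r + λ₂L_p + λ₃L_GAN` mixes terms
that belong to different players. The assignment used here: one
discriminator Adam step on `λ₂L_p + λ₃L_GAN_d`, then one generator Adam
step on `L_I + λ₁L_r + λ₃L_GAN_g` with fresh per-item noise. Defaults are
the standard training configuration: `λ₁ = λ₂ = 1`, `λ₃ = 0.01`, Adam with
learning rate 1e-4 and first-moment decay 0.5, batch size 16. Totals are
asserted every step to equal the λ-weighted sums of the logged components.

**Numerics.** All tensor computation runs on a compact reverse-mode
autodiff engine over numpy float32 arrays (`ouroboros._nn`). Convolutions
are nine shifted GEMMs; normalisation is per-sample channel normalisation
over spatial positions (no running statistics), which keeps small-batch
CPU training stable and makes generation exactly reproducible from seeds.
Training is bit-reproducible on CPU given the run seed. A non-finite loss
aborts with the offending term named.

## Preprocessing

**Geometry.** WSIs are partitioned into non-overlapping spot tiles (128 px
at full scale) with context patches (256 px) centred on each spot;
coordinates are 0-based, row-major, half-open. Border spots whose context
patch would leave the image are dropped by default (clamping is available)
— patches are meant to be full context windows.

**Expression transform.** Per marker, positive counts are log-transformed
and z-scored using statistics of the positive values only. Zero counts are
pushed through the same affine map after substituting a pseudo-count
`min_positive(marker)/1000`, which places them strictly below every
positive value — "not expressed" stays a separate category and does not
distort the z-statistics. Degenerate cases are defined explicitly: a
marker with a single distinct positive value gets σ = 1; an all-zero
marker maps to a fixed floor of −10 (both logged). The fitted state
(μ, σ, minimum positive value per marker) is serialisable and reusable on
held-out data, which is what the cross-validation protocol requires.
Open choices resolved here: the 1000× sentinel divides the *per-marker*
minimum positive value (keeping the sentinel on each marker's own scale),
and sentinel values are excluded from μ, σ.

**Batch correction.** Patients are batches. The correction standardises
each marker against a reference frame fitted on training batches
(sample-size-weighted batch means; within-batch pooled residual variance),
estimates per-batch additive (γ) and multiplicative (δ) effects, shrinks
them toward cross-marker priors by the parametric empirical-Bayes
iteration, removes them, and restores the reference location/scale. Two
deliberate choices:

* *Location effects are removed unshrunk by default.* Shrinking γ toward
  the cross-marker prior mean retains a sampling-noise residue of order
  `1/√n` in the corrected batch means; with hundreds of spots per patient
  the unshrunk estimates are already precise, and exact alignment of batch
  means is what downstream pooled training needs. Scale effects, which are
  noisier, keep the EB shrinkage. Full shrinkage on both is available via
  `shrink_location=True`.
* *Fit/apply split.* In leave-one-patient-out runs the reference frame is
  fitted on training patients only; the held-out patient's own batch
  effects are then estimated from its data against that fixed frame and
  removed. The held-out patient never influences the reference.

A single batch is returned unchanged; a batch with zero variance in a
marker falls back to scale 1 with a warning.

## Synthetic cohorts

The simulator exists so that every downstream stage — transform, batch
correction, adversarial training, evaluation, perturbation, alignment —
can be exercised end to end with known ground truth. It emulates a
multi-patient imaging-mass-cytometry study paired with H&E-like patches.

Four designated *driver* markers causally control morphology:

| driver  | latent → rendered effect | default mapping |
|---------|--------------------------|-----------------|
| density | nucleus count `K = round(K_min + σ(d)(K_max − K_min))`, logistic in the latent | `K` 5–28 per 64 px patch |
| size    | mean nuclear radius `r = r₀·exp(0.25·d)` | `r₀` = 3.2 px |
| hema    | nuclear darkness toward the hematoxylin anchor RGB (60, 35, 110) | mix 0.35–0.90 |
| eos     | background pink toward the eosin anchor RGB (238, 150, 180) | mix 0.30–0.85 |

Driver latents are standard normal per spot; the other 34 markers are
fixed linear mixtures of the drivers plus independent noise (realistic
marker correlation without extra mechanisms). Counts are gamma-Poisson
(negative-binomial) draws around `exp(latent + patient_shift)` per cell,
with `K` cells per spot, so zeros arise naturally at low means; patient
shifts are fixed per-patient, per-marker normal offsets with configurable
scale (default 0.6 on the log scale), giving a linearly detectable batch
effect that the correction step must remove.

Rendering adds two kinds of within-patch variability that matter for the
evaluation pipeline: per-nucleus darkness jitter and per-nucleus size
jitter (biological heterogeneity), and a crowding effect — nuclei in dense
patches are drawn more elongated (spindle-like), the classic appearance of
highly cellular regions. The crowding effect is what makes the density
driver recoverable from *per-cell averaged* morphometry, where a pure
count change would cancel out.

What the simulator does **not** model: real H&E texture and stain
variability, cell-type taxonomies, spatial interactions between cells,
registration error between consecutive sections, and imaging noise.
Passing the end-to-end checks therefore demonstrates that the pipeline's
machinery works and that its statistics behave as designed — not that the
model reaches any particular performance on real tissue.

## Evaluation

* **Central crops.** Quantitative metrics are computed on the central
  spot-sized crop of both real and generated patches.
* **FID.** `‖μ_A − μ_B‖² + Tr(Σ_A + Σ_B − 2(Σ_AΣ_B)^{1/2})` on embedded
  crops, with a small logged diagonal regulariser if the covariance
  product is singular. The default embedding is a *seeded random
  convolutional network* (three fixed random conv/pool stages; embedding =
  per-channel spatial mean and std, 64-D), so no pretrained weights are
  needed; a handcrafted 64-D descriptor is available, and requesting a
  pretrained external embedding raises with an explanation. FID values are
  comparable only within one embedding; the meaningful statistic is the
  ratio of generated-vs-real to noise-vs-real.
* **Nucleus detection.** Classical pipeline: fixed H&E colour
  deconvolution → hematoxylin channel → Gaussian smoothing → Otsu
  threshold (with a contrast guard for near-blank images) → morphological
  opening → connected components → size filter → distance-transform
  watershed applied only to components larger than 1.8× the median
  component area (self-calibrating split of merged blobs that leaves
  ordinary nuclei alone). The detector interface accepts externally
  supplied masks.
* **Morphometry.** 63 features per patch: 9 shape descriptors (area,
  perimeter, equivalent diameter, major/minor axis, eccentricity,
  solidity, extent, circularity) and 9 statistics (mean, std, min, max,
  median, p10, p90, skewness, excess kurtosis) of 6 intensity channels
  (R, G, B, hematoxylin, eosin, optical density) over nuclear pixels,
  averaged across detected nuclei. A patch with no detected nucleus is
  flagged and excluded from distance analyses. The exact feature list of
  the original QuPath-based profile is not published; this is a documented
  stand-in covering the same size/solidity/stain-distribution categories.
* **Paired morphometry test.** Per real patch: the standardized Euclidean
  distance to its generated counterpart versus the mean distance to
  `n_random = 100` real patches of the same WSI (without replacement when
  the pool allows, else with, logged), followed by a one-sided Wilcoxon
  signed-rank test of "matched < baseline". The feature scaler is fitted
  on the real reference set.
* **Prediction metrics.** Per-marker Pearson and Spearman correlations
  across held-out spots; constant columns are recorded as undefined and
  excluded from means with a count.
* **Baseline.** A prediction-only residual CNN (the discriminator trunk
  architecture without the adversarial game, no attention) trained with
  MSE under the identical fold and step budget.

## Perturbation and alignment

Interpolation takes 10 steps *including* both endpoints (matching the
10-panel presentation of the experiment; configurable), with the noise
vector held fixed across steps so image changes reflect expression changes
only. Perturbation shifts single markers in transformed space.

The subspace alignment uses regularized CCA: columns standardized, ridge
`1e-3` on within-view covariances, whitening + SVD of the cross-covariance.
The 2-D morphology projection of *generated* patches is clustered with a
seeded 8-component full-covariance Gaussian mixture (k-means++
initialisation, bounded re-seeded restarts on non-convergence), and
concordance with expression space is quantified as the adjusted Rand index
against an independent mixture fit on the expression projection — a
numerical version of a claim that is usually made visually.

## Desk-scale study conditions

The acceptance run and the end-to-end tests use one fixed configuration:
4 pseudo-patients × 400 spots, 64 px patches with 32 px spots, noise
dimension 32, 800 alternating training steps (batch 16) on the first
leave-one-patient-out fold, with the prediction-only baseline given the
same step budget. These sizes were chosen as the smallest configuration at
which the four driver effects are cleanly learnable and all statistics are
stable; the architecture instantiates the full 256 px model from the same
code by changing the descriptor.

## Known limitations

* The adversarial weight λ₃ = 0.01 makes training essentially
  reconstruction-driven at desk scale; generated patches are smoother than
  real renders, and absolute FIDs are far below literature scales because
  of the private embedding.
* Desk-scale generation is good enough for conditioning analyses
  (prediction, interpolation, subspace alignment) but not for the paired
  morphometry test: the L1-reconstruction-dominated generator converges
  toward conditional-median images whose detected nuclei are systematically
  larger, lower-contrast and smoother than real renders, and this
  cross-modal offset in the standardized 63-feature space exceeds the
  within-WSI spread of real patches. A perfect conditional sampler passes
  the same test overwhelmingly, so the limitation is generation quality at
  this scale and step budget, not the test protocol. Closing it requires
  training far past the desk-scale regime (where adversarial pressure can
  shape texture), as the full-scale published setting does.
* Nucleus detection is tuned for simulator-like contrast; on real H&E it
  should be replaced through the detector interface by a trained detector.
* Batch correction assumes location/scale effects per marker without
  covariates; nonlinear batch distortions are out of scope.
* The Wilcoxon paired test inherits the usual caveat that matched and
  baseline distances are dependent within a WSI pool; with the 63-D
  profile the difference distribution is close enough to symmetric that
  the null behaves (verified by the shuffled-pairing control).
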