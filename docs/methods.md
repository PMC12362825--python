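# Methods

This note documents the models implemented in `genoface`, the synthetic
data they are validated on, the numerical choices made where the design
was genuinely open, and what the shipped tests do and do not establish.

## Problem setting

Facial shape is heritable: common variants influence the soft-tissue
geometry of the nose, eyes and cheeks.  Given a panel of face-associated
SNP dosages for an individual, the package reconstructs a 3D facial
surface in dense vertex correspondence with a template.  The pipeline has
two stages:

1. **Contrastive alignment.**  A spiral-convolution mesh autoencoder maps
   a registered face mesh `X` (V vertices, mm units) to a latent face
   embedding `z_f` and back; a transformer maps the SNP dosage vector `Y`
   (m SNPs, dosage in [0, 2]) to an SNP embedding `z_s` in the same
   space.  A symmetric cross-entropy loss on scaled cosine similarities
   pulls matched `(z_f, z_s)` pairs together within each batch while
   pushing the N(N−1) mismatched pairs apart; an L1 loss trains the
   decoder to reconstruct meshes from `z_f`.
2. **Conditional diffusion prior.**  With stage-1 weights frozen, a
   denoising diffusion model learns `p(z_f | z_s)`: the forward process
   corrupts face embeddings with Gaussian noise over T steps; the reverse
   chain is driven by a small attention network that predicts the clean
   embedding directly (x0-parameterisation, no classifier-free guidance)
   and steps through the exact Gaussian posterior `q(z_{t-1} | z_t, z_0)`.
   Decoding a sampled `z_f` yields the reconstructed face.

## Model components

### Spiral neighbourhoods and convolution

The 0-ring of a vertex is the vertex itself; the (k+1)-ring is the set of
neighbours of the k-ring outside the k-disk (the union of rings 0..k).
A spiral sequence concatenates rings in order, each ring enumerated
counter-clockwise with respect to the mesh's consistent face winding,
starting adjacent to the previous ring's first element (the start/
orientation convention is not fixed by the method family; ours is chosen
to be deterministic and orientation-consistent, and is frozen in tests).
A spiral convolution gathers features along the fixed length-l sequence
of every vertex, concatenates them, and applies a shared linear map.
Dilated spirals enumerate l·d vertices and keep every d-th.  Truncated
spirals (boundary or small components) are padded with a virtual vertex
index whose features read as zeros.

### Pooling hierarchy

Pooling uses a fixed multiresolution hierarchy built by quadric-error-
metric half-edge collapse: each collapse moves a vertex onto a neighbour,
choosing the cheapest collapse under the accumulated plane quadrics and
rejecting collapses that flip face normals or create duplicate faces.
Coarse vertices are therefore a subset of fine vertices: down-sampling is
restriction to the kept vertices, and up-sampling interpolates each
removed vertex barycentrically from its nearest coarse triangle (convex
weights).  Pool∘unpool is exactly the identity on coarse-representable
fields.  Hierarchies are cached in an HDF5 sidecar keyed by mesh hash and
pool factors.

### Architectures

The full-scale reference configuration is: face encoder
`3×{Conv(32)→Pool(4)} → {Conv(64)→Pool(4)} → FC(128)`, spiral lengths
[9,9,9,9], dilations [1,1,1,1], ReLU after every convolution; decoder
mirrored with unpooling plus a final convolution with output dimension 3;
SNP encoder: 2 transformer layers, model dim 128, 8 heads, feed-forward
512, dropout 0.1, layer-norm eps 1e-5; diffusion prior: 4 attention
layers, 4 heads of dim 64, hidden dim 128, feed-forward expansion 2,
dropout 0.1, T = 1000 steps.  All sizes are configuration fields, and the
desk-scale preset used throughout the tests is: 642-vertex template,
three pool stages (a 642-vertex mesh cannot support four factor-4 pools
above the 4-vertex floor), channels [16,16,32], latent 32, SNP model dim
64, prior depth 2 with 4 heads of dim 16, T = 250 with a linear beta
schedule from 1e-4 to 0.06 (chosen so the terminal signal fraction
alpha-bar_T is below 1e-3, matching the role of the 1000-step default).

The SNP tokenizer is an open design point: the dosage vector is split
into contiguous chunks (default 128 SNPs at full scale, 100 at desk
scale), each projected to the model dimension by its own linear map —
per-chunk weights matter: a projection shared across chunks cannot give
each SNP its own coefficient, which removes the additive genetic model
from the encoder's hypothesis space and leaves only attention-mediated
memorisation — combined with
learned positional encodings and a learned pooling token whose final
state is projected to `z_s`.  Because a few hundred training samples
cannot constrain an unregularised transformer over hundreds of input
dimensions, the encoder also supports per-SNP input dropout (desk preset
0.2); this is the single most effective control against pair
memorisation in the contrastive stage at desk scale, and doubles as
training-time exposure to the panel-subsampling regime evaluated in the
deletion study.

### Losses and optimisation

With `N` the batch size, `zf_hat`/`zs_hat` the L2-normalised embeddings
and α a fixed similarity scale (default 10):

    Logit1 = α · zf_hat zs_hatᵀ,  Logit2 = Logit1ᵀ
    L_con  = ½ [CE(Logit1, 0..N−1) + CE(Logit2, 0..N−1)]
    L_mesh = mean |X̂ − X|          (over samples, vertices, coordinates; mm)
    L      = β1 L_con + β2 L_mesh   (β1 = β2 = 1 by default)

L2 normalisation is applied inside the contrastive loss only; the raw
`z_f` feeds the decoder, since reconstruction needs an unconstrained
latent.  The per-sample reduction of the L1 loss is the mean over
vertices and coordinates, making the loss a per-coordinate error in mm
regardless of V.  β1, β2, α and N are not fixed by the reference
description; the defaults above are this package's choices.

Optimisation is AdamW with two parameter groups — encoders (reference:
lr 7.3e-6, weight decay 0.30) and decoder (lr 3.2e-5, weight decay
0.001) — with a multiplicative 0.99 learning-rate decay per epoch.  The
reference rates are tuned to a ~9,700-sample cohort and days of GPU
training; the desk preset uses lr 1e-3/2e-3 with weight decay 0.01/1e-5
so that the loss moves within minutes of CPU time.  The diffusion prior
trains with AdamW (reference lr 0.31e-4, weight decay 0.752; desk 1e-3,
1e-3), gradient-norm clipping at 0.5, and an exponential moving average
of the weights (decay 0.98) that is used for sampling.

### Diffusion details

The forward marginal is `q(z_t | z_0) = N(sqrt(abar_t) z_0,
(1−abar_t) I)` with `abar_t` the cumulative product of `1−beta_t`.  The
reverse step uses the exact posterior

    mean = [sqrt(abar_{t-1}) β_t z_0 + sqrt(α_t)(1−abar_{t-1}) z_t] / (1−abar_t)
    var  = β_t (1−abar_{t-1}) / (1−abar_t)

with the network's prediction substituted for `z_0`; the final step
returns the prediction deterministically.  Conditioning enters as
tokens: the sinusoidal timestep embedding, the projected SNP embedding,
optional covariate tokens (linear maps of standardised age and BMI, a
learned two-row table for sex; a mask supports ablations with any subset)
and the projected noisy state, processed by the attention layers with the
prediction read from the state token's position.  The one-channel wording
in the reference description is not interpretable as written; it is
realised here as a single conditioning token per input.

## Synthetic data

No public paired genome/3D-face cohort exists, so correctness is
established on simulated data with planted ground truth:

* **Genotypes** are Hardy-Weinberg draws: per-SNP MAF ~ U(0.05, 0.5),
  dosage ~ Binomial(2, MAF).  SNPs carry locus tags (consecutive pairs)
  standing in for LD-independent loci.
* **Template**: a subdivided icosphere at 80 mm radius (level 3 = 642
  vertices) with pseudo-landmarks (pronasale, nasion, glabella, alare,
  cheilion, ...) and nose/eye/cheek/face region masks defined by
  direction cones.
* **Effects**: three localized radial bump fields (nose, eyes, cheeks)
  and three global smoothed random fields, all normalised to unit RMS
  displacement so the configured effect scales (1.5 mm per amplitude SD
  each) are comparable across fields.  Each field is driven additively by
  its own causal SNP set (25 per feature field, 15 per global field) with
  random-sign loadings scaled to give the stated amplitude SD.
  Covariates add their own fields (0.5 mm/SD age, 1.0 mm sex, 0.5 mm/SD
  BMI) and i.i.d. Gaussian vertex noise with σ = 0.2 mm is added.  The
  default desk cohort is n = 600 (480/120 split), m = 400.
* **Labels**: tertiles of landmark statistics of the generated geometry
  (mean radial displacement over the nose / eye / cheek masks), so each
  categorical feature has a known causal SNP set.
* **GWAS sets**: causal sets plus random decoys, per feature and pooled.

What the simulator does **not** emulate: LD beyond locus tags, ancestry
stratification, non-additive genetics, capture/registration artefacts,
and any facial realism.  Passing the recovery tests shows the pipeline
can extract a planted additive genotype→shape signal at realistic
sample-size-to-dimension ratios — not that it would reach any particular
accuracy on a real cohort.

## Evaluation metrics

* **Identification**: rank-k% rate — the fraction of queries whose true
  match is within the top ceil(k/100·N) gallery entries of the cosine
  similarity matrix; ties break by stable gallery order.
* **Verification**: ROC over genuine (diagonal) vs impostor
  (off-diagonal) scores; AUC by trapezoid; EER where FPR = 1−TPR with
  linear interpolation (degenerate all-equal scores: EER = AUC = 50%).
* **Geometry**: per-vertex Euclidean distance (mean and RMSE, mm),
  symmetric chamfer distance, per-landmark tables.
* **Diversity**: determinantal-point-process score det K with
  K_ij = 1/(1+dist); mean per-vertex Euclidean distance between meshes by
  default; a ≤1e-6 seed-controlled diagonal jitter guards conditioning.
* **Feature preservation**: per-feature MLP+softmax classifiers trained
  on real training-set face latents, evaluated on real and generated test
  latents.
* **Attribution**: expected gradients through the frozen SNP encoder and
  a feature head (baselines drawn from the data; default 50 baselines ×
  20 interpolation points, seed-controlled); top-k selection by mean
  absolute attribution with index tie-break; optional best-per-locus
  filter standing in for LD pruning; upper-tail hypergeometric test
  against GWAS sets.

## Numerical and engineering choices

* The networks run on an in-repo reverse-mode autodiff engine over
  float64 numpy arrays; gradients are verified against central finite
  differences.  Training is single-threaded CPU and fully deterministic
  given seeds.
* QEM decimation targets round(V/factor) vertices per stage and refuses
  to go below 4 vertices.
* Degenerate inputs: a one-pair contrastive batch returns loss 0 with a
  warning; singleton batches are skipped in training; empty SNP sets in
  enrichment return p = 1 with a warning; non-finite losses abort with
  diagnostics.
* A single global seed fans out to per-stage seeds as
  `(seed · 10007 + offset) mod 2³¹` with a fixed offset per stage, so
  stages are independently reproducible.
* Problem sizes in the shipped tests and the acceptance script (desk
  cohort n = 600, m = 400, V = 642; stage-1 ~60-100 epochs; prior ~3000
  steps; T = 250) are chosen so the full recovery experiment runs in
  minutes on a single CPU.

## Known limitations

* The desk-scale recovery experiment demonstrates mechanism, not
  clinical or forensic performance; absolute error numbers depend
  entirely on the simulator's effect scales.
* Honest posterior sampling puts a hard ceiling on how well generated
  faces preserve categorical features: if the SNP embedding explains a
  fraction R² of a feature statistic's variance, a sampled face's
  statistic correlates with the truth at only ρ = R² (the conditional
  mean would correlate at √R²).  At desk scale the transformer encoder
  reaches R² ≈ 0.6–0.7 held-out (its cap even under direct supervision
  at 480 training samples, although the planted map is linear and ridge
  regression attains R² = 1), so classifiers that score ~0.88 on real
  test faces score ~0.57 on generated ones.  Closing that gap requires
  either many more samples, a more linearity-biased encoder, or
  evaluating conditional means instead of samples.
* The contrastive stage at n≈500 is regularisation-sensitive; without
  input dropout and weight decay the SNP encoder memorises training
  pairs (the package exposes both knobs).
* The spiral orientation convention and decimation algorithm are
  package choices where the method family leaves them open; spiral
  tables are deterministic but not guaranteed identical to other
  implementations'.
* The minimal VCF reader handles diploid GT fields only.
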