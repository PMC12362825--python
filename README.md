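# genoface

Generative modelling from genotype to 3D facial shape.

`genoface` reconstructs registered 3D face meshes from a panel of
face-associated SNP dosages.  It is aimed at researchers studying the
genetics of facial morphology and at method developers in DNA
phenotyping who need a tested, fully reproducible desk-scale
implementation of the contrastive-alignment + diffusion-prior approach,
together with a synthetic cohort generator that makes every stage
verifiable without access to any private study data.

## The model

Two encoders map both modalities into one latent space (dimension `d`,
default 128 at full scale, 32 at desk scale):

* a **spiral-convolution mesh autoencoder** for faces: convolutions
  gather vertex features along fixed spiral enumerations of each
  vertex's ring neighbourhood (0-ring(v) = {v}; (k+1)-ring =
  N(k-ring) \ k-disk), with pooling over a quadric-decimation mesh
  hierarchy; the decoder mirrors it with unpooling and a final
  3-channel convolution;
* a **transformer SNP encoder**: the dosage vector is chunked into
  tokens, projected per-chunk, and processed by a 2-layer transformer
  whose pooling token yields the SNP embedding `z_s`.

Stage 1 trains both with a joint objective over batches of N pairs,

    Logit₁ = α ẑ_f ẑ_sᵀ,   Logit₂ = Logit₁ᵀ
    L = β₁ · ½[CE(Logit₁, 0..N−1) + CE(Logit₂, 0..N−1)] + β₂ · mean|X̂ − X|

pulling matched SNP/face pairs together in cosine similarity while the
decoder learns to reconstruct meshes (mm) from face embeddings.

Stage 2 freezes everything and trains a **conditional diffusion prior**
in embedding space: forward process q(z_t | z_{t−1}) =
N(√(1−β_t) z_{t−1}, β_t I) over T steps; a small attention network
predicts the clean embedding z₀ from (z_t, t, z_s) and the reverse chain
steps through the exact Gaussian posterior q(z_{t−1} | z_t, z₀).
Generation is: genotype → `z_s` → sampled `z_f` → decoded mesh.
Optional covariate tokens (age, sex, BMI) refine the conditioning.

Evaluation covers biometric identification (rank-k% rates), verification
(EER/AUC), geometry errors (per-vertex Euclidean, RMSE, chamfer,
per-landmark tables), generation diversity (determinantal-point-process
scores), feature-preservation classification, an SNP-deletion study, and
expected-gradients SNP attribution with hypergeometric enrichment
against GWAS sets.

## Worked example

```python
from genoface.simulate import SimConfig, make_dataset
from genoface.hierarchy import build_hierarchy
from genoface.networks import FaceAutoencoderSpec, SnpEncoderSpec
from genoface.training import AlignTrainConfig, train_alignment
from genoface.evaluation import cosine_similarity_matrix, identification_rates
from genoface.autodiff import Tensor

ds = make_dataset(SimConfig(n_samples=200, n_snps=120, template_level=2,
                            n_causal_per_feature=10, n_global_fields=2,
                            n_causal_per_global=8, seed=0))
hier = build_hierarchy(ds.template, [4, 4])
enc, dec, snp_enc, hist = train_alignment(
    ds, hier,
    AlignTrainConfig(alpha=10.0, batch_size=32, lr_core=1e-3, wd_core=0.01,
                     lr_decoder=2e-3, wd_decoder=1e-5, epochs=30, seed=0),
    FaceAutoencoderSpec(conv_channels=[16, 16], pool_factors=[4, 4],
                        spiral_lengths=[9, 9], spiral_dilations=[1, 1], latent=16),
    SnpEncoderSpec(model_dim=32, ff_dim=64, layers=2, heads=4,
                   chunk_size=30, latent=16, input_dropout=0.2))

z_f = enc(Tensor(ds.meshes[ds.test_idx])).data
z_s = snp_enc(Tensor(ds.centered_genotypes(ds.test_idx))).data
rates = identification_rates(cosine_similarity_matrix(z_s, z_f), [1, 10, 20])
print(rates)
```

This trains the alignment stage on a 200-individual synthetic cohort in
about two minutes and prints held-out identification rates:

```
{1: 7.5, 10: 27.5, 20: 47.5}
```

meaning 7.5% of test individuals are ranked first in the 40-face gallery
when queried by their genotype embedding, 27.5% fall in the top 10% and
47.5% in the top 20% — roughly three times the chance levels (2.5%, 10%,
20%) after this deliberately short demonstration run.  The default
desk-scale configuration (600 individuals, 60 epochs, as used by
`scripts/acceptance.py`) reaches a top-10% rate around 70%.  The
`examples/` directory has one short script per capability: simulation,
spiral convolution, alignment, the diffusion prior, biometric metrics,
attribution/enrichment, and the full pipeline.

A thin CLI wraps the same library code end to end:

```bash
genoface simulate -o runs/demo
genoface train-align -o runs/demo && genoface train-prior -o runs/demo
genoface generate -o runs/demo -g runs/demo/dataset/genotypes.tsv
genoface evaluate -o runs/demo && genoface dropout -o runs/demo
genoface attribute -o runs/demo
```

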