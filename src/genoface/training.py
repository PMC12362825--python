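"""Stage-1 objectives and the joint contrastive + reconstruction loop.

The face encoder, face decoder and SNP encoder are trained together.
The decoder is supervised by a mean-absolute (L1) reconstruction loss in
millimetres; the two encoders are pulled together by a symmetric
cross-entropy contrastive loss on the cosine-similarity logits between
all face/SNP pairs in a batch:

    Logit1 = alpha * zf_hat @ zs_hat.T        (faces index the rows)
    Logit2 = Logit1.T
    L_con  = (CE(Logit1, 0..N-1) + CE(Logit2, 0..N-1)) / 2
    L_all  = beta1 * L_con + beta2 * L_mesh

Embeddings are L2-normalised inside the contrastive loss only; the raw
face embedding feeds the decoder.  Optimisation is AdamW with two
parameter groups (encoders vs decoder — the reference run used lr
7.3e-6 / weight decay 0.30 for the core and lr 3.2e-5 / weight decay
0.001 for the decoder) and a multiplicative 0.99-per-epoch LR decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .data import PairedDataset
from .hierarchy import MeshHierarchy
from .networks import (FaceAutoencoderSpec, FaceDecoder, FaceEncoder,
                       SnpEncoder, SnpEncoderSpec)
from .nn import AdamW, StepLR

__all__ = ["AlignTrainConfig", "mesh_l1_loss", "contrastive_loss", "total_loss",
           "train_alignment"]


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def mesh_l1_loss(pred, true) -> Tensor:
    """Mean absolute coordinate deviation (mm), averaged over samples,
    vertices and coordinates."""
    pred, true = _as_t(pred), _as_t(true)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    return (pred - true).abs().mean()


def contrastive_loss(z_f, z_s, alpha: float) -> Tensor:
    """Symmetric InfoNCE-style loss over an N-pair batch.

    Both embedding sets are L2-normalised internally so the logits are
    scaled cosine similarities.  At the uniform-similarity point (all
    logits equal) the loss is exactly ln N; with perfectly aligned,
    mutually orthogonal pairs it tends to 0 as alpha grows.
    """
    z_f, z_s = _as_t(z_f), _as_t(z_s)
    if z_f.shape != z_s.shape:
        raise ValueError("z_f and z_s must have the same shape")
    N = z_f.shape[0]
    if N == 1:
        warnings.warn("contrastive loss is degenerate for a single pair (N=1)")
        return Tensor(np.zeros(()))
    zf_hat = z_f / ((z_f**2).sum(axis=1, keepdims=True)).sqrt()
    zs_hat = z_s / ((z_s**2).sum(axis=1, keepdims=True)).sqrt()
    logits = (zf_hat @ zs_hat.transpose(1, 0)) * float(alpha)
    labels = np.arange(N)
    ce1 = -logits.log_softmax(axis=1)[labels, labels].mean()
    ce2 = -logits.transpose(1, 0).log_softmax(axis=1)[labels, labels].mean()
    return (ce1 + ce2) * 0.5


def total_loss(loss_con, loss_mesh, beta1: float, beta2: float) -> Tensor:
    """Weighted sum beta1 * contrastive + beta2 * reconstruction."""
    return _as_t(loss_con) * float(beta1) + _as_t(loss_mesh) * float(beta2)


@dataclass
class AlignTrainConfig:
    """Hyperparameters of the stage-1 run (reference values as defaults).

    ``alpha`` is the fixed similarity scale, ``beta1``/``beta2`` the loss
    weights (neither is printed in the reference; 10 / 1 / 1 are this
    package's defaults).
    """

    alpha: float = 10.0
    beta1: float = 1.0
    beta2: float = 1.0
    batch_size: int = 32
    lr_core: float = 7.3e-6
    wd_core: float = 0.30
    lr_decoder: float = 3.2e-5
    wd_decoder: float = 0.001
    lr_decay: float = 0.99
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.alpha, self.batch_size, self.lr_core, self.lr_decoder,
               self.lr_decay, self.epochs) <= 0:
            raise ValueError("config values must be positive")
        if self.beta1 + self.beta2 <= 0:
            raise ValueError("beta1 + beta2 must be positive")


def train_alignment(dataset: PairedDataset, hierarchy: MeshHierarchy,
                    cfg: AlignTrainConfig,
                    face_spec: FaceAutoencoderSpec | None = None,
                    snp_spec: SnpEncoderSpec | None = None,
                    log=None,
                    ) -> tuple[FaceEncoder, FaceDecoder, SnpEncoder, list[dict]]:
    """Train the two encoders and the decoder on the training split.

    Returns the trained modules and a per-epoch loss history
    (dicts with total / contrastive / mesh components and the LR).
    """
    face_spec = face_spec or FaceAutoencoderSpec()
    snp_spec = snp_spec or SnpEncoderSpec()
    rng = np.random.default_rng(cfg.seed)
    init_rng = np.random.default_rng(rng.integers(2**31))

    enc = FaceEncoder(face_spec, hierarchy, init_rng)
    dec = FaceDecoder(face_spec, hierarchy, init_rng)
    snp_enc = SnpEncoder(dataset.genotypes.n_snps, snp_spec, init_rng)

    opt = AdamW([
        {"params": enc.parameters() + snp_enc.parameters(),
         "lr": cfg.lr_core, "weight_decay": cfg.wd_core},
        {"params": dec.parameters(),
         "lr": cfg.lr_decoder, "weight_decay": cfg.wd_decoder},
    ])
    sched = StepLR(opt, cfg.lr_decay)

    train_idx = np.asarray(dataset.train_idx)
    meshes = dataset.meshes
    genotypes = dataset.centered_genotypes()
    history: list[dict] = []
    for mod in (enc, dec, snp_enc):
        mod.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        bs = min(cfg.batch_size, len(order))
        ep = {"con": 0.0, "mesh": 0.0, "total": 0.0, "n": 0}
        for start in range(0, len(order), bs):
            idx = order[start:start + bs]
            if len(idx) < 2:
                continue  # a singleton batch has no contrastive signal
            verts = Tensor(meshes[idx])
            z_f = enc(verts)
            recon = dec(z_f)
            z_s = snp_enc(Tensor(genotypes[idx]))
            l_con = contrastive_loss(z_f, z_s, cfg.alpha)
            l_mesh = mesh_l1_loss(recon, verts)
            loss = total_loss(l_con, l_mesh, cfg.beta1, cfg.beta2)
            val = float(loss.data)
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}: con={float(l_con.data):.4g} "
                    f"mesh={float(l_mesh.data):.4g} batch_mean={meshes[idx].mean():.4g}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep["con"] += float(l_con.data) * len(idx)
            ep["mesh"] += float(l_mesh.data) * len(idx)
            ep["total"] += val * len(idx)
            ep["n"] += len(idx)
        sched.step()
        rec = {"epoch": epoch,
               "loss_total": ep["total"] / ep["n"],
               "loss_con": ep["con"] / ep["n"],
               "loss_mesh": ep["mesh"] / ep["n"],
               "lr_core": opt.groups[0]["lr"]}
        history.append(rec)
        if log is not None:
            log(rec)
    for mod in (enc, dec, snp_enc):
        mod.eval()
    return enc, dec, snp_enc, history
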