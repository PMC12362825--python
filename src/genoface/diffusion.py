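"""Conditional diffusion prior in embedding space.

The prior bridges the two encoders: given an SNP embedding ``y`` it
generates a face embedding ``z_f`` by denoising diffusion.  The forward
process adds Gaussian noise to face embeddings over ``T`` steps,

    q(z_t | z_{t-1}) = N(z_t; sqrt(1 - beta_t) z_{t-1}, beta_t I),

whose iterated marginal is the closed form
``q(z_t | z_0) = N(sqrt(abar_t) z_0, (1 - abar_t) I)`` with
``abar_t = prod_{s<=t} (1 - beta_s)``.  The reverse chain uses the exact
Gaussian posterior q(z_{t-1} | z_t, z_0) obtained by Bayes' theorem, with
the network predicting the clean embedding directly
(x0-parameterisation, no conditional dropout); the training loss is the
mean-squared error between the prediction and ``z_0`` at a uniformly
drawn timestep.

Reference settings: T = 1000 steps; a 4-layer attention denoiser with
4 heads of dimension 64, hidden dim 128, feed-forward expansion 2,
dropout 0.1; AdamW at lr 0.31e-4, weight decay 0.752, gradient norm
clipped at 0.5; EMA of the weights with beta 0.98.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .nn import AdamW, Dropout, EMA, Linear, Module, TransformerEncoderLayer, clip_grad_norm

__all__ = [
    "DiffusionSchedule", "make_schedule", "q_sample", "posterior_params",
    "PriorNetSpec", "PriorNet", "PriorTrainConfig", "prior_loss",
    "sample_prior", "train_prior",
]


# --------------------------------------------------------------------------
# schedule
# --------------------------------------------------------------------------

@dataclass
class DiffusionSchedule:
    """Variance schedule beta_1..beta_T and derived cumulative products.

    Arrays are indexed 0..T-1 for timesteps 1..T.
    """

    betas: np.ndarray

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=np.float64)
        if self.betas.ndim != 1 or self.betas.size < 1:
            raise ValueError("betas must be a nonempty 1-d array")
        if np.any(self.betas <= 0) or np.any(self.betas >= 1):
            raise ValueError("betas must lie in (0, 1)")
        self.alphas = 1.0 - self.betas
        self.alpha_bars = np.cumprod(self.alphas)

    @property
    def T(self) -> int:
        return self.betas.size

    def abar(self, t: int) -> float:
        """alpha_bar_t for t in 1..T; alpha_bar_0 = 1 (no noise)."""
        if not (0 <= t <= self.T):
            raise IndexError(f"t={t} out of range 0..{self.T}")
        return 1.0 if t == 0 else float(self.alpha_bars[t - 1])


def make_schedule(T: int, kind: str = "linear",
                  beta_start: float = 1e-4, beta_end: float = 0.02) -> DiffusionSchedule:
    """Build a variance schedule. ``linear`` interpolates beta from
    ``beta_start`` to ``beta_end``; ``cosine`` uses the squared-cosine
    alpha-bar profile."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if kind == "linear":
        betas = np.linspace(beta_start, beta_end, T)
    elif kind == "cosine":
        s = 0.008
        ts = np.arange(T + 1) / T
        abar = np.cos((ts + s) / (1 + s) * np.pi / 2) ** 2
        abar /= abar[0]
        betas = np.clip(1.0 - abar[1:] / abar[:-1], 1e-8, 0.999)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    return DiffusionSchedule(betas=betas)


def q_sample(z0: np.ndarray, t: int, schedule: DiffusionSchedule,
             rng: np.random.Generator) -> np.ndarray:
    """Draw z_t ~ q(z_t | z_0) = N(sqrt(abar_t) z_0, (1 - abar_t) I).

    ``t = 0`` is the no-noise extension and returns ``z0`` exactly.
    """
    if not (0 <= t <= schedule.T):
        raise IndexError(f"t={t} out of range 0..{schedule.T}")
    ab = schedule.abar(t)
    z0 = np.asarray(z0, dtype=np.float64)
    if t == 0:
        return z0.copy()
    return np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * rng.standard_normal(z0.shape)


def posterior_params(z0: np.ndarray, zt: np.ndarray, t: int,
                     schedule: DiffusionSchedule) -> tuple[np.ndarray, float]:
    """Mean and variance of the Gaussian posterior q(z_{t-1} | z_t, z_0).

    For t >= 2 this is the standard result of conditioning the linear-
    Gaussian forward chain:

        mean = [sqrt(abar_{t-1}) beta_t z0 + sqrt(alpha_t)(1 - abar_{t-1}) zt]
               / (1 - abar_t)
        var  = beta_t (1 - abar_{t-1}) / (1 - abar_t)

    ``t = 1`` returns (z0, 0): the final step is the deterministic read-out
    of the predicted clean embedding.
    """
    if not (1 <= t <= schedule.T):
        raise IndexError(f"t={t} out of range 1..{schedule.T}")
    z0 = np.asarray(z0, dtype=np.float64)
    zt = np.asarray(zt, dtype=np.float64)
    if t == 1:
        return z0.copy(), 0.0
    beta_t = schedule.betas[t - 1]
    alpha_t = schedule.alphas[t - 1]
    ab_t = schedule.abar(t)
    ab_tm1 = schedule.abar(t - 1)
    mean = (np.sqrt(ab_tm1) * beta_t * z0 + np.sqrt(alpha_t) * (1 - ab_tm1) * zt) / (1 - ab_t)
    var = float(beta_t * (1 - ab_tm1) / (1 - ab_t))
    return mean, var


# --------------------------------------------------------------------------
# denoising network
# --------------------------------------------------------------------------

@dataclass
class PriorNetSpec:
    """Denoiser architecture (reference values as defaults)."""

    embed_dim: int = 128   # transformer hidden dim
    depth: int = 4
    heads: int = 4
    head_dim: int = 64
    ff_mult: int = 2
    dropout: float = 0.1
    latent: int = 128      # dimension of the embeddings being denoised
    covariates: list[str] = field(default_factory=list)  # e.g. ["age", "sex", "bmi"]


def _sinusoidal(t: np.ndarray, dim: int) -> np.ndarray:
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = np.asarray(t, dtype=np.float64)[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(ang), np.cos(ang)], axis=1)
    if emb.shape[1] < dim:
        emb = np.pad(emb, ((0, 0), (0, dim - emb.shape[1])))
    return emb


class PriorNet(Module):
    """Attention denoiser: predicts the clean face embedding z_0 from
    (z_t, t, condition tokens).

    The timestep embedding, the SNP-condition token, optional covariate
    tokens (linear embeddings for standardized age/BMI, a learned table
    for sex) and the noisy-state token form a short sequence processed by
    ``depth`` transformer layers; the prediction is read from the
    noisy-state (final) token.
    """

    def __init__(self, spec: PriorNetSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        d = spec.embed_dim
        self.time_proj = Linear(d, d, rng)
        self.cond_proj = Linear(spec.latent, d, rng)
        self.state_proj = Linear(spec.latent, d, rng)
        for name in spec.covariates:
            if name == "sex":
                self.sex_table = Tensor(rng.normal(0, 0.02, size=(2, d)), requires_grad=True)
            else:
                setattr(self, f"cov_{name}", Linear(1, d, rng))
        n_tokens = 2 + len(spec.covariates)  # time + [covariates] + cond? see below
        self.pos = Tensor(rng.normal(0, 0.02, size=(n_tokens + 1, d)), requires_grad=True)
        for i in range(spec.depth):
            setattr(self, f"layer{i}",
                    TransformerEncoderLayer(d, spec.heads, spec.ff_mult * d, rng,
                                            dropout=spec.dropout,
                                            head_dim=spec.head_dim))
        self.drop = Dropout(spec.dropout, rng)
        self.head = Linear(d, spec.latent, rng)

    def forward(self, z_t: Tensor, t: np.ndarray, y: Tensor | None,
                covariates: dict[str, np.ndarray] | None = None,
                cov_mask: set[str] | None = None) -> Tensor:
        """``z_t``: (B, latent); ``t``: (B,) int; ``y``: (B, latent) or None.

        ``covariates`` maps name -> (B,) values (age/BMI standardized,
        sex in {0,1}); ``cov_mask`` restricts which are used (ablations).
        """
        B = z_t.shape[0]
        d = self.spec.embed_dim
        tokens = [self.time_proj(Tensor(_sinusoidal(t, d))).reshape(B, 1, d)]
        if y is not None:
            tokens.append(self.cond_proj(y).reshape(B, 1, d))
        else:
            tokens.append(Tensor(np.zeros((B, 1, d))))
        for name in self.spec.covariates:
            if cov_mask is not None and name not in cov_mask:
                tokens.append(Tensor(np.zeros((B, 1, d))))
                continue
            if covariates is None or name not in covariates:
                raise KeyError(f"covariate {name!r} required by the prior but not provided")
            vals = np.asarray(covariates[name], dtype=np.float64)
            if name == "sex":
                tok = self.sex_table.take_rows(vals.astype(np.int64)).reshape(B, 1, d)
            else:
                tok = getattr(self, f"cov_{name}")(Tensor(vals[:, None])).reshape(B, 1, d)
            tokens.append(tok)
        tokens.append(self.state_proj(z_t).reshape(B, 1, d))
        x = concat(tokens, axis=1) + self.pos
        x = self.drop(x)
        for i in range(self.spec.depth):
            x = getattr(self, f"layer{i}")(x)
        n_last = x.shape[1] - 1
        return self.head(x[:, n_last, :])


# --------------------------------------------------------------------------
# training and sampling
# --------------------------------------------------------------------------

def prior_loss(net: PriorNet, z0: np.ndarray, y: np.ndarray | None,
               schedule: DiffusionSchedule, rng: np.random.Generator,
               covariates: dict[str, np.ndarray] | None = None,
               cov_mask: set[str] | None = None) -> Tensor:
    """MSE between the denoiser's prediction and z_0 at a uniform t ~ 1..T."""
    z0 = np.asarray(z0, dtype=np.float64)
    B = z0.shape[0]
    t = rng.integers(1, schedule.T + 1, size=B)
    ab = np.array([schedule.abar(int(ti)) for ti in t])[:, None]
    zt = np.sqrt(ab) * z0 + np.sqrt(1 - ab) * rng.standard_normal(z0.shape)
    y_t = Tensor(np.asarray(y, dtype=np.float64)) if y is not None else None
    pred = net(Tensor(zt), t, y_t, covariates=covariates, cov_mask=cov_mask)
    return ((pred - Tensor(z0)) ** 2).mean()


def sample_prior(net: PriorNet, y: np.ndarray | None, schedule: DiffusionSchedule,
                 rng: np.random.Generator,
                 covariates: dict[str, np.ndarray] | None = None,
                 cov_mask: set[str] | None = None) -> np.ndarray:
    """Ancestral sampling of face embeddings conditioned on ``y``.

    Starts from z_T ~ N(0, I); at each step predicts z0_hat and draws
    z_{t-1} from the exact posterior around it; the final step returns
    z0_hat deterministically.  Batched over the rows of ``y``.
    """
    if y is not None:
        y = np.asarray(y, dtype=np.float64)
        B = y.shape[0]
    else:
        if covariates is None or not covariates:
            raise ValueError("need y or covariates to determine batch size")
        B = len(next(iter(covariates.values())))
    latent = net.spec.latent
    net.eval()
    z = rng.standard_normal((B, latent))
    y_t = Tensor(y) if y is not None else None
    for t in range(schedule.T, 0, -1):
        tt = np.full(B, t)
        z0_hat = net(Tensor(z), tt, y_t, covariates=covariates, cov_mask=cov_mask).data
        if not np.all(np.isfinite(z0_hat)):
            raise FloatingPointError(f"non-finite denoiser output at step t={t}")
        mean, var = posterior_params(z0_hat, z, t, schedule)
        if t > 1:
            z = mean + np.sqrt(var) * rng.standard_normal(mean.shape)
        else:
            z = mean
    return z


@dataclass
class PriorTrainConfig:
    """Optimizer settings for the diffusion prior (reference defaults)."""

    lr: float = 0.31e-4
    weight_decay: float = 0.752
    max_grad_norm: float = 0.5
    ema_beta: float = 0.98
    ema_update_every: int = 100
    steps: int = 2000
    batch_size: int = 64
    seed: int = 0


def train_prior(z_face: np.ndarray, z_snp: np.ndarray, net: PriorNet,
                schedule: DiffusionSchedule, cfg: PriorTrainConfig,
                covariates: dict[str, np.ndarray] | None = None,
                cov_mask: set[str] | None = None,
                log=None) -> tuple[PriorNet, EMA, list[float]]:
    """Train the denoiser on precomputed (face, SNP) embedding pairs.

    The stage-1 encoders stay frozen: only their outputs enter here.
    Gradients are clipped to ``max_grad_norm``; an EMA of the weights is
    maintained and used for sampling by default.
    """
    z_face = np.asarray(z_face, dtype=np.float64)
    z_snp = np.asarray(z_snp, dtype=np.float64)
    n = z_face.shape[0]
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW([{"params": net.parameters(), "lr": cfg.lr,
                  "weight_decay": cfg.weight_decay}])
    ema = EMA(net, beta=cfg.ema_beta, update_every=cfg.ema_update_every)
    net.train()
    history: list[float] = []
    for step in range(cfg.steps):
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        cov_b = ({k: np.asarray(v)[idx] for k, v in covariates.items()}
                 if covariates else None)
        loss = prior_loss(net, z_face[idx], z_snp[idx], schedule, rng,
                          covariates=cov_b, cov_mask=cov_mask)
        val = float(loss.data)
        if not np.isfinite(val):
            raise FloatingPointError(f"NaN/inf diffusion loss at step {step}")
        opt.zero_grad()
        loss.backward()
        clip_grad_norm(net.parameters(), cfg.max_grad_norm)
        opt.step()
        ema.update(net)
        history.append(val)
        if log is not None and (step % 100 == 0 or step == cfg.steps - 1):
            log({"stage": "prior", "step": step, "loss": val})
    return net, ema, history
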