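"""Neural-network building blocks on top of :mod:`genoface.autodiff`.

Layers follow the usual conventions (Glorot/He initialisation, pre-norm
transformer blocks, AdamW with decoupled weight decay) so the printed
architecture hyperparameters — model dim, feed-forward dim, head counts,
dropout, layer-norm epsilon — map one-to-one onto constructor arguments.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module", "Linear", "LayerNorm", "Dropout", "MultiheadSelfAttention",
    "TransformerEncoderLayer", "AdamW", "StepLR", "EMA", "clip_grad_norm",
]


class Module:
    """Container of parameters and sub-modules with torch-like traversal."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / (in_dim + out_dim))
        self.weight = Tensor(rng.normal(0.0, scale, size=(in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; a shared Generator makes training reproducible."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 head_dim: int | None = None, dropout: float = 0.0):
        super().__init__()
        self.heads = heads
        self.head_dim = head_dim if head_dim is not None else dim // heads
        inner = self.heads * self.head_dim
        self.q = Linear(dim, inner, rng)
        self.k = Linear(dim, inner, rng)
        self.v = Linear(dim, inner, rng)
        self.out = Linear(inner, dim, rng)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, L, D)
        B, L, _ = x.shape
        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, self.heads, self.head_dim).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.head_dim))
        attn = self.drop(scores.softmax(axis=-1))
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, self.heads * self.head_dim)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Pre-norm transformer block with ReLU feed-forward."""

    def __init__(self, dim: int, heads: int, ff_dim: int, rng: np.random.Generator,
                 dropout: float = 0.1, layernorm_eps: float = 1e-5,
                 head_dim: int | None = None):
        super().__init__()
        self.norm1 = LayerNorm(dim, eps=layernorm_eps)
        self.attn = MultiheadSelfAttention(dim, heads, rng, head_dim=head_dim, dropout=dropout)
        self.drop1 = Dropout(dropout, rng)
        self.norm2 = LayerNorm(dim, eps=layernorm_eps)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.drop1(self.attn(self.norm1(x)))
        x = x + self.drop2(self.ff2(self.drop2(self.ff1(self.norm2(x)).relu())))
        return x


# --------------------------------------------------------------------------
# optimisation
# --------------------------------------------------------------------------

class AdamW(Module):
    """Adam with decoupled weight decay and per-group hyperparameters.

    ``groups`` is a list of dicts with keys ``params``, ``lr``, ``weight_decay``.
    """

    def __init__(self, groups: list[dict], betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__()
        self.groups = []
        for g in groups:
            self.groups.append({
                "params": list(g["params"]),
                "lr": float(g["lr"]),
                "weight_decay": float(g.get("weight_decay", 0.0)),
            })
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for g in self.groups:
            lr, wd = g["lr"], g["weight_decay"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                key = id(p)
                m = self._m.get(key)
                if m is None:
                    m = np.zeros_like(p.data)
                    self._v[key] = np.zeros_like(p.data)
                v = self._v[key]
                m[:] = b1 * m + (1 - b1) * p.grad
                v[:] = b2 * v + (1 - b2) * p.grad**2
                self._m[key] = m
                mh = m / (1 - b1**self.t)
                vh = v / (1 - b2**self.t)
                if wd:
                    p.data *= 1.0 - lr * wd
                p.data -= lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.grad = None


class StepLR:
    """Multiply every group's learning rate by ``gamma`` once per epoch."""

    def __init__(self, opt: AdamW, gamma: float):
        self.opt = opt
        self.gamma = float(gamma)

    def step(self):
        for g in self.opt.groups:
            g["lr"] *= self.gamma


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class EMA:
    """Exponential moving average of a module's parameters.

    ``beta`` is the decay toward the running average:
    ``ema = beta * ema + (1 - beta) * current``; ``beta = 0`` tracks the raw
    weights exactly.
    """

    def __init__(self, module: Module, beta: float = 0.98, update_every: int = 1):
        self.beta = float(beta)
        self.update_every = int(update_every)
        self._step = 0
        self.shadow = {k: v.copy() for k, v in module.state_dict().items()}

    def update(self, module: Module):
        self._step += 1
        if self._step % self.update_every:
            return
        for k, v in module.state_dict().items():
            self.shadow[k] = self.beta * self.shadow[k] + (1.0 - self.beta) * v

    def copy_to(self, module: Module):
        module.load_state_dict(self.shadow)
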