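"""Encoders and decoder: spiral-convolution face autoencoder and
transformer SNP encoder.

Three parameterised function families map between modalities and a shared
latent space:

* ``FaceEncoder`` — spiral convolutions with pooling over a fixed mesh
  hierarchy, ending in a fully connected layer to the latent embedding
  ``z_f``.  The reference architecture is
  ``3 x {Conv(32) -> Pool(4)} -> {Conv(64) -> Pool(4)} -> FC(128)`` with
  ReLU after every convolution and spiral lengths [9, 9, 9, 9].
* ``FaceDecoder`` — the encoder reversed, with unpooling in place of
  pooling and one extra convolution with output dimension 3 to produce
  coordinates.
* ``SnpEncoder`` — the allele-dosage vector is chunked into a token
  sequence, each chunk linearly projected (the dimensionality-reduction
  MLP), combined with learned positional encodings, and passed through a
  transformer encoder (reference: 2 layers, model dim 128, 8 heads,
  feed-forward dim 512, dropout 0.1, layer-norm eps 1e-5).  The output of
  a learned pooling token is the SNP embedding ``z_s``.

All sizes are configuration-driven so a desk-scale synthetic mesh (642
vertices, latent 32) and the full-scale face configuration (7906
vertices, latent 128) share one code path.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat
from .hierarchy import MeshHierarchy
from .mesh import TriMesh
from .nn import Dropout, Linear, Module, TransformerEncoderLayer
from .spiral import SpiralTable, build_spirals

__all__ = [
    "FaceAutoencoderSpec", "SnpEncoderSpec", "SpiralConv",
    "FaceEncoder", "FaceDecoder", "SnpEncoder",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class FaceAutoencoderSpec:
    """Architecture of the mesh autoencoder (reference values as defaults)."""

    conv_channels: list[int] = field(default_factory=lambda: [32, 32, 32, 64])
    pool_factors: list[int] = field(default_factory=lambda: [4, 4, 4, 4])
    spiral_lengths: list[int] = field(default_factory=lambda: [9, 9, 9, 9])
    spiral_dilations: list[int] = field(default_factory=lambda: [1, 1, 1, 1])
    latent: int = 128

    def __post_init__(self):
        n = len(self.conv_channels)
        if not (len(self.pool_factors) == len(self.spiral_lengths)
                == len(self.spiral_dilations) == n):
            raise ValueError("conv_channels, pool_factors, spiral_lengths, "
                             "spiral_dilations must have equal length")


@dataclass
class SnpEncoderSpec:
    """Architecture of the SNP transformer encoder."""

    model_dim: int = 128
    ff_dim: int = 512
    layers: int = 2
    heads: int = 8
    dropout: float = 0.1
    layernorm_eps: float = 1e-5
    chunk_size: int = 128  # SNPs per token
    latent: int = 128
    input_dropout: float = 0.0  # per-SNP dropout on the dosage vector
    pooling: str = "token"  # 'token': learned pooling token; 'mean': average


class SpiralConv(Module):
    """Spiral convolution: gather features along each vertex's spiral
    sequence, concatenate, and apply a shared linear map (gamma).

    The output at vertex i depends only on the features at S(i, l); padded
    slots read as zeros.
    """

    def __init__(self, in_ch: int, out_ch: int, spirals: SpiralTable,
                 rng: np.random.Generator):
        super().__init__()
        self.spirals = spirals
        self.in_ch = in_ch
        self.gamma = Linear(spirals.length * in_ch, out_ch, rng)

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, V, C); append the zero pad row so pad_index gathers zeros
        B, V, C = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {C}")
        seq = self.spirals.sequences
        if V != seq.shape[0]:
            raise ValueError(f"feature rows ({V}) do not align with spiral rows ({seq.shape[0]})")
        padded = concat([x, Tensor(np.zeros((B, 1, C)))], axis=1)
        gathered = padded[:, seq]  # (B, V, l, C)
        return self.gamma(gathered.reshape(B, V, seq.shape[1] * C))


class _Pool(Module):
    def __init__(self, mat: np.ndarray):
        super().__init__()
        self.mat = np.asarray(mat.todense() if hasattr(mat, "todense") else mat,
                              dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        return Tensor(self.mat) @ x


class FaceEncoder(Module):
    """Spiral-conv encoder from registered mesh coordinates to ``z_f``.

    Input coordinates are centred by the template before convolution so
    the network models shape deviation, not absolute position.
    """

    def __init__(self, spec: FaceAutoencoderSpec, hierarchy: MeshHierarchy,
                 rng: np.random.Generator):
        super().__init__()
        if len(spec.conv_channels) != len(hierarchy.down_maps):
            raise ValueError("spec stages must match hierarchy depth")
        self.spec = spec
        self.template = hierarchy.levels[0].vertices.copy()
        chans = [3] + list(spec.conv_channels)
        self._stages = []
        for i, (cin, cout) in enumerate(zip(chans[:-1], chans[1:])):
            spir = build_spirals(hierarchy.levels[i], spec.spiral_lengths[i],
                                 spec.spiral_dilations[i])
            conv = SpiralConv(cin, cout, spir, rng)
            pool = _Pool(hierarchy.down_maps[i])
            setattr(self, f"conv{i}", conv)
            setattr(self, f"pool{i}", pool)
            self._stages.append((conv, pool))
        v_last = hierarchy.levels[-1].n_vertices
        self.fc = Linear(v_last * chans[-1], spec.latent, rng)
        self._v_in = hierarchy.levels[0].n_vertices

    def forward(self, vertices: Tensor) -> Tensor:
        # vertices: (B, V, 3) -> (B, latent)
        if vertices.shape[-2] != self._v_in:
            raise ValueError(f"expected {self._v_in} vertices, got {vertices.shape[-2]}")
        x = vertices - Tensor(self.template)
        for conv, pool in self._stages:
            x = pool(conv(x).relu())
        B = x.shape[0]
        return self.fc(x.reshape(B, x.shape[1] * x.shape[2]))


class FaceDecoder(Module):
    """Mirror of the encoder: FC, then {unpool -> conv} per level, plus a
    final convolution with output dimension 3.  Outputs are offsets added
    to the template, so a zero latent decodes near the template shape."""

    def __init__(self, spec: FaceAutoencoderSpec, hierarchy: MeshHierarchy,
                 rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.template = hierarchy.levels[0].vertices.copy()
        chans = list(spec.conv_channels)  # e.g. [32, 32, 32, 64]
        v_last = hierarchy.levels[-1].n_vertices
        self._c0 = chans[-1]
        self._v0 = v_last
        self.fc = Linear(spec.latent, v_last * chans[-1], rng)
        rev_channels = list(reversed(chans))  # [64, 32, 32, 32]
        out_chans = rev_channels[1:] + [rev_channels[-1]]
        self._stages = []
        n = len(hierarchy.down_maps)
        for i in range(n):
            level = n - 1 - i  # unpool from level+1 up to level
            unpool = _Pool(hierarchy.up_maps[level])
            spir = build_spirals(hierarchy.levels[level],
                                 spec.spiral_lengths[level],
                                 spec.spiral_dilations[level])
            conv = SpiralConv(rev_channels[i], out_chans[i], spir, rng)
            setattr(self, f"unpool{i}", unpool)
            setattr(self, f"conv{i}", conv)
            self._stages.append((unpool, conv))
        spir0 = build_spirals(hierarchy.levels[0], spec.spiral_lengths[0],
                              spec.spiral_dilations[0])
        self.final_conv = SpiralConv(out_chans[-1], 3, spir0, rng)

    def forward(self, z: Tensor) -> Tensor:
        # z: (B, latent) -> (B, V, 3)
        B = z.shape[0]
        x = self.fc(z).reshape(B, self._v0, self._c0)
        for unpool, conv in self._stages:
            x = conv(unpool(x)).relu()
        return self.final_conv(x) + Tensor(self.template)


class SnpEncoder(Module):
    """Transformer encoder from an m-SNP dosage vector to ``z_s``."""

    def __init__(self, n_snps: int, spec: SnpEncoderSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.n_snps = int(n_snps)
        self.n_tokens = int(np.ceil(self.n_snps / spec.chunk_size))
        # per-chunk projection: every SNP gets its own coefficient, so the
        # encoder contains the additive (linear) genotype->embedding map
        scale = np.sqrt(2.0 / (spec.chunk_size + spec.model_dim))
        self.token_weight = Tensor(
            rng.normal(0.0, scale, size=(self.n_tokens, spec.chunk_size, spec.model_dim)),
            requires_grad=True)
        self.token_bias = Tensor(np.zeros((self.n_tokens, spec.model_dim)),
                                 requires_grad=True)
        self.pos = Tensor(rng.normal(0, 0.02, size=(self.n_tokens + 1, spec.model_dim)),
                          requires_grad=True)
        self.pool_token = Tensor(rng.normal(0, 0.02, size=(spec.model_dim,)),
                                 requires_grad=True)
        for i in range(spec.layers):
            setattr(self, f"layer{i}",
                    TransformerEncoderLayer(spec.model_dim, spec.heads, spec.ff_dim,
                                            rng, dropout=spec.dropout,
                                            layernorm_eps=spec.layernorm_eps))
        self.drop = Dropout(spec.dropout, rng)
        self.input_drop = Dropout(spec.input_dropout, rng)
        self.head = Linear(spec.model_dim, spec.latent, rng)

    def forward(self, dosages: Tensor) -> Tensor:
        # dosages: (B, m) -> (B, latent)
        B, m = dosages.shape
        if m != self.n_snps:
            raise ValueError(f"expected panel of {self.n_snps} SNPs, got {m}")
        spec = self.spec
        dosages = self.input_drop(dosages)  # SNP-level dropout (train only)
        pad = self.n_tokens * spec.chunk_size - m
        if pad:
            dosages = concat([dosages, Tensor(np.zeros((B, pad)))], axis=1)
        chunks = dosages.reshape(B, self.n_tokens, 1, spec.chunk_size)
        tokens = (chunks @ self.token_weight).reshape(B, self.n_tokens, spec.model_dim)
        tokens = tokens + self.token_bias
        if spec.pooling == "token":
            pool = (Tensor(np.ones((B, 1, 1))) * self.pool_token.reshape(1, 1, spec.model_dim))
            x = concat([pool, tokens], axis=1) + self.pos
        elif spec.pooling == "mean":
            x = tokens + self.pos[1:]
        else:
            raise ValueError(f"unknown pooling {spec.pooling!r}")
        x = self.drop(x)
        for i in range(spec.layers):
            x = getattr(self, f"layer{i}")(x)
        if spec.pooling == "token":
            return self.head(x[:, 0, :])
        return self.head(x.mean(axis=1))


# --------------------------------------------------------------------------
# checkpoints: single-file .npz archive with config + weights + mesh hash
# --------------------------------------------------------------------------

def save_checkpoint(path, modules: dict[str, Module], config: dict,
                    mesh_hash: str | None = None) -> None:
    arrays: dict[str, np.ndarray] = {}
    for mod_name, mod in modules.items():
        for k, v in mod.state_dict().items():
            arrays[f"{mod_name}/{k}"] = v
    meta = {"config": config, "mesh_hash": mesh_hash,
            "modules": sorted(modules)}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta, default=_json_default).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def _json_default(o):
    if isinstance(o, np.generic):
        return o.item()
    if hasattr(o, "__dataclass_fields__"):
        return asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_checkpoint(path) -> tuple[dict[str, dict[str, np.ndarray]], dict]:
    """Return ({module: state_dict}, metadata)."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        states: dict[str, dict[str, np.ndarray]] = {m: {} for m in meta["modules"]}
        for key in data.files:
            if key == "__meta__":
                continue
            mod_name, param = key.split("/", 1)
            states[mod_name][param] = data[key]
    return states, meta
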