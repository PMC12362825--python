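"""Spiral convolution, encoders and decoder contracts."""

import numpy as np
import pytest

from genoface.autodiff import Tensor
from genoface.hierarchy import build_hierarchy
from genoface.networks import (FaceAutoencoderSpec, FaceDecoder, FaceEncoder,
                               SnpEncoder, SnpEncoderSpec, SpiralConv,
                               load_checkpoint, save_checkpoint)
from genoface.spiral import build_spirals


@pytest.fixture(scope="module")
def small_setup(icosphere_642):
    hier = build_hierarchy(icosphere_642, [4, 4])
    spec = FaceAutoencoderSpec(conv_channels=[8, 16], pool_factors=[4, 4],
                               spiral_lengths=[6, 6], spiral_dilations=[1, 1],
                               latent=16)
    return hier, spec


def spiral_conv_oracle(x, seq, W, b, pad_index):
    """Brute-force gather-concat-matmul reference."""
    B, V, C = x.shape
    out = []
    for bi in range(B):
        rows = []
        for v in range(V):
            feats = []
            for j in seq[v]:
                feats.append(np.zeros(C) if j == pad_index else x[bi, j])
            rows.append(np.concatenate(feats) @ W + b)
        out.append(rows)
    return np.asarray(out)


def test_spiral_conv_matches_bruteforce_oracle(grid_mesh):
    rng = np.random.default_rng(0)
    tab = build_spirals(grid_mesh, 5)
    conv = SpiralConv(3, 4, tab, rng)
    x = rng.normal(size=(2, grid_mesh.n_vertices, 3))
    got = conv(Tensor(x)).data
    want = spiral_conv_oracle(x, tab.sequences, conv.gamma.weight.data,
                              conv.gamma.bias.data, tab.pad_index)
    assert np.abs(got - want).max() < 1e-6


def test_spiral_conv_slot_zero_selector_is_identity(grid_mesh):
    rng = np.random.default_rng(1)
    tab = build_spirals(grid_mesh, 5)
    conv = SpiralConv(3, 3, tab, rng)
    W = np.zeros((5 * 3, 3))
    W[:3, :3] = np.eye(3)  # select the centre-vertex slot
    conv.gamma.weight.data = W
    conv.gamma.bias.data = np.zeros(3)
    x = rng.normal(size=(1, grid_mesh.n_vertices, 3))
    assert np.allclose(conv(Tensor(x)).data, x)


def test_spiral_conv_averaging_preserves_constant_field(icosphere_642):
    # every spiral row on the closed icosphere is full (no padding)
    rng = np.random.default_rng(2)
    tab = build_spirals(icosphere_642, 7)
    assert not np.any(tab.sequences == tab.pad_index)
    conv = SpiralConv(2, 2, tab, rng)
    W = np.tile(np.eye(2) / 7.0, (7, 1))
    conv.gamma.weight.data = W
    conv.gamma.bias.data = np.zeros(2)
    x = np.full((1, icosphere_642.n_vertices, 2), 1.7)
    assert np.allclose(conv(Tensor(x)).data, 1.7)


def test_face_encoder_output_shape_and_determinism(small_setup, icosphere_642):
    hier, spec = small_setup
    enc = FaceEncoder(spec, hier, np.random.default_rng(3)).eval()
    x = Tensor(np.stack([icosphere_642.vertices, icosphere_642.vertices * 1.01]))
    z = enc(x).data
    assert z.shape == (2, 16)
    assert np.all(np.isfinite(z))
    assert np.allclose(z[0], enc(Tensor(icosphere_642.vertices[None])).data[0])


def test_face_encoder_rejects_wrong_vertex_count(small_setup):
    hier, spec = small_setup
    enc = FaceEncoder(spec, hier, np.random.default_rng(4))
    with pytest.raises(ValueError, match="vertices"):
        enc(Tensor(np.zeros((1, 100, 3))))


def test_face_decoder_finite_and_deterministic(small_setup):
    hier, spec = small_setup
    dec = FaceDecoder(spec, hier, np.random.default_rng(5)).eval()
    z = Tensor(np.zeros((1, 16)))
    out1, out2 = dec(z).data, dec(z).data
    assert out1.shape == (1, 642, 3)
    assert np.all(np.isfinite(out1))
    assert np.array_equal(out1, out2)


@pytest.mark.parametrize("pooling", ["token", "mean"])
def test_snp_encoder_shape_contract_and_determinism(pooling):
    spec = SnpEncoderSpec(model_dim=32, ff_dim=64, layers=2, heads=4,
                          chunk_size=25, latent=16, pooling=pooling)
    enc = SnpEncoder(90, spec, np.random.default_rng(6)).eval()
    z = enc(Tensor(np.zeros((2, 90)))).data
    assert z.shape == (2, 16)
    assert np.all(np.isfinite(z))
    with pytest.raises(ValueError, match="panel"):
        enc(Tensor(np.zeros((1, 91))))


def test_snp_encoder_is_order_sensitive():
    spec = SnpEncoderSpec(model_dim=32, ff_dim=64, layers=2, heads=4,
                          chunk_size=25, latent=16)
    enc = SnpEncoder(100, spec, np.random.default_rng(7)).eval()
    rng = np.random.default_rng(8)
    x = rng.normal(size=(1, 100))
    base = enc(Tensor(x)).data
    # permute within one chunk
    within = x.copy()
    within[0, :25] = within[0, rng.permutation(25)]
    assert not np.allclose(enc(Tensor(within)).data, base)
    # swap two whole chunks: positional encodings must distinguish them
    chunks = x.copy()
    chunks[0, :25], chunks[0, 25:50] = x[0, 25:50].copy(), x[0, :25].copy()
    assert not np.allclose(enc(Tensor(chunks)).data, base)


def test_checkpoint_roundtrip(tmp_path, small_setup):
    hier, spec = small_setup
    rng = np.random.default_rng(9)
    enc = FaceEncoder(spec, hier, rng)
    path = tmp_path / "ck.npz"
    save_checkpoint(path, {"encoder": enc}, config={"latent": 16}, mesh_hash="abc")
    states, meta = load_checkpoint(path)
    enc2 = FaceEncoder(spec, hier, np.random.default_rng(10))
    enc2.load_state_dict(states["encoder"])
    for (_, a), (_, b) in zip(enc.named_parameters(), enc2.named_parameters()):
        assert np.array_equal(a.data, b.data)
    assert meta["mesh_hash"] == "abc"
    assert meta["config"]["latent"] == 16
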