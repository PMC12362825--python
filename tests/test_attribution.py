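"""Expected-gradients attribution and hypergeometric enrichment."""

import itertools
import math

import numpy as np
import pytest

from genoface.attribution import (AttributionResult, FeatureHead,
                                  filter_independent_loci,
                                  gradient_attribution,
                                  hypergeometric_enrichment, select_top_snps,
                                  train_feature_head)
from genoface.autodiff import Tensor
from genoface.networks import SnpEncoder, SnpEncoderSpec
from genoface.nn import Linear, Module


class _LinearModel(Module):
    """Identity 'encoder' + linear head: closed-form attribution target."""

    def __init__(self, w):
        super().__init__()
        self.w = np.asarray(w, dtype=np.float64)

    def eval(self):
        return self

    def parameters(self):
        return []


class _IdentityEncoder(_LinearModel):
    def forward(self, x):
        return x


class _LinearHead(_LinearModel):
    def __init__(self, w):
        super().__init__(w)
        self.fc2 = type("W", (), {"weight": Tensor(self.w)})()

    def forward(self, z):
        return z @ Tensor(self.w)


class TestGradientAttribution:
    def test_linear_model_matches_closed_form(self):
        rng = np.random.default_rng(0)
        m = 6
        w = rng.normal(size=(m, 2))
        enc, head = _IdentityEncoder(w), _LinearHead(w)
        x = rng.normal(size=(1, m))
        baselines = rng.normal(size=(40, m))
        attr = gradient_attribution(enc, head, x, baselines, seed=1,
                                    n_baselines=40, n_points=8)
        # for score_c = w_c . x the attribution is w_jc * (x_j - mean_b b_j)
        # with the baseline mean estimated from the sampled baselines
        for c in range(2):
            got = attr.per_class[c]
            # MC over baselines: tolerance from baseline spread
            want = w[:, c] * (x[0] - baselines.mean(axis=0))
            assert np.abs(got - want).max() < 0.25

    def test_zero_influence_snp_gets_zero_attribution(self):
        w = np.array([[1.0], [0.0], [2.0]])
        enc, head = _IdentityEncoder(w), _LinearHead(w)
        rng = np.random.default_rng(2)
        attr = gradient_attribution(enc, head, rng.normal(size=(2, 3)),
                                    rng.normal(size=(20, 3)), seed=3,
                                    n_baselines=10, n_points=5)
        assert np.allclose(attr.per_class[:, 1], 0.0)

    def test_completeness_property_through_real_encoder(self):
        spec = SnpEncoderSpec(model_dim=16, ff_dim=32, layers=1, heads=2,
                              dropout=0.0, chunk_size=10, latent=8)
        rng = np.random.default_rng(4)
        enc = SnpEncoder(20, spec, rng).eval()
        head = FeatureHead(8, 2, rng)
        x = rng.normal(size=(1, 20))
        baselines = rng.normal(size=(5, 20))
        attr = gradient_attribution(enc, head, x, baselines, seed=5,
                                    n_baselines=5, n_points=200)

        def score(v, c):
            return float(head(enc(Tensor(v)))[:, c].sum().data)

        for c in range(2):
            total = attr.per_class[c].sum()
            want = score(x, c) - np.mean([score(b[None], c) for b in baselines])
            assert abs(total - want) < 0.05 * max(1.0, abs(want))

    def test_empty_baselines_rejected(self):
        w = np.ones((2, 1))
        with pytest.raises(ValueError, match="baseline"):
            gradient_attribution(_IdentityEncoder(w), _LinearHead(w),
                                 np.zeros((1, 2)), np.zeros((0, 2)))


class TestTopK:
    def _attr(self, scores):
        scores = np.asarray(scores, dtype=np.float64)
        return AttributionResult(snp_ids=[f"s{i}" for i in range(len(scores))],
                                 per_class=scores[None], mean_abs=np.abs(scores),
                                 n_baselines=1, n_points=1, seed=0)

    def test_full_panel_returns_everything(self):
        top = select_top_snps(self._attr([3, 1, 2]), 3)
        assert set(top) == {"s0", "s1", "s2"}

    def test_selects_largest_scores(self):
        assert select_top_snps(self._attr([3, 1, 2]), 2) == ["s0", "s2"]

    def test_ties_break_toward_lower_index(self):
        assert select_top_snps(self._attr([1, 1, 1, 1]), 2) == ["s0", "s1"]

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            select_top_snps(self._attr([1, 2]), 0)
        with pytest.raises(ValueError):
            select_top_snps(self._attr([1, 2]), 5)

    def test_independent_loci_filter_keeps_best_per_locus(self):
        attr = self._attr([5, 4, 1, 9])
        filtered = filter_independent_loci(attr, np.array([0, 0, 1, 1]))
        assert select_top_snps(filtered, 2) == ["s3", "s0"]


class TestHypergeometric:
    def test_zero_overlap_gives_p_one(self):
        res = hypergeometric_enrichment({"a"}, {"b"}, panel_size=10)
        assert res.p_value == 1.0 and res.overlap == 0

    def test_full_overlap_small_panel_closed_form(self):
        snps = {f"s{i}" for i in range(5)}
        res = hypergeometric_enrichment(snps, snps, panel_size=10)
        assert np.isclose(res.p_value, 1 / math.comb(10, 5))

    @pytest.mark.parametrize("panel,k_gwas,k_top,overlap", [
        (10, 4, 3, 2), (12, 5, 5, 3), (15, 6, 4, 1)])
    def test_matches_exhaustive_subset_enumeration(self, panel, k_gwas, k_top, overlap):
        gwas = set(range(k_gwas))
        hits = 0
        total = 0
        for top in itertools.combinations(range(panel), k_top):
            total += 1
            if len(gwas & set(top)) >= overlap:
                hits += 1
        want = hits / total
        top_set = set(range(overlap)) | set(range(k_gwas, k_gwas + k_top - overlap))
        res = hypergeometric_enrichment({str(i) for i in top_set},
                                        {str(i) for i in gwas}, panel_size=panel)
        assert np.isclose(res.p_value, want, atol=1e-12)

    def test_matches_direct_pmf_tail_sum(self):
        panel, k_gwas, k_top, overlap = 100, 10, 10, 3
        want = sum(math.comb(k_gwas, i) * math.comb(panel - k_gwas, k_top - i)
                   for i in range(overlap, min(k_gwas, k_top) + 1)) / math.comb(panel, k_top)
        top = {str(i) for i in range(overlap)} | {f"x{i}" for i in range(k_top - overlap)}
        gwas = {str(i) for i in range(overlap)} | {f"g{i}" for i in range(k_gwas - overlap)}
        res = hypergeometric_enrichment(top, gwas, panel_size=panel)
        assert np.isclose(res.p_value, want, atol=1e-12)

    def test_empty_sets_warn(self):
        with pytest.warns(UserWarning):
            res = hypergeometric_enrichment(set(), {"a"}, panel_size=5)
        assert res.p_value == 1.0


def test_feature_head_trains_on_separable_embeddings():
    rng = np.random.default_rng(6)
    z = rng.normal(size=(200, 8))
    labels = (z[:, 0] > 0).astype(int)
    head = train_feature_head(z, labels, latent=8, seed=0, epochs=150)
    pred = np.argmax(head(Tensor(z)).data, axis=1)
    assert (pred == labels).mean() > 0.95
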