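"""Identification, verification, geometry, DPP and classification metrics."""

import numpy as np
import pytest

from genoface.evaluation import (SimilarityMatrix, chamfer_distance,
                                 cosine_similarity_matrix, dpp_diversity,
                                 feature_classification, geometry_errors,
                                 identification_rates, verification_metrics)


class TestIdentification:
    def test_identity_matrix_gives_perfect_rank1(self):
        sim = SimilarityMatrix(np.eye(20))
        rates = identification_rates(sim, [1, 10, 100])
        assert rates[1] == 100.0
        assert rates[100] == 100.0

    def test_all_wrong_matches_give_zero_at_rank1(self):
        n = 100
        scores = np.fliplr(np.eye(n))  # best match is always the anti-diagonal
        np.fill_diagonal(scores, -1.0)
        sim = SimilarityMatrix(scores)
        assert identification_rates(sim, [1])[1] == 0.0

    def test_rank_100_percent_is_always_full(self):
        rng = np.random.default_rng(0)
        sim = SimilarityMatrix(rng.normal(size=(37, 37)))
        assert identification_rates(sim, [100])[100] == 100.0

    def test_random_scores_match_chance_level(self):
        rng = np.random.default_rng(1)
        sim = SimilarityMatrix(rng.normal(size=(1000, 1000)))
        rate = identification_rates(sim, [10])[10]
        assert abs(rate - 10.0) < 3.0  # ~binomial CI at n=1000

    def test_ties_break_by_stable_gallery_order(self):
        scores = np.zeros((3, 3))  # all tied: query i's match ranks at i+1
        sim = SimilarityMatrix(scores)
        ranks_pct = identification_rates(sim, [33, 66, 100])
        assert ranks_pct[33] == pytest.approx(100 / 3, abs=1e-9)
        assert ranks_pct[66] == pytest.approx(200 / 3, abs=1e-9)
        assert ranks_pct[100] == 100.0


class TestVerification:
    def test_perfect_separation(self):
        n = 10
        scores = np.full((n, n), -1.0)
        np.fill_diagonal(scores, 1.0)
        eer, auc = verification_metrics(SimilarityMatrix(scores))
        assert eer == 0.0 and auc == 100.0

    def test_identical_distributions_are_chance_level(self):
        eer, auc = verification_metrics(SimilarityMatrix(np.zeros((8, 8))))
        assert eer == 50.0 and auc == 50.0

    def test_small_matrix_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(4, 4))
        scores += 2 * np.eye(4)
        genuine = np.diag(scores)
        impostor = scores[~np.eye(4, dtype=bool)]
        # oracle: sweep every observed score as threshold, trapezoid AUC
        thr = np.unique(np.concatenate([genuine, impostor]))[::-1]
        tpr = [0.0] + [np.mean(genuine >= t) for t in thr] + [1.0]
        fpr = [0.0] + [np.mean(impostor >= t) for t in thr] + [1.0]
        auc_oracle = 100 * np.trapezoid(tpr, fpr)
        eer, auc = verification_metrics(SimilarityMatrix(scores))
        assert np.isclose(auc, auc_oracle, atol=1e-9)
        assert 0.0 <= eer <= 100.0

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(12, 12)) + 1.5 * np.eye(12)
        _, auc1 = verification_metrics(SimilarityMatrix(scores))
        _, auc2 = verification_metrics(SimilarityMatrix(np.exp(scores / 2)))
        assert np.isclose(auc1, auc2, atol=1e-9)


class TestGeometry:
    def test_identical_meshes_have_zero_error(self):
        v = np.random.default_rng(4).normal(size=(30, 3))
        out = geometry_errors(v, v)
        assert out["mean_mm"] == out["rmse_mm"] == out["chamfer_mm"] == 0.0

    def test_rigid_translation_error_equals_offset(self):
        v = np.random.default_rng(5).normal(size=(30, 3))
        out = geometry_errors(v + np.array([3.0, 0, 0]), v)
        assert np.isclose(out["mean_mm"], 3.0)
        assert np.isclose(out["rmse_mm"], 3.0)

    def test_chamfer_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        d = np.linalg.norm(a[:, None] - b[None], axis=-1)
        want = (d.min(axis=1).mean() + d.min(axis=0).mean()) / 2
        assert np.isclose(chamfer_distance(a, b), want, atol=1e-12)

    def test_topology_mismatch_rejected(self):
        with pytest.raises(ValueError, match="topology"):
            geometry_errors(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_landmark_table(self):
        v = np.zeros((10, 3))
        p = v.copy()
        p[3] += [0, 4.0, 0]
        out = geometry_errors(p, v, landmark_ids={"pn": 3, "n": 5})
        table = dict(zip(out["landmarks"]["landmark"], out["landmarks"]["error_mm"]))
        assert table == {"pn": 4.0, "n": 0.0}


class TestDpp:
    def test_single_item_scores_one(self):
        assert np.isclose(dpp_diversity(np.zeros((1, 4)), dist="embedding",
                                        jitter=0.0), 1.0)

    def test_identical_items_score_zero(self):
        items = np.tile(np.arange(4.0), (2, 1))
        assert np.isclose(dpp_diversity(items, dist="embedding", jitter=0.0), 0.0)

    def test_two_points_at_unit_distance_score_three_quarters(self):
        items = np.array([[0.0], [1.0]])
        assert np.isclose(dpp_diversity(items, dist="embedding", jitter=0.0), 0.75)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(7)
        items = rng.normal(size=(6, 3))
        a = dpp_diversity(items, dist="embedding", jitter=0.0)
        b = dpp_diversity(items[rng.permutation(6)], dist="embedding", jitter=0.0)
        assert np.isclose(a, b, atol=1e-12)

    def test_moving_items_apart_never_decreases_two_item_score(self):
        prev = -1.0
        for d in (0.1, 0.5, 1.0, 5.0, 50.0):
            s = dpp_diversity(np.array([[0.0], [d]]), dist="embedding", jitter=0.0)
            assert s >= prev
            prev = s
        assert prev <= 1.0

    def test_mesh_distance_mode(self):
        # two meshes offset by 2 mm everywhere: mean per-vertex distance 2
        m0 = np.zeros((4, 5, 3))
        m0[1, :, 0] = 2.0
        score = dpp_diversity(m0[:2], dist="mesh", jitter=0.0)
        assert np.isclose(score, 1 - (1 / 3) ** 2)  # det [[1, 1/3], [1/3, 1]]


class TestFeatureClassification:
    def test_separable_labels_reach_high_accuracy(self):
        import pandas as pd
        rng = np.random.default_rng(8)
        z = rng.normal(size=(300, 8))
        labels = pd.DataFrame({"f": (z[:, 0] > 0).astype(int)})
        out = feature_classification(z[:200], labels.iloc[:200],
                                     z[200:], labels.iloc[200:], seed=0)
        assert out.loc[0, "accuracy_real"] > 0.9

    def test_shuffled_labels_hit_chance(self):
        import pandas as pd
        rng = np.random.default_rng(9)
        z = rng.normal(size=(400, 6))
        labels = pd.DataFrame({"f": rng.integers(0, 2, size=400)})
        out = feature_classification(z[:300], labels.iloc[:300],
                                     z[300:], labels.iloc[300:], seed=0)
        assert abs(out.loc[0, "accuracy_real"] - 0.5) < 0.15

    def test_single_class_feature_skipped_with_warning(self):
        import pandas as pd
        z = np.random.default_rng(10).normal(size=(50, 4))
        labels = pd.DataFrame({"f": np.zeros(50, dtype=int)})
        with pytest.warns(UserWarning, match="single class"):
            out = feature_classification(z[:40], labels.iloc[:40],
                                         z[40:], labels.iloc[40:])
        assert out.empty


def test_cosine_similarity_matrix_bounds_and_diagonal():
    rng = np.random.default_rng(11)
    z = rng.normal(size=(9, 5))
    sim = cosine_similarity_matrix(z, z)
    assert np.all(sim.scores <= 1 + 1e-12) and np.all(sim.scores >= -1 - 1e-12)
    assert np.allclose(np.diag(sim.scores), 1.0)
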