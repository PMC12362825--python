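"""Synthetic-data generator: genotypes, template, planted effects, labels."""

import numpy as np
import pandas as pd
import pytest

from genoface.simulate import (SimConfig, genotype_to_faces, make_dataset,
                               simulate_genotypes, template_mesh)


class TestGenotypes:
    def test_column_means_match_hwe_expectation(self):
        g = simulate_genotypes(10_000, 20, maf_range=(0.5, 0.5), seed=0)
        # dosage mean = 2 * MAF = 1.0; binomial CI at n=1e4
        assert np.abs(g.dosages.mean(axis=0) - 1.0).max() < 0.05

    def test_near_zero_maf_gives_nearly_all_zero_column(self):
        g = simulate_genotypes(500, 5, maf_range=(1e-6, 1e-6), seed=1)
        assert g.dosages.sum() == 0

    def test_same_seed_reproduces_matrix(self):
        a = simulate_genotypes(50, 30, seed=7)
        b = simulate_genotypes(50, 30, seed=7)
        assert np.array_equal(a.dosages, b.dosages)

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 10, maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            simulate_genotypes(10, 10, maf_range=(0.1, 0.7))

    def test_locus_tags_group_neighbouring_snps(self):
        g = simulate_genotypes(5, 10, seed=2, snps_per_locus=2)
        assert len(set(g.locus_tags)) == 5


class TestTemplate:
    def test_subdivision_vertex_count_formula(self):
        for level in (2, 3):
            mesh = template_mesh(level)
            assert mesh.n_vertices == 10 * 4**level + 2
            assert mesh.n_faces == 20 * 4**level
        assert template_mesh(3).n_vertices == 642

    def test_winding_is_consistent(self):
        template_mesh(2).validate()

    def test_region_masks_disjoint_and_nonempty(self):
        mesh = template_mesh(3)
        regions = mesh.metadata["regions"]
        for name in ("nose", "eyes", "cheeks", "face"):
            assert len(regions[name]) > 0
        combined = np.concatenate([regions["nose"], regions["eyes"],
                                   regions["cheeks"], regions["face"]])
        assert len(combined) == len(set(combined))

    def test_landmarks_exist_and_are_valid_vertices(self):
        mesh = template_mesh(3)
        lm = mesh.metadata["landmarks"]
        assert {"pronasale", "nasion", "glabella"} <= set(lm)
        for v in lm.values():
            assert 0 <= v < mesh.n_vertices


class TestGenotypeToFaces:
    def _tiny(self, noise=0.0, seed=0):
        cfg = SimConfig(n_samples=80, n_snps=30, template_level=2,
                        n_causal_per_feature=4, n_global_fields=1,
                        n_causal_per_global=3, noise_mm=noise, seed=seed)
        return make_dataset(cfg, return_truth=True), cfg

    def test_zero_effects_and_zero_noise_reproduce_template(self):
        from genoface.simulate import SimTruth
        (ds, truth), cfg = self._tiny()
        zero_truth = SimTruth(fields=truth.fields,
                              loadings=np.zeros_like(truth.loadings),
                              causal_snps={}, cov_fields={k: np.zeros_like(v)
                                                          for k, v in truth.cov_fields.items()},
                              noise_mm=0.0, seed=0)
        rng = np.random.default_rng(0)
        meshes, _ = genotype_to_faces(ds.template, ds.genotypes, zero_truth,
                                      ds.covariates, rng)
        assert np.allclose(meshes, ds.template.vertices[None])

    def test_regression_recovers_planted_effect_field_without_noise(self):
        (ds, truth), cfg = self._tiny(noise=0.0)
        g = ds.genotypes.dosages
        centred = g - g.mean(axis=0)
        dev = (ds.meshes - ds.template.vertices[None]).reshape(len(g), -1)
        # remove covariate contribution using the known fields
        for name in ("age", "sex", "bmi"):
            dev -= np.outer(ds.covariates[name].to_numpy(),
                            truth.cov_fields[name].ravel())
        beta, *_ = np.linalg.lstsq(centred, dev, rcond=None)
        B = truth.loadings @ truth.fields.reshape(truth.fields.shape[0], -1)
        assert np.abs(beta - B).max() < 1e-8

    def test_label_tertiles_are_balanced(self):
        cfg = SimConfig(n_samples=3000, n_snps=60, template_level=2,
                        n_causal_per_feature=5, n_global_fields=1,
                        n_causal_per_global=3, seed=3)
        ds = make_dataset(cfg)
        freqs = ds.feature_labels.apply(lambda c: c.value_counts(normalize=True))
        assert np.abs(freqs.to_numpy() - 1 / 3).max() < 0.02

    def test_noncausal_snps_have_zero_loadings(self):
        (ds, truth), cfg = self._tiny()
        causal_ids = {s for ids in truth.causal_snps.values() for s in ids}
        for j, sid in enumerate(ds.genotypes.snp_ids):
            if sid not in causal_ids:
                assert np.all(truth.loadings[j] == 0)

    def test_planted_fields_are_spatially_smooth(self):
        (ds, truth), cfg = self._tiny()
        adj = ds.template.vertex_adjacency()
        for field in truth.fields:
            lap = np.stack([field[v] - np.mean([field[u] for u in adj[v]], axis=0)
                            for v in range(len(field))])
            # Laplacian energy small relative to field energy
            assert (lap**2).mean() < 0.5 * (field**2).mean()


class TestMakeDataset:
    def test_split_fractions_and_alignment(self):
        ds = make_dataset(SimConfig(n_samples=100, n_snps=40, template_level=2,
                                    n_causal_per_feature=5, n_global_fields=1,
                                    n_causal_per_global=3, seed=4))
        assert len(ds.train_idx) == 80 and len(ds.test_idx) == 20
        assert not set(ds.train_idx) & set(ds.test_idx)
        assert ds.meshes.shape[0] == ds.genotypes.n_samples == 100

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = SimConfig(n_samples=30, n_snps=20, template_level=2,
                        n_causal_per_feature=3, n_global_fields=1,
                        n_causal_per_global=2, seed=5)
        make_dataset(cfg, out_dir=tmp_path / "a")
        make_dataset(cfg, out_dir=tmp_path / "b")
        for name in ("genotypes.tsv", "covariates.tsv", "feature_labels.tsv",
                     "split.tsv", "panel.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_gwas_sets_contain_causal_plus_decoys(self):
        ds, truth = make_dataset(SimConfig(n_samples=40, n_snps=60, template_level=2,
                                           n_causal_per_feature=5, n_global_fields=1,
                                           n_causal_per_global=3,
                                           n_decoys_per_gwas_set=4, seed=6),
                                 return_truth=True)
        for feat in ("nose_protrusion", "eye_depth", "cheek_width"):
            gwas = set(ds.gwas_sets[feat])
            causal = set(truth.causal_snps[feat])
            assert causal <= gwas
            assert len(gwas - causal) == 4

    def test_written_dataset_files_exist(self, tmp_path):
        cfg = SimConfig(n_samples=10, n_snps=12, template_level=2,
                        n_causal_per_feature=2, n_global_fields=1,
                        n_causal_per_global=2, seed=7)
        make_dataset(cfg, out_dir=tmp_path, write_meshes=True)
        for name in ("genotypes.tsv", "covariates.tsv", "feature_labels.tsv",
                     "panel.tsv", "split.tsv", "truth.json", "template.ply"):
            assert (tmp_path / name).exists()
        assert len(list((tmp_path / "meshes").glob("*.ply"))) == 10
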