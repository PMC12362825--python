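"""The desk-scale parameter-recovery experiment, end to end.

This is the package's integration benchmark: generate the default
synthetic cohort (n = 600, m = 400, 642-vertex template, strong planted
effects, small noise), train the contrastive alignment stage and the
diffusion prior, and measure on the held-out 20%:

* rank-k% identification and EER/AUC of SNP-vs-face embedding matching;
* mean per-vertex generation error against the mean-face baseline;
* DPP diversity of real vs generated face sets;
* per-feature classifier accuracy on real vs generated face latents;
* the SNP-deletion error curve and its fraction/error rank correlation;
* enrichment of planted causal SNPs among top attributions.

Everything is driven by one seed; the model/optimizer settings are the
desk preset of :mod:`genoface.config`.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .attribution import (gradient_attribution, hypergeometric_enrichment,
                          select_top_snps, train_feature_head)
from .config import RunConfig, stage_seed
from .diffusion import PriorNet, train_prior
from .dropout_experiment import dropout_curve
from .hierarchy import build_hierarchy
from .pipeline import Pipeline
from .report import full_evaluation, mean_face_baseline_error
from .simulate import make_dataset
from .training import train_alignment

__all__ = ["run_recovery_experiment"]


def run_recovery_experiment(seed: int = 0, config: RunConfig | None = None,
                            dropout_mask_seeds=(0, 1),
                            n_attr_samples: int = 20,
                            attr_features=("nose_protrusion", "eye_depth",
                                           "cheek_width"),
                            log=None) -> dict:
    """Run the full pipeline at desk scale and return every recovery metric.

    Returns a JSON-serialisable dict; see the module docstring for what is
    measured.  About ten minutes on one CPU.
    """
    cfg = config or RunConfig(seed=seed)
    if cfg.seed != seed:
        cfg = cfg.model_copy(update={"seed": seed})

    dataset, truth = make_dataset(cfg.sim.build(cfg.stage_seed("simulate")),
                                  return_truth=True)
    hier = build_hierarchy(dataset.template, cfg.face_model.pool_factors)
    face_spec = cfg.face_model.build()
    snp_spec = cfg.snp_model.build()

    enc, dec, snp_enc, align_hist = train_alignment(
        dataset, hier, cfg.align.build(cfg.stage_seed("align")),
        face_spec, snp_spec, log=log)

    schedule = cfg.schedule.build()
    prior_spec = cfg.prior_model.build(face_spec.latent)
    net = PriorNet(prior_spec, np.random.default_rng(cfg.stage_seed("prior")))
    pipe = Pipeline(template=dataset.template, hierarchy=hier,
                    face_spec=face_spec, snp_spec=snp_spec,
                    prior_spec=prior_spec, schedule=schedule,
                    encoder=enc, decoder=dec, snp_encoder=snp_enc, prior=net,
                    panel_mean=dataset.panel_mean,
                    snp_ids=dataset.genotypes.snp_ids)
    use_cov = bool(prior_spec.covariates)
    z_f_train = pipe.encode_faces(dataset.meshes[dataset.train_idx])
    z_s_train = pipe.encode_snps(dataset.genotypes.dosages[dataset.train_idx])
    net, ema, prior_hist = train_prior(
        z_f_train, z_s_train, net, schedule,
        cfg.prior_train.build(cfg.stage_seed("prior")),
        covariates=(dataset.covariate_arrays(dataset.train_idx) if use_cov else None),
        log=log)
    ema.copy_to(net)

    report = full_evaluation(pipe, dataset, seed=cfg.stage_seed("evaluate"),
                             rank_percents=cfg.evaluation.rank_percents,
                             n_dpp_items=cfg.evaluation.n_dpp_items,
                             use_covariates=use_cov)

    curve = dropout_curve(pipe, dataset, fractions=cfg.dropout.fractions,
                          mask_seeds=dropout_mask_seeds,
                          sample_seed=cfg.stage_seed("dropout"),
                          use_covariates=use_cov)
    whole = curve.summary[curve.summary.region == "whole_face"]
    rho = float(spearmanr(whole.fraction, whole.mean_error_mm).statistic)

    aseed = cfg.stage_seed("attribute")
    centred = dataset.centered_genotypes()
    enrichment = {}
    for feat in attr_features:
        labels = dataset.feature_labels[feat].to_numpy()
        head = train_feature_head(z_s_train, labels[dataset.train_idx],
                                  latent=face_spec.latent, seed=aseed)
        attr = gradient_attribution(
            pipe.snp_encoder, head,
            inputs=centred[dataset.test_idx[:n_attr_samples]],
            baselines=centred[dataset.train_idx], seed=aseed,
            n_baselines=cfg.attribute.n_baselines,
            n_points=cfg.attribute.n_points,
            snp_ids=dataset.genotypes.snp_ids)
        top = select_top_snps(attr, min(200, dataset.genotypes.n_snps))
        res = hypergeometric_enrichment(
            top, truth.causal_snps[feat],
            panel_size=dataset.genotypes.n_snps, feature=feat,
            k_top=len(top))
        enrichment[feat] = {"overlap": res.overlap,
                            "n_causal": len(truth.causal_snps[feat]),
                            "p_value": res.p_value}

    return {
        "seed": seed,
        "n_train": int(len(dataset.train_idx)),
        "n_test": int(len(dataset.test_idx)),
        "align_loss_first": align_hist[0]["loss_total"],
        "align_loss_last": align_hist[-1]["loss_total"],
        "prior_loss_first": float(prior_hist[0]),
        "prior_loss_last": float(np.mean(prior_hist[-50:])),
        "identification": report["identification"],
        "verification": report["verification"],
        "generation": report["generation"],
        "mean_face_baseline_mm": mean_face_baseline_error(dataset),
        "dpp": report["dpp"],
        "feature_classification": report["feature_classification"],
        "dropout_spearman": rho,
        "dropout_summary": whole.to_dict(orient="records"),
        "enrichment": enrichment,
    }
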