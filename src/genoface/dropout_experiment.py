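"""SNP-deletion study: how reconstruction degrades as the panel shrinks.

Forensic samples rarely yield the full SNP panel.  This experiment
evaluates the trained pipeline with only a fraction f of the panel
retained (0.1 .. 0.9): dropped SNPs are set to the training-panel mean
dosage (the imputation point, i.e. zero after centring), faces are
regenerated from the masked genotypes, and region-wise vertex errors are
tabulated.  No re-training is involved — the encoder sees a degraded
input, exactly as it would at casework time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PairedDataset
from .evaluation import geometry_errors
from .pipeline import Pipeline

__all__ = ["DropoutCurve", "subsample_panel", "dropout_curve"]

DEFAULT_FRACTIONS = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)


@dataclass
class DropoutCurve:
    """Tabulated error growth under panel subsampling.

    ``table`` has one row per (fraction, seed, region) with the mean
    per-vertex error in mm; ``summary`` aggregates over seeds.
    """

    fractions: list[float]
    retained_counts: list[int]
    table: pd.DataFrame
    summary: pd.DataFrame
    landmark_table: pd.DataFrame | None = None


def subsample_panel(dosages: np.ndarray, fraction: float, seed: int,
                    impute_values: np.ndarray) -> tuple[np.ndarray, int]:
    """Retain floor(fraction * m) uniformly chosen SNPs; impute the rest.

    Returns the masked dosage matrix and the retained count.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    dosages = np.asarray(dosages, dtype=np.float64)
    m = dosages.shape[1]
    count = int(np.floor(fraction * m))
    rng = np.random.default_rng(seed)
    keep = rng.choice(m, size=count, replace=False)
    masked = np.broadcast_to(np.asarray(impute_values, dtype=np.float64),
                             dosages.shape).copy()
    masked[:, keep] = dosages[:, keep]
    return masked, count


def dropout_curve(pipe: Pipeline, dataset: PairedDataset,
                  fractions=DEFAULT_FRACTIONS, mask_seeds=(0, 1, 2),
                  sample_seed: int = 0, regions=("whole_face", "nose", "eyes"),
                  use_covariates: bool = False) -> DropoutCurve:
    """Evaluate generation error on the test split at each panel fraction.

    For each fraction and mask seed, test genotypes are masked, faces are
    regenerated through the diffusion prior and decoder, and the mean
    per-vertex Euclidean error is computed overall and per region.
    """
    test_idx = np.asarray(dataset.test_idx)
    true_meshes = dataset.meshes[test_idx]
    raw = dataset.genotypes.dosages[test_idx]
    region_masks = _resolve_regions(pipe.template, regions)
    cov = dataset.covariate_arrays(test_idx) if use_covariates else None
    landmarks = pipe.template.metadata.get("landmarks", {})

    rows = []
    lm_rows = []
    for f in fractions:
        for ms in mask_seeds:
            masked, count = subsample_panel(raw, f, seed=ms,
                                            impute_values=dataset.panel_mean)
            gen = pipe.generate_faces(masked, seed=sample_seed + ms,
                                      covariates=cov)
            d = np.linalg.norm(gen - true_meshes, axis=-1)  # (n_test, V)
            for rname, mask in region_masks.items():
                if mask.size == 0:
                    raise ValueError(f"empty region mask {rname!r}")
                rows.append({"fraction": f, "retained": count, "mask_seed": ms,
                             "region": rname,
                             "mean_error_mm": float(d[:, mask].mean()),
                             "sd_mm": float(d[:, mask].mean(axis=1).std())})
            for lname, vid in landmarks.items():
                lm_rows.append({"fraction": f, "mask_seed": ms,
                                "landmark": lname,
                                "mean_error_mm": float(d[:, vid].mean())})
    table = pd.DataFrame(rows)
    summary = (table.groupby(["fraction", "region"], as_index=False)
               .agg(retained=("retained", "first"),
                    mean_error_mm=("mean_error_mm", "mean"),
                    sd_mm=("mean_error_mm", "std")))
    counts = (table.drop_duplicates("fraction").sort_values("fraction")
              ["retained"].tolist())
    lm_table = pd.DataFrame(lm_rows) if lm_rows else None
    return DropoutCurve(fractions=sorted(set(fractions)),
                        retained_counts=counts, table=table, summary=summary,
                        landmark_table=lm_table)


def _resolve_regions(template, names) -> dict[str, np.ndarray]:
    regions = template.metadata.get("regions", {})
    out = {}
    for name in names:
        if name == "whole_face":
            out[name] = np.arange(template.n_vertices)
        elif name in regions:
            out[name] = np.asarray(regions[name])
        else:
            raise KeyError(f"unknown region {name!r}; have {sorted(regions)}")
    return out
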