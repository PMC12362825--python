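"""Matching, verification, geometry, diversity and classification metrics.

These quantify how well the two embeddings align (rank-k% identification,
EER/AUC verification from the cosine-similarity matrix), how close
generated meshes are to the truth (per-vertex Euclidean error, RMSE,
symmetric chamfer distance, per-landmark tables), how diverse a set of
generated faces is (determinantal-point-process score), and whether
generated faces preserve categorical feature information (per-feature
classifier accuracy on latents, real vs generated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve
from sklearn.neural_network import MLPClassifier

from .mesh import TriMesh

__all__ = [
    "SimilarityMatrix", "cosine_similarity_matrix", "identification_rates",
    "verification_metrics", "geometry_errors", "chamfer_distance",
    "dpp_diversity", "feature_classification",
]


@dataclass
class SimilarityMatrix:
    """Query x gallery cosine similarities; row i's true match is column i
    when the gallery is the paired test set."""

    scores: np.ndarray
    query_ids: list | None = None
    gallery_ids: list | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-d")

    @property
    def is_square(self) -> bool:
        return self.scores.shape[0] == self.scores.shape[1]


def cosine_similarity_matrix(z_query: np.ndarray, z_gallery: np.ndarray,
                             query_ids=None, gallery_ids=None) -> SimilarityMatrix:
    q = np.asarray(z_query, dtype=np.float64)
    g = np.asarray(z_gallery, dtype=np.float64)
    qn = q / np.linalg.norm(q, axis=1, keepdims=True)
    gn = g / np.linalg.norm(g, axis=1, keepdims=True)
    return SimilarityMatrix(qn @ gn.T, query_ids, gallery_ids)


def _true_match_ranks(scores: np.ndarray) -> np.ndarray:
    """1-based rank of the diagonal entry in each row, ties broken by
    stable gallery order (equal scores at a lower index rank ahead)."""
    N = scores.shape[0]
    ranks = np.empty(N, dtype=np.int64)
    for i in range(N):
        order = np.argsort(-scores[i], kind="stable")
        ranks[i] = int(np.flatnonzero(order == i)[0]) + 1
    return ranks


def identification_rates(sim: SimilarityMatrix, rank_percents: list[float]
                         ) -> dict[float, float]:
    """Rank-k% identification rates (in %): the fraction of queries whose
    true match ranks within the top ceil(k/100 * N) gallery entries."""
    if not sim.is_square:
        raise ValueError("identification needs a square matched matrix")
    N = sim.scores.shape[0]
    if N == 0:
        raise ValueError("empty similarity matrix")
    ranks = _true_match_ranks(sim.scores)
    out = {}
    for k in rank_percents:
        cutoff = int(np.ceil(k / 100.0 * N))
        out[k] = 100.0 * float(np.mean(ranks <= cutoff))
    return out


def verification_metrics(sim: SimilarityMatrix) -> tuple[float, float]:
    """(EER %, AUC %) from genuine (diagonal) vs impostor (off-diagonal)
    scores.  EER is located where FPR equals 1 - TPR, with linear
    interpolation between ROC points; an all-constant score set is the
    declared degenerate case (EER 50, AUC 50)."""
    if not sim.is_square:
        raise ValueError("verification needs a square matched matrix")
    s = sim.scores
    N = s.shape[0]
    genuine = np.diag(s)
    mask = ~np.eye(N, dtype=bool)
    impostor = s[mask]
    scores = np.concatenate([genuine, impostor])
    labels = np.concatenate([np.ones(N), np.zeros(impostor.size)])
    if np.allclose(scores, scores[0]):
        return 50.0, 50.0
    fpr, tpr, _ = roc_curve(labels, scores)
    auc_val = _sk_auc(fpr, tpr)
    fnr = 1.0 - tpr
    diff = fpr - fnr
    idx = int(np.flatnonzero(diff >= 0)[0])
    if idx == 0 or diff[idx] == 0:
        eer = (fpr[idx] + fnr[idx]) / 2.0
    else:
        # linear interpolation of both rates between the bracketing points
        d0, d1 = diff[idx - 1], diff[idx]
        w = -d0 / (d1 - d0)
        eer_fpr = fpr[idx - 1] + w * (fpr[idx] - fpr[idx - 1])
        eer_fnr = fnr[idx - 1] + w * (fnr[idx] - fnr[idx - 1])
        eer = (eer_fpr + eer_fnr) / 2.0
    return 100.0 * float(eer), 100.0 * float(auc_val)


def chamfer_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric chamfer distance (mm): mean of the two directed mean
    nearest-neighbour distances between point clouds."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    d_ab = cKDTree(b).query(a)[0].mean()
    d_ba = cKDTree(a).query(b)[0].mean()
    return float((d_ab + d_ba) / 2.0)


def geometry_errors(pred: TriMesh | np.ndarray, true: TriMesh | np.ndarray,
                    landmark_ids: dict[str, int] | None = None) -> dict:
    """Vertex-wise Euclidean error statistics between registered meshes.

    Returns mean / RMSE / chamfer (all mm), the per-vertex distance array,
    and a per-landmark error table when ``landmark_ids`` is given.
    Vertex-wise metrics require identical topology (same vertex count and
    correspondence); chamfer does not.
    """
    pv = pred.vertices if isinstance(pred, TriMesh) else np.asarray(pred)
    tv = true.vertices if isinstance(true, TriMesh) else np.asarray(true)
    if pv.shape != tv.shape:
        raise ValueError(f"topology mismatch for vertex-wise error: {pv.shape} vs {tv.shape}")
    d = np.linalg.norm(pv - tv, axis=-1)
    out = {
        "per_vertex": d,
        "mean_mm": float(d.mean()),
        "rmse_mm": float(np.sqrt((d**2).mean())),
        "chamfer_mm": chamfer_distance(pv, tv),
    }
    if landmark_ids:
        out["landmarks"] = pd.DataFrame(
            {"landmark": list(landmark_ids),
             "error_mm": [float(d[i]) for i in landmark_ids.values()]})
    return out


def dpp_diversity(items: np.ndarray, dist: str = "mesh",
                  jitter_seed: int = 0, jitter: float = 1e-6) -> float:
    """Determinantal-point-process diversity: det K with
    K_ij = 1 / (1 + dist(c_i, c_j)).

    ``dist`` = 'mesh' treats items as (n, V, 3) meshes with mean
    per-vertex Euclidean distance; 'embedding' treats them as (n, d)
    vectors with Euclidean distance.  A tiny uniform diagonal jitter
    (<= ``jitter``, seed-controlled) guards against exact singularity.
    Identical items give ~0; well-separated items approach 1.
    """
    items = np.asarray(items, dtype=np.float64)
    n = items.shape[0]
    if n < 1:
        raise ValueError("need at least one item")
    flat = items.reshape(n, -1)
    if dist == "mesh":
        V = items.shape[1]
        diff = flat[:, None, :] - flat[None, :, :]
        D = np.linalg.norm(diff.reshape(n, n, V, 3), axis=-1).mean(axis=-1)
    elif dist == "embedding":
        diff = flat[:, None, :] - flat[None, :, :]
        D = np.linalg.norm(diff, axis=-1)
    else:
        raise ValueError(f"unknown dist {dist!r}")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    K = 1.0 / (1.0 + D)
    if jitter > 0:
        rng = np.random.default_rng(jitter_seed)
        K = K + np.diag(rng.uniform(0, jitter, size=n))
    return float(np.linalg.det(K))


def feature_classification(latents_train: np.ndarray, labels_train: pd.DataFrame,
                           latents_real: np.ndarray, labels_real: pd.DataFrame,
                           latents_generated: np.ndarray | None = None,
                           seed: int = 0, hidden: int = 32) -> pd.DataFrame:
    """Per-feature accuracy of a small MLP + softmax classifier.

    One classifier per feature column is trained on training-set latents
    of real meshes; accuracy is reported on test latents of real meshes
    and, if provided, of generated meshes (same true labels).  Features
    with a single observed class are skipped with a warning.
    """
    rows = []
    for feat in labels_train.columns:
        y_tr = labels_train[feat].to_numpy()
        if len(np.unique(y_tr)) < 2:
            warnings.warn(f"feature {feat!r} has a single class; skipped")
            continue
        clf = MLPClassifier(hidden_layer_sizes=(hidden,), max_iter=2000,
                            random_state=seed, alpha=1e-3)
        clf.fit(latents_train, y_tr)
        y_te = labels_real[feat].to_numpy()
        row = {"feature": feat,
               "accuracy_real": float(clf.score(latents_real, y_te))}
        if latents_generated is not None:
            row["accuracy_generated"] = float(clf.score(latents_generated, y_te))
        rows.append(row)
    return pd.DataFrame(rows)
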