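"""Synthetic paired genotype/face datasets with known ground truth.

No public cohort of paired genomes and registered 3D face scans exists,
so every stage of the pipeline is exercised on simulated data in which
the genotype-to-face map is planted and therefore checkable:

* genotypes are Hardy-Weinberg draws, dosage ~ Binomial(2, MAF), with
  MAFs uniform over a configured range;
* the template "face" is a subdivided icosphere (level 3 = 642 vertices)
  at head scale, with named pseudo-landmarks and nose/eye/cheek/face
  region masks derived from direction cones;
* each feature (nose protrusion, eye depth, cheek width) has a smooth
  radial bump deformation field over its region driven additively by a
  planted set of causal SNPs; additional global smooth fields add
  individual variation; covariates (standardized age/BMI, binary sex)
  contribute their own fields; i.i.d. Gaussian vertex noise is added;
* categorical feature labels are tertiles of landmark statistics of the
  generated geometry, so each label has a known causal SNP set;
* "GWAS-significant" SNP sets are the causal sets plus decoys, for the
  enrichment analysis.

The simulator makes no claim of facial or population-genetic realism
(no LD beyond locus tags, no ancestry structure); it provides
identifiable ground truth at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import trimesh as _trimesh

from .data import GenotypeMatrix, PairedDataset
from .mesh import TriMesh

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "template_mesh",
           "genotype_to_faces", "make_dataset", "landmark_statistics"]

_TEMPLATE_RADIUS_MM = 80.0

# direction cones defining pseudo-anatomy on the sphere (+x is "forward")
_REGION_CONES = {
    "nose": (np.array([1.0, 0.0, 0.0]), 0.92),
    "eye_left": (np.array([0.72, 0.45, 0.45]), 0.95),
    "eye_right": (np.array([0.72, -0.45, 0.45]), 0.95),
    "cheek_left": (np.array([0.72, 0.62, -0.2]), 0.95),
    "cheek_right": (np.array([0.72, -0.62, -0.2]), 0.95),
}

_LANDMARK_DIRS = {
    "pronasale": [1.0, 0.0, 0.0],
    "nasion": [0.85, 0.0, 0.53],
    "glabella": [0.78, 0.0, 0.63],
    "subnasale": [0.95, 0.0, -0.3],
    "alare_left": [0.9, 0.42, 0.0],
    "alare_right": [0.9, -0.42, 0.0],
    "cheilion_left": [0.82, 0.5, -0.28],
    "cheilion_right": [0.82, -0.5, -0.28],
}


@dataclass
class SimConfig:
    """Study conditions of the desk-scale synthetic cohort."""

    n_samples: int = 600
    n_snps: int = 400
    template_level: int = 3
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_per_feature: int = 25
    n_global_fields: int = 3
    n_causal_per_global: int = 15
    feature_effect_mm: float = 1.5   # RMS vertex displacement per amplitude SD
    global_effect_mm: float = 1.5    # RMS vertex displacement per amplitude SD
    age_effect_mm: float = 0.5       # per SD of age
    sex_effect_mm: float = 1.0
    bmi_effect_mm: float = 0.5
    noise_mm: float = 0.2            # i.i.d. vertex noise sigma
    snps_per_locus: int = 2
    n_decoys_per_gwas_set: int = 10
    train_fraction: float = 0.8
    seed: int = 0


@dataclass
class SimTruth:
    """Planted parameters: deformation fields and per-SNP loadings.

    The per-SNP effect field is ``B_j = sum_k loadings[j, k] * fields[k]``
    (shape V x 3, mm per dosage unit); non-causal SNPs have zero rows.
    """

    fields: np.ndarray        # (r, V, 3) unit-scale smooth fields
    loadings: np.ndarray      # (m, r)
    causal_snps: dict[str, list[str]]
    cov_fields: dict[str, np.ndarray]   # name -> (V, 3)
    noise_mm: float
    seed: int

    def effect_field(self, j: int) -> np.ndarray:
        return np.tensordot(self.loadings[j], self.fields, axes=(0, 0))


def simulate_genotypes(n: int, m: int, maf_range=(0.05, 0.5),
                       seed: int = 0, snps_per_locus: int = 2) -> GenotypeMatrix:
    """HWE genotypes: per-SNP MAF ~ U(maf_range), dosage ~ Binomial(2, MAF)."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(np.float64)
    snp_ids = [f"rs{j:06d}" for j in range(m)]
    locus_tags = np.arange(m) // snps_per_locus
    return GenotypeMatrix(dosages, snp_ids, locus_tags, mafs=mafs)


def template_mesh(level: int = 3) -> TriMesh:
    """Subdivided icosphere template (level 3 -> 642 vertices) at head
    scale, with region masks and pseudo-landmark ids in ``metadata``."""
    if level < 1:
        raise ValueError("level must be >= 1")
    ico = _trimesh.creation.icosphere(subdivisions=level, radius=_TEMPLATE_RADIUS_MM)
    mesh = TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
    dirs = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    masks: dict[str, np.ndarray] = {}
    for name, (axis, thresh) in _REGION_CONES.items():
        axis = axis / np.linalg.norm(axis)
        masks[name] = np.flatnonzero(dirs @ axis > thresh)
    masks["eyes"] = np.concatenate([masks["eye_left"], masks["eye_right"]])
    masks["cheeks"] = np.concatenate([masks["cheek_left"], masks["cheek_right"]])
    special = set(np.concatenate([masks["nose"], masks["eyes"], masks["cheeks"]]))
    forward = np.flatnonzero(dirs[:, 0] > 0.15)
    masks["face"] = np.array(sorted(set(forward) - special))
    landmarks = {}
    for name, d in _LANDMARK_DIRS.items():
        d = np.asarray(d) / np.linalg.norm(d)
        landmarks[name] = int(np.argmax(dirs @ d))
    mesh.metadata["regions"] = masks
    mesh.metadata["landmarks"] = landmarks
    return mesh


def _smooth_field(template: TriMesh, rng: np.random.Generator,
                  iterations: int = 40) -> np.ndarray:
    """Random spatially smooth (V, 3) field, unit RMS, via repeated
    one-ring averaging (bounded Laplacian energy)."""
    adj = template.vertex_adjacency()
    V = template.n_vertices
    x = rng.standard_normal((V, 3))
    idx = [np.fromiter(a, dtype=np.int64) for a in adj]
    for _ in range(iterations):
        x = 0.5 * x + 0.5 * np.stack([x[i].mean(axis=0) for i in idx])
    return x / np.sqrt((x**2).mean())


def _bump_field(template: TriMesh, center_dirs: list[np.ndarray],
                width: float = 0.35) -> np.ndarray:
    """Smooth radial bump: displacement along the outward normal with a
    Gaussian profile in angle around each centre direction.

    Normalised to unit RMS over all vertices so that the effect scales in
    :class:`SimConfig` mean the same thing (mm of RMS vertex displacement
    per amplitude SD) for localised and global fields alike.
    """
    dirs = template.vertices / np.linalg.norm(template.vertices, axis=1, keepdims=True)
    w = np.zeros(template.n_vertices)
    for c in center_dirs:
        c = np.asarray(c, dtype=np.float64)
        c /= np.linalg.norm(c)
        ang = np.arccos(np.clip(dirs @ c, -1, 1))
        w += np.exp(-(ang**2) / (2 * width**2))
    field = w[:, None] * dirs
    return field / np.sqrt((field**2).mean())


def _plant_truth(template: TriMesh, geno: GenotypeMatrix,
                 cfg: SimConfig, rng: np.random.Generator) -> tuple[SimTruth, dict]:
    m = geno.n_snps
    feature_centers = {
        "nose_protrusion": [_REGION_CONES["nose"][0]],
        "eye_depth": [_REGION_CONES["eye_left"][0], _REGION_CONES["eye_right"][0]],
        "cheek_width": [_REGION_CONES["cheek_left"][0], _REGION_CONES["cheek_right"][0]],
    }
    fields = [ _bump_field(template, centers) for centers in feature_centers.values() ]
    for _ in range(cfg.n_global_fields):
        fields.append(_smooth_field(template, rng))
    fields = np.stack(fields)
    r = fields.shape[0]

    var_dosage = 2 * geno.mafs * (1 - geno.mafs)
    loadings = np.zeros((m, r))
    order = rng.permutation(m)
    causal: dict[str, list[str]] = {}
    cursor = 0
    for k, feat in enumerate(feature_centers):
        snps = order[cursor:cursor + cfg.n_causal_per_feature]
        cursor += cfg.n_causal_per_feature
        scale = cfg.feature_effect_mm / np.sqrt(var_dosage[snps].sum())
        signs = rng.choice([-1.0, 1.0], size=len(snps))
        loadings[snps, k] = signs * scale
        causal[feat] = [geno.snp_ids[j] for j in snps]
    for k in range(len(feature_centers), r):
        snps = order[cursor:cursor + cfg.n_causal_per_global]
        cursor += cfg.n_causal_per_global
        scale = cfg.global_effect_mm / np.sqrt(var_dosage[snps].sum())
        signs = rng.choice([-1.0, 1.0], size=len(snps))
        loadings[snps, k] = signs * scale
        causal[f"global_{k - len(feature_centers)}"] = [geno.snp_ids[j] for j in snps]

    cov_fields = {
        "age": cfg.age_effect_mm * _smooth_field(template, rng),
        "sex": cfg.sex_effect_mm * _smooth_field(template, rng),
        "bmi": cfg.bmi_effect_mm * _smooth_field(template, rng),
    }
    truth = SimTruth(fields=fields, loadings=loadings, causal_snps=causal,
                     cov_fields=cov_fields, noise_mm=cfg.noise_mm, seed=cfg.seed)
    summary = {
        "config": asdict(cfg),
        "causal_snps": causal,
        "n_effect_fields": int(r),
        "loadings_nonzero": int(np.count_nonzero(loadings)),
    }
    return truth, summary


def genotype_to_faces(template: TriMesh, geno: GenotypeMatrix, truth: SimTruth,
                      covariates: pd.DataFrame, rng: np.random.Generator
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the planted additive model and derive tertile feature labels.

    x_i = template + sum_j (g_ij - gbar_j) B_j + age_i B_age + sex_i B_sex
          + bmi_i B_bmi + eps,   eps ~ N(0, sigma^2) per coordinate.
    """
    if truth.noise_mm < 0:
        raise ValueError("noise sigma must be nonnegative")
    g = geno.dosages
    centred = g - g.mean(axis=0)
    amplitudes = centred @ truth.loadings                       # (n, r)
    meshes = (template.vertices[None] +
              np.tensordot(amplitudes, truth.fields, axes=(1, 0)))
    for name in ("age", "sex", "bmi"):
        meshes += covariates[name].to_numpy()[:, None, None] * truth.cov_fields[name][None]
    if truth.noise_mm > 0:
        meshes += truth.noise_mm * rng.standard_normal(meshes.shape)
    labels = feature_labels_from_geometry(template, meshes)
    return meshes, labels


def landmark_statistics(template: TriMesh, meshes: np.ndarray) -> pd.DataFrame:
    """Scalar geometry statistics behind the categorical feature labels:
    mean radial displacement over the relevant region masks."""
    regions = template.metadata["regions"]
    dirs = template.vertices / np.linalg.norm(template.vertices, axis=1, keepdims=True)

    def radial(mask):
        return np.einsum("nvc,vc->n", meshes[:, mask], dirs[mask]) / len(mask)

    return pd.DataFrame({
        "nose_protrusion": radial(regions["nose"]),
        "eye_depth": radial(regions["eyes"]),
        "cheek_width": radial(regions["cheeks"]),
    })


def feature_labels_from_geometry(template: TriMesh, meshes: np.ndarray) -> pd.DataFrame:
    """Tertile labels (0/1/2) of each landmark statistic."""
    stats = landmark_statistics(template, meshes)
    out = {}
    for col in stats.columns:
        q = np.quantile(stats[col], [1 / 3, 2 / 3])
        out[col] = np.digitize(stats[col], q)
    return pd.DataFrame(out)


def make_dataset(cfg: SimConfig | None = None, out_dir=None,
                 write_meshes: bool = False,
                 return_truth: bool = False):
    """Generate the full paired dataset (and optionally write it to disk).

    Returns a :class:`PairedDataset`; with ``return_truth=True`` also the
    :class:`SimTruth` carrying the planted deformation fields.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    geno = simulate_genotypes(cfg.n_samples, cfg.n_snps, cfg.maf_range,
                              seed=int(rng.integers(2**31)),
                              snps_per_locus=cfg.snps_per_locus)
    template = template_mesh(cfg.template_level)
    truth, summary = _plant_truth(template, geno, cfg, rng)

    age_raw = rng.uniform(18, 70, size=cfg.n_samples)
    covariates = pd.DataFrame({
        "age": (age_raw - age_raw.mean()) / age_raw.std(),
        "sex": rng.integers(0, 2, size=cfg.n_samples).astype(float),
        "bmi": rng.standard_normal(cfg.n_samples),
    })
    meshes, labels = genotype_to_faces(template, geno, truth, covariates, rng)

    perm = rng.permutation(cfg.n_samples)
    n_train = int(round(cfg.train_fraction * cfg.n_samples))
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])

    non_causal = sorted(set(geno.snp_ids)
                        - {s for ids in truth.causal_snps.values() for s in ids})
    gwas_sets = {}
    n_decoys = min(cfg.n_decoys_per_gwas_set, len(non_causal))
    for feat in ("nose_protrusion", "eye_depth", "cheek_width"):
        decoys = list(rng.choice(non_causal, size=n_decoys, replace=False))
        gwas_sets[feat] = sorted(truth.causal_snps[feat] + decoys)
    gwas_sets["pooled"] = sorted(set().union(*[set(v) for v in gwas_sets.values()]))

    dataset = PairedDataset(
        genotypes=geno, meshes=meshes, template=template, covariates=covariates,
        feature_labels=labels, train_idx=train_idx, test_idx=test_idx,
        gwas_sets=gwas_sets, truth=summary, seed=cfg.seed)
    if out_dir is not None:
        dataset.write(out_dir, write_meshes=write_meshes)
    if return_truth:
        return dataset, truth
    return dataset
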