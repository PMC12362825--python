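"""In-memory containers for paired genotype/mesh datasets and their
on-disk TSV / PLY / JSON representations."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import TriMesh, write_mesh

__all__ = ["GenotypeMatrix", "PairedDataset", "read_genotype_tsv", "read_vcf_dosages"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele dosages in [0, 2].

    ``locus_tags`` group SNPs into independent loci (used by the
    independent-loci filter in the attribution analysis).
    """

    dosages: np.ndarray          # (n, m) float
    snp_ids: list[str]
    locus_tags: np.ndarray       # (m,) int
    mafs: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.locus_tags = np.asarray(self.locus_tags)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-d (samples x SNPs)")
        if self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids length must match number of columns")
        if np.any(self.dosages < 0) or np.any(self.dosages > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, columns=self.snp_ids)


@dataclass
class PairedDataset:
    """Aligned (genotype, mesh, covariates, feature labels) records.

    ``meshes`` is (n, V, 3): every sample shares the template's topology.
    ``train_idx`` / ``test_idx`` realise the 80/20 split.  ``panel_mean``
    is the training-set mean dosage per SNP, used both to centre encoder
    inputs and as the imputation value for dropped SNPs.
    """

    genotypes: GenotypeMatrix
    meshes: np.ndarray
    template: TriMesh
    covariates: pd.DataFrame            # columns: age, sex, bmi (standardized where noted)
    feature_labels: pd.DataFrame        # categorical labels per feature
    train_idx: np.ndarray
    test_idx: np.ndarray
    gwas_sets: dict[str, list[str]] = field(default_factory=dict)
    truth: dict | None = None
    seed: int | None = None

    def __post_init__(self):
        self.meshes = np.asarray(self.meshes, dtype=np.float64)
        n = self.genotypes.n_samples
        if self.meshes.shape[0] != n:
            raise ValueError("one mesh per sample required")
        self.panel_mean = self.genotypes.dosages[self.train_idx].mean(axis=0)

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples

    def centered_genotypes(self, idx=None) -> np.ndarray:
        """Dosages centred by the training-panel mean (imputation point)."""
        d = self.genotypes.dosages if idx is None else self.genotypes.dosages[idx]
        return d - self.panel_mean

    def covariate_arrays(self, idx=None) -> dict[str, np.ndarray]:
        df = self.covariates if idx is None else self.covariates.iloc[idx]
        return {c: df[c].to_numpy() for c in df.columns}

    # ---- persistence -----------------------------------------------------
    def write(self, out_dir: str | Path, write_meshes: bool = False) -> None:
        """Write genotype/covariate/label TSVs, GWAS sets, truth JSON and
        (optionally) one PLY mesh per sample."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gframe = self.genotypes.to_frame()
        gframe.insert(0, "sample", [f"s{i:05d}" for i in range(self.n_samples)])
        gframe.to_csv(out / "genotypes.tsv", sep="\t", index=False, float_format="%.6g")
        self.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False,
                               float_format="%.6g")
        self.feature_labels.to_csv(out / "feature_labels.tsv", sep="\t", index=False)
        pd.DataFrame({
            "snp_id": self.genotypes.snp_ids,
            "locus_tag": self.genotypes.locus_tags,
        }).to_csv(out / "panel.tsv", sep="\t", index=False)
        split = np.full(self.n_samples, "train", dtype=object)
        split[self.test_idx] = "test"
        pd.DataFrame({"sample": gframe["sample"], "split": split}).to_csv(
            out / "split.tsv", sep="\t", index=False)
        for name, snps in self.gwas_sets.items():
            pd.DataFrame({"snp_id": snps, "p_value": 1e-9}).to_csv(
                out / f"gwas_{name}.tsv", sep="\t", index=False)
        if self.truth is not None:
            with open(out / "truth.json", "w") as fh:
                json.dump(self.truth, fh, indent=1, default=_jsonify)
        write_mesh(self.template, out / "template.ply", encoding="ascii")
        if write_meshes:
            mesh_dir = out / "meshes"
            mesh_dir.mkdir(exist_ok=True)
            for i in range(self.n_samples):
                write_mesh(self.template.with_vertices(self.meshes[i]),
                           mesh_dir / f"s{i:05d}.ply")


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.generic):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a genotype TSV (rows = samples, header = SNP ids, optional
    leading ``sample`` column)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] == "sample":
        df = df.drop(columns="sample")
    snp_ids = list(df.columns)
    return GenotypeMatrix(df.to_numpy(dtype=np.float64), snp_ids,
                          locus_tags=np.arange(len(snp_ids)))


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Minimal VCF reader: maps diploid GT fields to alt-allele dosages.

    Handles uncompressed VCF with GT as the first FORMAT key; missing
    genotypes ('./.') become the site's mean dosage.
    """
    ids, rows = [], []
    with open(path) as fh:
        samples = None
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if samples is None:
                raise ValueError(f"{path}: missing #CHROM header line")
            chrom, pos, vid = fields[0], fields[1], fields[2]
            ids.append(vid if vid != "." else f"{chrom}:{pos}")
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT")
            dosages = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_i]
                alleles = gt.replace("|", "/").split("/")
                if "." in alleles:
                    dosages.append(np.nan)
                else:
                    dosages.append(float(sum(int(a) > 0 for a in alleles)))
            rows.append(dosages)
    mat = np.asarray(rows, dtype=np.float64).T  # samples x snps
    col_mean = np.nanmean(mat, axis=0)
    nan_r, nan_c = np.where(np.isnan(mat))
    mat[nan_r, nan_c] = col_mean[nan_c]
    return GenotypeMatrix(mat, ids, locus_tags=np.arange(len(ids)))
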