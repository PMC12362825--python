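"""End-to-end bundle: trained encoders + decoder + diffusion prior.

``Pipeline`` holds everything needed to go from an allele-dosage vector
(plus optional covariates) to a generated 3D face mesh, and to embed
faces/SNPs for evaluation.  It serialises to a single ``.npz`` archive
containing the template mesh, variance schedule, panel statistics and
every module's weights.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor
from .diffusion import (DiffusionSchedule, PriorNet, PriorNetSpec, sample_prior)
from .hierarchy import MeshHierarchy, build_hierarchy, mesh_hash
from .mesh import TriMesh
from .networks import (FaceAutoencoderSpec, FaceDecoder, FaceEncoder,
                       SnpEncoder, SnpEncoderSpec)

__all__ = ["Pipeline"]


@dataclass
class Pipeline:
    template: TriMesh
    hierarchy: MeshHierarchy
    face_spec: FaceAutoencoderSpec
    snp_spec: SnpEncoderSpec
    prior_spec: PriorNetSpec
    schedule: DiffusionSchedule
    encoder: FaceEncoder
    decoder: FaceDecoder
    snp_encoder: SnpEncoder
    prior: PriorNet
    panel_mean: np.ndarray
    snp_ids: list[str]

    # ---- embedding ------------------------------------------------------
    def encode_faces(self, meshes: np.ndarray, batch: int = 128) -> np.ndarray:
        """(n, V, 3) vertex arrays -> (n, latent) face embeddings."""
        self.encoder.eval()
        out = []
        meshes = np.asarray(meshes, dtype=np.float64)
        for s in range(0, len(meshes), batch):
            out.append(self.encoder(Tensor(meshes[s:s + batch])).data)
        return np.concatenate(out)

    def encode_snps(self, dosages: np.ndarray, batch: int = 128) -> np.ndarray:
        """(n, m) raw dosages -> (n, latent) SNP embeddings (centred by the
        training panel mean internally)."""
        self.snp_encoder.eval()
        x = np.asarray(dosages, dtype=np.float64) - self.panel_mean
        out = []
        for s in range(0, len(x), batch):
            out.append(self.snp_encoder(Tensor(x[s:s + batch])).data)
        return np.concatenate(out)

    def decode(self, z: np.ndarray, batch: int = 128) -> np.ndarray:
        self.decoder.eval()
        z = np.asarray(z, dtype=np.float64)
        out = []
        for s in range(0, len(z), batch):
            out.append(self.decoder(Tensor(z[s:s + batch])).data)
        return np.concatenate(out)

    # ---- generation -----------------------------------------------------
    def generate_embeddings(self, dosages: np.ndarray, seed: int,
                            covariates: dict[str, np.ndarray] | None = None,
                            cov_mask: set[str] | None = None) -> np.ndarray:
        z_s = self.encode_snps(dosages)
        rng = np.random.default_rng(seed)
        return sample_prior(self.prior, z_s, self.schedule, rng,
                            covariates=covariates, cov_mask=cov_mask)

    def generate_faces(self, dosages: np.ndarray, seed: int,
                       covariates: dict[str, np.ndarray] | None = None,
                       cov_mask: set[str] | None = None) -> np.ndarray:
        """Dosages -> sampled face embeddings -> decoded (n, V, 3) meshes."""
        return self.decode(self.generate_embeddings(dosages, seed,
                                                    covariates, cov_mask))

    # ---- persistence ----------------------------------------------------
    def save(self, path) -> None:
        arrays: dict[str, np.ndarray] = {
            "template_vertices": self.template.vertices,
            "template_faces": self.template.faces,
            "betas": self.schedule.betas,
            "panel_mean": self.panel_mean,
        }
        modules = {"encoder": self.encoder, "decoder": self.decoder,
                   "snp_encoder": self.snp_encoder, "prior": self.prior}
        for mod_name, mod in modules.items():
            for k, v in mod.state_dict().items():
                arrays[f"w/{mod_name}/{k}"] = v
        regions = self.template.metadata.get("regions", {})
        for name, mask in regions.items():
            arrays[f"region/{name}"] = np.asarray(mask)
        meta = {
            "face_spec": asdict(self.face_spec),
            "snp_spec": asdict(self.snp_spec),
            "prior_spec": asdict(self.prior_spec),
            "snp_ids": self.snp_ids,
            "landmarks": self.template.metadata.get("landmarks", {}),
            "mesh_hash": mesh_hash(self.template),
        }
        arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "Pipeline":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            template = TriMesh(data["template_vertices"], data["template_faces"])
            regions = {}
            for key in data.files:
                if key.startswith("region/"):
                    regions[key.split("/", 1)[1]] = data[key]
            template.metadata["regions"] = regions
            template.metadata["landmarks"] = meta.get("landmarks", {})
            face_spec = FaceAutoencoderSpec(**meta["face_spec"])
            snp_spec = SnpEncoderSpec(**meta["snp_spec"])
            prior_spec = PriorNetSpec(**meta["prior_spec"])
            schedule = DiffusionSchedule(betas=data["betas"])
            hierarchy = build_hierarchy(template, face_spec.pool_factors)
            rng = np.random.default_rng(0)
            encoder = FaceEncoder(face_spec, hierarchy, rng)
            decoder = FaceDecoder(face_spec, hierarchy, rng)
            snp_encoder = SnpEncoder(len(meta["snp_ids"]), snp_spec, rng)
            prior = PriorNet(prior_spec, rng)
            states: dict[str, dict[str, np.ndarray]] = {
                "encoder": {}, "decoder": {}, "snp_encoder": {}, "prior": {}}
            for key in data.files:
                if key.startswith("w/"):
                    _, mod_name, param = key.split("/", 2)
                    states[mod_name][param] = data[key]
            encoder.load_state_dict(states["encoder"])
            decoder.load_state_dict(states["decoder"])
            snp_encoder.load_state_dict(states["snp_encoder"])
            prior.load_state_dict(states["prior"])
            pipe = cls(template=template, hierarchy=hierarchy, face_spec=face_spec,
                       snp_spec=snp_spec, prior_spec=prior_spec, schedule=schedule,
                       encoder=encoder, decoder=decoder, snp_encoder=snp_encoder,
                       prior=prior, panel_mean=data["panel_mean"],
                       snp_ids=list(meta["snp_ids"]))
            for mod in (encoder, decoder, snp_encoder, prior):
                mod.eval()
            return pipe
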