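"""Checkpointing for trained networks.

One ``.npz`` file per model stores a JSON metadata header (architecture,
annealing schedule, a hash of the pathway mask) plus every parameter and
batch-norm running statistic. Loading reconstructs the model and verifies
the mask hash, so a checkpoint cannot silently be applied to a different
pathway wiring.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from .containers import PathwayMask
from .survnet import LFSurv, SurvNetSpec
from .vae import KLPMVAE, VaeArchitecture

__all__ = ["mask_hash", "save_vae", "load_vae", "save_survnet", "load_survnet"]


def mask_hash(mask: PathwayMask) -> str:
    payload = mask.mask.astype(np.uint8).tobytes() + \
        "|".join(mask.gene_ids + mask.pathway_ids).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def save_vae(model: KLPMVAE, path, schedule=None) -> None:
    arch = model.arch
    meta = {
        "kind": "kl_pmvae",
        "integration": arch.integration,
        "d_latent": arch.d_latent,
        "hidden_width": arch.hidden_width,
        "n_miRNA": arch.n_miRNA,
        "use_batchnorm": arch.use_batchnorm,
        "mask_hash": mask_hash(arch.mask) if arch.mask is not None else None,
        "schedule": None if schedule is None else {
            "n_epochs": schedule.n_epochs, "n_cycles": schedule.n_cycles,
            "cutting_ratio": schedule.cutting_ratio},
    }
    arrays = dict(model.get_state())
    if arch.mask is not None:
        arrays["__mask__"] = arch.mask.mask
        arrays["__gene_ids__"] = np.array(arch.mask.gene_ids)
        arrays["__pathway_ids__"] = np.array(arch.mask.pathway_ids)
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_vae(path) -> KLPMVAE:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        if meta.get("kind") != "kl_pmvae":
            raise ValueError("not a KL-PMVAE checkpoint")
        mask = None
        if "__mask__" in archive:
            mask = PathwayMask(mask=archive["__mask__"],
                               gene_ids=[str(g) for g in archive["__gene_ids__"]],
                               pathway_ids=[str(p) for p in archive["__pathway_ids__"]])
            if mask_hash(mask) != meta["mask_hash"]:
                raise ValueError("pathway-mask hash mismatch in checkpoint")
        arch = VaeArchitecture(mask=mask, n_miRNA=meta["n_miRNA"],
                               integration=meta["integration"],
                               d_latent=meta["d_latent"],
                               hidden_width=meta["hidden_width"],
                               use_batchnorm=meta["use_batchnorm"])
        model = KLPMVAE(arch, seed=0)
        state = {k: archive[k] for k in archive.files
                 if not k.startswith("__")}
    model.set_state(state)
    return model


def save_survnet(model: LFSurv, path) -> None:
    meta = {"kind": "lfsurv", "n_inputs": model.spec.n_inputs,
            "hidden_width": model.spec.hidden_width,
            "dropout_rate": model.spec.dropout_rate}
    np.savez(path, __meta__=json.dumps(meta), **model.get_state())


def load_survnet(path) -> LFSurv:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        if meta.get("kind") != "lfsurv":
            raise ValueError("not an LFSurv checkpoint")
        spec = SurvNetSpec(n_inputs=meta["n_inputs"],
                           hidden_width=meta["hidden_width"],
                           dropout_rate=meta["dropout_rate"])
        model = LFSurv(spec, seed=0)
        state = {k: archive[k] for k in archive.files
                 if not k.startswith("__")}
    model.set_state(state)
    return model
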