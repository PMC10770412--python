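"""Orchestration of the evaluation protocol: repeated tuning-set splits,
two-stage training (VAE by validation reconstruction loss, survival net by
validation C-index), refit on the full tuning set, and held-out testing.

The held-out 20% test set is drawn once per protocol from the master seed
and is never touched before final evaluation; the remaining tuning set is
re-split 4:1 for each of ``n_repeats`` repeats. Matched-split model variants
are compared with the two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import preprocess as pp
from .evaluate import TestResult, concordance_index, wilcoxon_signed_rank
from .survnet import SurvNetSpec, forward_pi, train_lfsurv
from .vae import (ConcatenateVAE, VaeArchitecture, beta_schedule, extract_latent,
                  train_kl_pmvae)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_protocol", "compare_models"]


@dataclass
class ExperimentConfig:
    """Grids and seeds for one protocol run.

    Grid defaults are deliberately small singletons so a protocol run is a
    single train/evaluate cycle per repeat; widen them for a real search.
    """

    integration: str = "entangle"   # entangle | concatenate | gene_only | miRNA_only | clinical_only
    n_repeats: int = 10
    master_seed: int = 0
    # preprocessing
    variance_threshold: float = 0.02
    mask_min_genes: int = 15
    mask_max_genes: int = 300
    # VAE stage
    d_latent_grid: tuple = (16,)
    vae_hidden_grid: tuple = (64,)
    lambda1_grid: tuple = (0.0,)
    cutting_ratio_grid: tuple = (0.5,)
    n_cycles: int = 2
    vae_epochs: int = 30
    vae_lr: float = 1e-3
    vae_batch_size: int = 64
    # survival stage
    surv_hidden_grid: tuple = (16,)
    dropout_grid: tuple = (0.0,)
    lambda2_grid: tuple = (0.0,)
    surv_epochs: int = 150
    surv_lr: float = 1e-2

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        for g in (self.d_latent_grid, self.vae_hidden_grid, self.lambda1_grid,
                  self.cutting_ratio_grid, self.surv_hidden_grid,
                  self.dropout_grid, self.lambda2_grid):
            if len(g) == 0:
                raise ValueError("hyperparameter grids must be non-empty")

    def repeat_seed(self, r: int) -> int:
        # documented counter scheme: repeats are independent but reproducible
        return int((self.master_seed * 10007 + 31 * r + 1) % (2**31))


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    test_ids: list
    repeats: list                       # one record dict per repeat
    test_cindices: np.ndarray
    summary: dict = field(default=None)

    def __post_init__(self):
        self.test_cindices = np.asarray(self.test_cindices, dtype=float)
        if self.summary is None:
            c = self.test_cindices
            self.summary = {"median": float(np.median(c)), "mean": float(c.mean()),
                            "sd": float(c.std(ddof=1)) if len(c) > 1 else 0.0}


def _prepare_block(matrix, split_ids_sets, threshold):
    """Self-normalize each split of one omics block; the variance filter is
    computed on the normalized tuning set and applied everywhere."""
    tuning_ids, subsets = split_ids_sets["tuning"], {}
    tuning_norm = pp.minmax_normalize(matrix.subset_samples(tuning_ids))
    filtered, _ = pp.variance_filter(tuning_norm, threshold)
    kept = filtered.feature_ids
    for name, ids in split_ids_sets.items():
        subsets[name] = pp.minmax_normalize(
            matrix.subset_samples(ids).subset_features(kept))
    return kept, subsets


def run_protocol(data, config: ExperimentConfig) -> ExperimentReport:
    """Run the full repeated-split protocol on a cohort bundle.

    ``data`` must expose ``gene``, ``miRNA``, ``clinical``, ``survival`` and
    ``pathways`` attributes sharing sample ids (a SyntheticDataset does).
    Deterministic under ``config.master_seed``.
    """
    ids = list(data.gene.sample_ids)
    plan = pp.make_splits(ids, seed=config.master_seed)
    test_set = set(plan.test_ids)
    clinical = pp.encode_clinical(data.clinical)

    records = []
    cindices = []
    for r in range(config.n_repeats):
        seed_r = config.repeat_seed(r)
        train_ids, valid_ids = pp.split_tuning(plan.tuning_ids, seed_r)
        assert test_set.isdisjoint(train_ids) and test_set.isdisjoint(valid_ids)
        split_sets = {"tuning": plan.tuning_ids, "train": train_ids,
                      "valid": valid_ids, "test": plan.test_ids}
        record = {"repeat": r, "seed": seed_r, "train_ids": list(train_ids),
                  "valid_ids": list(valid_ids)}
        use_gene = config.integration in ("entangle", "concatenate", "gene_only")
        use_mirna = config.integration in ("entangle", "concatenate", "miRNA_only")

        feats = {}
        if config.integration == "clinical_only":
            for name, sids in split_sets.items():
                feats[name] = clinical.subset(sids).values
        else:
            gene_sub = mirna_sub = None
            mask = None
            if use_gene:
                kept_genes, gene_sub = _prepare_block(data.gene, split_sets,
                                                      config.variance_threshold)
                mask = pp.build_pathway_mask(data.pathways, kept_genes,
                                             config.mask_min_genes,
                                             config.mask_max_genes)
                gene_sub = {k: v.subset_features(mask.gene_ids)
                            for k, v in gene_sub.items()}
            if use_mirna:
                _, mirna_sub = _prepare_block(data.miRNA, split_sets,
                                              config.variance_threshold)
            n_mirna = mirna_sub["train"].n_features if use_mirna else 0

            def block(name):
                g = gene_sub[name].values if use_gene else None
                m = mirna_sub[name].values if use_mirna else None
                return g, m

            # stage 1: VAE grid by validation reconstruction loss
            best = None
            for d_latent in config.d_latent_grid:
                for width in config.vae_hidden_grid:
                    for lam1 in config.lambda1_grid:
                        for cr in config.cutting_ratio_grid:
                            sched = beta_schedule(config.vae_epochs,
                                                  config.n_cycles, cr)
                            model = _fit_vae(config, block("train"), block("valid"),
                                             mask, n_mirna, d_latent, width,
                                             lam1, sched, seed_r)
                            score = model.reconstruction_loss(*block("valid"))
                            if best is None or score < best[0]:
                                best = (score, dict(d_latent=d_latent, width=width,
                                                    lambda1=lam1, cutting_ratio=cr))
            record["vae_hyperparams"] = best[1]
            record["vae_valid_recon"] = float(best[0])
            hp = best[1]
            sched = beta_schedule(config.vae_epochs, config.n_cycles,
                                  hp["cutting_ratio"])
            vae = _fit_vae(config, block("tuning"), block("tuning"), mask, n_mirna,
                           hp["d_latent"], hp["width"], hp["lambda1"], sched, seed_r)
            for name in split_sets:
                mu = extract_latent(vae, *block(name))
                feats[name] = np.hstack([mu, clinical.subset(split_sets[name]).values])

        # stage 2: survival net grid by validation C-index
        surv = {name: data.survival.subset(sids) for name, sids in split_sets.items()}
        best = None
        for width in config.surv_hidden_grid:
            for drop in config.dropout_grid:
                for lam2 in config.lambda2_grid:
                    spec = SurvNetSpec(n_inputs=feats["train"].shape[1],
                                       hidden_width=width, dropout_rate=drop)
                    model, hist = train_lfsurv((feats["train"], surv["train"]),
                                               (feats["valid"], surv["valid"]),
                                               spec, lr=config.surv_lr,
                                               n_epochs=config.surv_epochs,
                                               lambda2=lam2, seed=seed_r)
                    score = max(h["valid_cindex"] for h in hist)
                    if best is None or score > best[0]:
                        best = (score, dict(width=width, dropout=drop, lambda2=lam2))
        record["surv_hyperparams"] = best[1]
        record["surv_valid_cindex"] = float(best[0])
        hp = best[1]
        spec = SurvNetSpec(n_inputs=feats["tuning"].shape[1],
                           hidden_width=hp["width"], dropout_rate=hp["dropout"])
        model, _ = train_lfsurv((feats["tuning"], surv["tuning"]),
                                (feats["tuning"], surv["tuning"]), spec,
                                lr=config.surv_lr, n_epochs=config.surv_epochs,
                                lambda2=hp["lambda2"], seed=seed_r)
        pi_test = forward_pi(feats["test"], model, sample_ids=plan.test_ids)
        cres = concordance_index(pi_test, surv["test"])
        record["test_cindex"] = cres.c_index
        records.append(record)
        cindices.append(cres.c_index)

    return ExperimentReport(config=config, test_ids=list(plan.test_ids),
                            repeats=records, test_cindices=np.array(cindices))


def _fit_vae(config, train_block, valid_block, mask, n_mirna, d_latent, width,
             lam1, sched, seed):
    if config.integration == "concatenate":
        model, _ = ConcatenateVAE.train(train_block, valid_block, mask, n_mirna,
                                        sched, d_latent=d_latent, hidden_width=width,
                                        lr=config.vae_lr,
                                        batch_size=config.vae_batch_size,
                                        lambda1=lam1, seed=seed)
        return model
    arch = VaeArchitecture(mask=mask, n_miRNA=n_mirna,
                           integration=config.integration, d_latent=d_latent,
                           hidden_width=width)
    model, _ = train_kl_pmvae(train_block, valid_block, arch, sched,
                              lr=config.vae_lr, batch_size=config.vae_batch_size,
                              lambda1=lam1, seed=seed)
    return model


def compare_models(reports) -> dict:
    """Pairwise Wilcoxon signed-rank tests on matched testing C-indices.

    All reports must have been produced on identical splits (same test set
    and the same per-repeat train/validation partitions); otherwise the
    matched-samples comparison is invalid and an error is raised.
    """
    reports = list(reports)
    ref = reports[0]
    for rep in reports[1:]:
        if rep.test_ids != ref.test_ids or len(rep.repeats) != len(ref.repeats):
            raise ValueError("reports built on different splits cannot be compared")
        for a, b in zip(rep.repeats, ref.repeats):
            if a["train_ids"] != b["train_ids"] or a["valid_ids"] != b["valid_ids"]:
                raise ValueError("reports built on different splits cannot be compared")
    out = {}
    for i, a in enumerate(reports):
        for j, b in enumerate(reports):
            if i == j:
                out[(i, j)] = TestResult(statistic=0.0, p_value=1.0,
                                         method="wilcoxon-signed-rank (self)")
            elif (j, i) in out:
                out[(i, j)] = out[(j, i)]
            else:
                out[(i, j)] = wilcoxon_signed_rank(a.test_cindices, b.test_cindices)
    return out
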