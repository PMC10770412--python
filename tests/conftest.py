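"""Shared fixtures: small synthetic cohorts and one fully trained pipeline.

The expensive fixtures are session-scoped; every test that needs a trained
model reuses the same pipeline instead of re-training.
"""

import numpy as np
import pytest

import pathsurv as ps
from pathsurv.synthetic import planted_signal_config


@pytest.fixture(scope="session")
def tiny_cohort():
    cfg = ps.SyntheticConfig(n_samples=160, n_genes=80, n_miRNAs=16,
                             n_pathways=4, d_true=4, seed=5)
    return ps.generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_pipeline():
    """Planted-module cohort with a trained VAE + survival net + attributions.

    The cohort plants a 20-gene module (2 single-factor hub genes plus two
    10-gene pathway groups spanning orthogonal combinations of the two
    gene-specific survival factors); the VAE, survival net and DeepSHAP
    stages are run end to end once.
    """
    seed, n, k = 13, 800, 20
    cfg = planted_signal_config(n_planted=k, planted_loading=2.0, n_samples=n,
                                n_genes=300, n_miRNAs=40, n_pathways=20,
                                seed=seed)
    data = ps.generate_cohort(cfg)
    planted = data.gene.feature_ids[-k:]
    xg = ps.minmax_normalize(data.gene).values
    xm = ps.minmax_normalize(data.miRNA).values
    mask = ps.build_pathway_mask(data.pathways, data.gene.feature_ids,
                                 min_genes=5, max_genes=300)
    arch = ps.VaeArchitecture(mask=mask, n_miRNA=40, integration="entangle",
                              d_latent=8, hidden_width=128)
    sched = ps.beta_schedule(150, 3, 0.5)
    ntr = int(0.8 * n)
    vae, _ = ps.train_kl_pmvae((xg[:ntr], xm[:ntr]), (xg[ntr:], xm[ntr:]),
                               arch, sched, lr=2e-3, seed=seed + 1)
    mu = ps.extract_latent(vae, xg, xm)
    feats = np.hstack([mu, data.clinical.values])
    ids = data.survival.sample_ids
    surv_tr = data.survival.subset(ids[:ntr])
    surv_va = data.survival.subset(ids[ntr:])
    model, hist = ps.train_lfsurv(
        (feats[:ntr], surv_tr), (feats[ntr:], surv_va),
        ps.SurvNetSpec(n_inputs=feats.shape[1], hidden_width=16),
        n_epochs=150, lambda2=3e-3, seed=seed + 2)
    pi = ps.forward_pi(feats, model, ids)
    groups = ps.assign_risk_groups(pi, pi)
    hi, lo = ps.sample_risk_groups(groups, 100, 100, seed=seed + 3)
    idx = {s: i for i, s in enumerate(ids)}
    return {
        "data": data, "planted": planted, "xg": xg, "xm": xm, "mask": mask,
        "vae": vae, "surv_model": model, "history": hist, "mu": mu,
        "feats": feats, "pi": pi, "groups": groups,
        "hi_rows": [idx[s] for s in hi], "lo_rows": [idx[s] for s in lo],
    }


@pytest.fixture(scope="session")
def protocol_reports():
    """Matched-split protocol runs: full model vs clinical-only baseline on a
    strong-signal cohort (n=600, 10 repeats)."""
    data = ps.generate_cohort(ps.SyntheticConfig.strong_signal(n_samples=600, seed=11))
    cfg_full = ps.ExperimentConfig(integration="entangle", n_repeats=10,
                                   master_seed=7, d_latent_grid=(8,),
                                   vae_hidden_grid=(64,), vae_epochs=25,
                                   surv_epochs=120, mask_min_genes=10)
    cfg_clin = ps.ExperimentConfig(integration="clinical_only", n_repeats=10,
                                   master_seed=7, surv_epochs=120)
    return (ps.run_protocol(data, cfg_full), ps.run_protocol(data, cfg_clin))
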