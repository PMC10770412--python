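"""End-to-end run: pathway-masked VAE -> survival net -> evaluation.

Trains the two stages on a synthetic cohort, computes the test C-index,
splits patients at the tuning-set median prognostic index, and compares the
two risk groups with a log-rank test.
"""

import numpy as np

import pathsurv as ps

data = ps.generate_cohort(ps.SyntheticConfig.strong_signal(n_samples=500, seed=4))
plan = ps.make_splits(data.gene.sample_ids, seed=4)

# per-split min-max normalization; variance filter fitted on the tuning set
gene_tune = ps.minmax_normalize(data.gene.subset_samples(plan.tuning_ids))
gene_tune, dropped = ps.variance_filter(gene_tune, 0.02)
mirna_tune = ps.minmax_normalize(data.miRNA.subset_samples(plan.tuning_ids))
print(f"variance filter dropped {len(dropped)} genes")

mask = ps.build_pathway_mask(data.pathways, gene_tune.feature_ids,
                             min_genes=10, max_genes=300)
gene_tune = gene_tune.subset_features(mask.gene_ids)

arch = ps.VaeArchitecture(mask=mask, n_miRNA=mirna_tune.n_features,
                          integration="entangle", d_latent=8, hidden_width=64)
schedule = ps.beta_schedule(n_epochs=30, n_cycles=2, cutting_ratio=0.5)
n_train = len(plan.train_ids)
xg, xm = gene_tune.values, mirna_tune.values
vae, history = ps.train_kl_pmvae((xg[:n_train], xm[:n_train]),
                                 (xg[n_train:], xm[n_train:]),
                                 arch, schedule, lr=1e-3, seed=4)
print(f"VAE reconstruction loss: {history[0]['train_bce']:.1f} -> "
      f"{history[-1]['train_bce']:.1f} over {len(history)} epochs")

clinical = ps.encode_clinical(data.clinical)
mu_tune = ps.extract_latent(vae, xg, xm)
feats_tune = np.hstack([mu_tune, clinical.subset(plan.tuning_ids).values])
surv_tune = data.survival.subset(plan.tuning_ids)

spec = ps.SurvNetSpec(n_inputs=feats_tune.shape[1], hidden_width=16)
model, hist = ps.train_lfsurv(
    (feats_tune[:n_train], data.survival.subset(plan.train_ids)),
    (feats_tune[n_train:], data.survival.subset(plan.valid_ids)),
    spec, n_epochs=150, seed=4)
print(f"best validation C-index: {max(h['valid_cindex'] for h in hist):.3f}")

# held-out test set, normalized on its own statistics
gene_test = ps.minmax_normalize(
    data.gene.subset_samples(plan.test_ids)).subset_features(mask.gene_ids)
mirna_test = ps.minmax_normalize(
    data.miRNA.subset_samples(plan.test_ids)).subset_features(mirna_tune.feature_ids)
mu_test = ps.extract_latent(vae, gene_test.values, mirna_test.values)
feats_test = np.hstack([mu_test, clinical.subset(plan.test_ids).values])

pi_tune = ps.forward_pi(feats_tune, model, plan.tuning_ids)
pi_test = ps.forward_pi(feats_test, model, plan.test_ids)
surv_test = data.survival.subset(plan.test_ids)

c = ps.concordance_index(pi_test, surv_test)
groups = ps.assign_risk_groups(pi_tune, pi_test)
lr = ps.logrank_test(groups, surv_test)

print(f"test C-index: {c.c_index:.3f}")
print(f"risk groups at tuning-median PI {groups.pi_med:.3f}: "
      f"{groups.labels.count('high')} high / {groups.labels.count('low')} low")
print(f"log-rank chi-square {lr.statistic:.2f}, p = {lr.p_value:.2g}")
print("A C-index near the true-PI ceiling and a small log-rank p mean the")
print("latent features carry the survival signal planted in the simulator.")
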