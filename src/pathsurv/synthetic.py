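"""Synthetic multi-omics survival cohorts.

The generator emulates the statistical structure the model assumes: a set of
latent factors, some shared between the gene and miRNA blocks and some
block-specific; genes partitioned into pathway blocks whose members load on
a small set of factors; expression observed as logistic(linear signal +
Gaussian noise) so values lie in (0, 1); clinical covariates (scaled age and
a late-stage indicator); and proportional-hazards survival with Weibull
baseline and independent exponential censoring calibrated by bisection to a
target censoring rate. Everything is deterministic under ``seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import (ClinicalTable, OmicsMatrix, PathwayCollection,
                         SurvivalTable)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_cohort",
           "achieved_event_rate"]

CLINICAL_COLUMNS = ["age", "stage_h"]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    ``effect_weights`` spans [d_true latent factors, age, stage_h] and defines
    the true log-hazard; ``shared_fraction`` is the fraction of latent factors
    loading on both omics blocks. ``planted_genes`` > 0 appends that many
    genes loading strongly on every survival-weighted factor, for attribution
    recovery experiments.
    """

    n_samples: int = 600
    n_genes: int = 400
    n_miRNAs: int = 80
    n_pathways: int = 25
    d_true: int = 8
    shared_fraction: float = 0.5
    effect_weights: np.ndarray | None = None
    baseline_hazard_shape: float = 1.5
    baseline_hazard_scale: float = 0.1
    censoring_rate_target: float = 0.5
    noise_sd: float = 0.5
    loading_scale: float = 1.5
    planted_genes: int = 0
    planted_loading: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_samples", "n_genes", "n_miRNAs", "n_pathways", "d_true"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")
        if not 0 < self.censoring_rate_target < 1:
            raise ValueError("censoring_rate_target must be in (0, 1)")
        if self.noise_sd <= 0 or self.baseline_hazard_shape <= 0 \
                or self.baseline_hazard_scale <= 0:
            raise ValueError("noise_sd and Weibull parameters must be positive")
        if self.effect_weights is None:
            w = np.zeros(self.d_true + len(CLINICAL_COLUMNS))
            w[: min(3, self.d_true)] = [1.0, -0.8, 0.6][: min(3, self.d_true)]
            w[self.d_true] = 0.5       # age
            w[self.d_true + 1] = 0.7   # stage_h
            self.effect_weights = w
        self.effect_weights = np.asarray(self.effect_weights, dtype=float)
        if self.effect_weights.shape != (self.d_true + len(CLINICAL_COLUMNS),):
            raise ValueError(
                "effect_weights must cover d_true latent factors plus "
                f"{len(CLINICAL_COLUMNS)} clinical covariates"
            )

    @classmethod
    def strong_signal(cls, **overrides) -> "SyntheticConfig":
        """Conditions with a dominant latent survival signal, used for
        end-to-end recovery experiments."""
        d_true = overrides.pop("d_true", 8)
        w = np.zeros(d_true + len(CLINICAL_COLUMNS))
        w[: min(3, d_true)] = [1.5, -1.2, 1.0][: min(3, d_true)]
        w[d_true] = 0.5
        w[d_true + 1] = 0.7
        overrides.setdefault("effect_weights", w)
        return cls(d_true=d_true, **overrides)


def planted_signal_config(n_planted: int = 2, planted_loading: float = 3.0,
                          **overrides) -> SyntheticConfig:
    """Conditions for attribution-recovery experiments: the survival signal
    rides on the two gene-specific latent factors, whose only gene-side
    carriers are ``n_planted`` planted hub genes (the miRNA block never sees
    these factors). With d_true=8 and shared_fraction=0.5, factors 4 and 5
    are gene-specific."""
    w = np.zeros(8 + len(CLINICAL_COLUMNS))
    w[4], w[5] = 1.5, -1.2
    w[8], w[9] = 0.5, 0.7  # age, stage_h
    overrides.setdefault("effect_weights", w)
    overrides.setdefault("d_true", 8)
    overrides.setdefault("shared_fraction", 0.5)
    return SyntheticConfig(planted_genes=n_planted,
                           planted_loading=planted_loading, **overrides)


@dataclass
class SyntheticDataset:
    gene: OmicsMatrix
    miRNA: OmicsMatrix
    clinical: ClinicalTable
    survival: SurvivalTable
    pathways: PathwayCollection
    true_latent: np.ndarray
    true_pi: np.ndarray
    gene_loadings: np.ndarray = field(repr=False, default=None)
    miRNA_loadings: np.ndarray = field(repr=False, default=None)
    config: SyntheticConfig | None = None


def _factor_assignment(cfg: SyntheticConfig):
    """Which latent factors drive which block.

    Shared factors come first; the remaining factors are split between
    gene-specific and miRNA-specific halves.
    """
    n_shared = int(round(cfg.shared_fraction * cfg.d_true))
    shared = list(range(n_shared))
    rest = list(range(n_shared, cfg.d_true))
    half = len(rest) // 2
    gene_specific = rest[:half]
    mirna_specific = rest[half:]
    return shared, gene_specific, mirna_specific


def generate_cohort(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw one cohort under ``cfg``; bitwise-reproducible under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_samples, cfg.d_true
    z = rng.standard_normal((n, d))

    shared, gene_specific, mirna_specific = _factor_assignment(cfg)
    gene_factors = shared + gene_specific if (shared or gene_specific) else [0]
    mirna_factors = shared + mirna_specific if (shared or mirna_specific) else [0]

    # pathway blocks: contiguous gene partition; block b loads on 1-2 of the
    # gene-driving factors (round-robin so coverage is even). When genes are
    # planted, the regular blocks avoid the survival-weighted factors so the
    # planted genes are the only gene-side carriers of survival signal.
    hot = set(np.flatnonzero(cfg.effect_weights[:d] != 0).tolist())
    block_factors = gene_factors
    if cfg.planted_genes > 0:
        block_factors = [f for f in gene_factors if f not in hot] or gene_factors
    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    mirna_ids = [f"mir{i:03d}" for i in range(cfg.n_miRNAs)]
    sample_ids = [f"s{i:04d}" for i in range(n)]
    bounds = np.linspace(0, cfg.n_genes - cfg.planted_genes, cfg.n_pathways + 1).astype(int)
    gene_load = np.zeros((cfg.n_genes, d))
    pathways = {}
    for b in range(cfg.n_pathways):
        members = list(range(bounds[b], bounds[b + 1]))
        if not members:
            continue
        f1 = block_factors[b % len(block_factors)]
        f2 = block_factors[(b + 1) % len(block_factors)]
        for g in members:
            gene_load[g, f1] = cfg.loading_scale * rng.uniform(0.5, 1.0) * rng.choice([-1, 1])
            if f2 != f1 and rng.random() < 0.5:
                gene_load[g, f2] = cfg.loading_scale * rng.uniform(0.25, 0.5) * rng.choice([-1, 1])
        pathways[f"P{b:03d}"] = {gene_ids[g] for g in members}

    # planted genes: load on every survival-weighted factor, appended to the
    # last pathway so they stay mask-covered
    if cfg.planted_genes > 0:
        planted = list(range(cfg.n_genes - cfg.planted_genes, cfg.n_genes))
        # complementary sign patterns: the planted set is jointly invertible
        # for the survival factors, so no planted gene is redundant. The
        # module is split into two dedicated pathways whose gene loadings
        # span orthogonal factor combinations, so each scalar pathway node
        # carries a distinct combination and together they transmit every
        # survival factor through the mask bottleneck.
        hot_sorted = sorted(hot)
        n_hubs = min(len(hot_sorted), max(0, cfg.planted_genes - 4)) if len(hot_sorted) > 1 else 0
        hubs, rest = planted[:n_hubs], planted[n_hubs:]
        # hub genes: each is the strong single carrier of one survival factor,
        # so it projects onto every latent direction mixing that factor
        for j, g in enumerate(hubs):
            f = hot_sorted[j % len(hot_sorted)]
            gene_load[g, f] = 1.25 * cfg.planted_loading * np.sign(cfg.effect_weights[f])
        group_a, group_b = [], []
        for k, g in enumerate(rest):
            signs = []
            for fi, f in enumerate(hot_sorted):
                sign = 1.0 if (k >> fi) & 1 == 0 else -1.0
                signs.append(sign)
                gene_load[g, f] = cfg.planted_loading * sign * np.sign(cfg.effect_weights[f])
            (group_a if np.prod(signs) > 0 else group_b).append(g)
        if group_a:
            pathways["Pplanted_a"] = {gene_ids[g] for g in group_a + hubs}
        if group_b:
            pathways["Pplanted_b"] = {gene_ids[g] for g in group_b + hubs}

    mirna_load = np.zeros((cfg.n_miRNAs, d))
    for m in range(cfg.n_miRNAs):
        f = mirna_factors[m % len(mirna_factors)]
        mirna_load[m, f] = cfg.loading_scale * rng.uniform(0.5, 1.0) * rng.choice([-1, 1])

    def squash(signal):
        noisy = signal + cfg.noise_sd * rng.standard_normal(signal.shape)
        return 1.0 / (1.0 + np.exp(-noisy))

    x_gene = squash(z @ gene_load.T)
    x_mirna = squash(z @ mirna_load.T)

    age = rng.uniform(0, 1, size=n)
    stage = (rng.random(n) < 0.4).astype(float)
    clinical = np.column_stack([age, stage])

    w = cfg.effect_weights
    true_pi = z @ w[:d] + clinical @ w[d:]
    true_pi = true_pi - true_pi.mean()

    # Weibull PH survival: T = (-log U / (scale * exp(pi)))^(1/shape)
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / (cfg.baseline_hazard_scale * np.exp(true_pi))) \
        ** (1.0 / cfg.baseline_hazard_shape)

    # independent exponential censoring; rate tuned by bisection on the
    # realized censoring fraction
    u2 = rng.uniform(size=n)
    lo, hi = 1e-8, 1e8

    def censor_frac(rate):
        c = -np.log(u2) / rate
        return float(np.mean(c < t_event))

    target = cfg.censoring_rate_target
    if censor_frac(hi) < target:
        warnings.warn(f"censoring target {target} infeasible; achieved "
                      f"{censor_frac(hi):.3f}", UserWarning, stacklevel=2)
        rate = hi
    elif censor_frac(lo) > target:
        warnings.warn(f"censoring target {target} infeasible; achieved "
                      f"{censor_frac(lo):.3f}", UserWarning, stacklevel=2)
        rate = lo
    else:
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if censor_frac(mid) < target:
                lo = mid
            else:
                hi = mid
        rate = np.sqrt(lo * hi)
    t_cens = -np.log(u2) / rate
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    return SyntheticDataset(
        gene=OmicsMatrix(x_gene, sample_ids, gene_ids, "gene"),
        miRNA=OmicsMatrix(x_mirna, sample_ids, mirna_ids, "miRNA"),
        clinical=ClinicalTable(sample_ids, clinical, list(CLINICAL_COLUMNS)),
        survival=SurvivalTable(sample_ids, time, event),
        pathways=PathwayCollection(pathways=pathways,
                                   names={p: p for p in pathways}),
        true_latent=z,
        true_pi=true_pi,
        gene_loadings=gene_load,
        miRNA_loadings=mirna_load,
        config=cfg,
    )


def achieved_event_rate(dataset_or_surv) -> float:
    """Fraction of samples with an observed event."""
    surv = getattr(dataset_or_surv, "survival", dataset_or_surv)
    if len(surv.sample_ids) == 0:
        raise ValueError("empty survival table")
    return float(surv.event.mean())
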