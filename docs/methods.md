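# Methods

## Model

The pipeline estimates patient-level hazard from two omics blocks plus
clinical covariates in two decoupled stages. Stage one is unsupervised: a
variational autoencoder compresses gene expression `x_gene ∈ [0,1]^G` and
miRNA expression `x_miRNA ∈ [0,1]^M` into `d` latent variables. Stage two is
a small Cox network on the latent means and clinical covariates. Decoupling
keeps the dimension-reduction step blind to the outcome, so the survival
network trains on a feature space whose size (`d` + a few covariates) is
commensurate with the number of events.

### Encoder / decoder wiring

Entangle variant (the default):

- gene layer → pathway layer: affine transform whose weight support is the
  binary gene×pathway membership mask; ReLU; batch norm;
- `[pathway activations, miRNA layer]` → hidden layer (ReLU, batch norm);
- two parallel linear heads emit μ and log σ² (no batch norm at the
  bottleneck);
- decoder: `ẑ` → hidden (ReLU, batch norm) → (a) fully connected miRNA
  branch with sigmoid outputs, (b) pathway-level layer (ReLU, batch norm)
  followed by a transposed-mask affine and sigmoid gene outputs.

The pathway layer is what gets concatenated with the miRNA layer (rather
than the raw gene layer) because the pathway count is comparable to the
miRNA count, which balances the two blocks' contributions to the shared
hidden layer. Single-omics variants reuse the same code paths with one
branch disabled; the "concatenate" integration trains two independent
single-omics VAEs and exports `[μ_gene, μ_miRNA]`.

### Loss and annealing

`L = BCE_gene + BCE_miRNA + β·KL + λ₁‖θ₁‖₂`, where the BCE terms are summed
over features and averaged over samples, the KL term is the closed-form
Gaussian divergence from `N(0, I)` averaged over samples, and the penalty is
the L2 *norm* (not squared norm) of all learnable parameters, added
explicitly to the loss rather than applied as weight decay. Reconstructions
are clamped to `(1e-7, 1 − 1e-7)` inside the BCE so saturated outputs stay
finite. β follows a cyclical schedule: epochs are split into `n_cycles`
equal cycles; within a cycle of length L, `β(e) = min(1, e/(cutting_ratio·L))`,
so β ramps from 0 during the first `cutting_ratio` fraction of the cycle and
is 1 for the remainder; `cutting_ratio = 0` gives the conventional fixed
β = 1 objective. If `cutting_ratio·L < 1` the ramp degenerates to a single
β = 0 epoch. With `cutting_ratio = 1` the ramp occupies the whole cycle and
the final within-cycle β is `(L−1)/L`; the default grid {0, 0.25, 0.5, 0.75}
avoids this edge.

### Survival network

`[μ, clinical] → tanh hidden layer (dropout) → linear output, no bias`. The
output bias is omitted because the Cox log-risk function has no intercept
(any constant cancels in the partial likelihood — shift invariance is a
tested property). Training is full batch: the risk sets `R(T_i)` are global,
and mini-batching would bias them. Tied event times follow the Breslow
convention (tied events share one risk set containing all tied subjects);
the log-sum-exp is computed stably via a cumulative `logaddexp` over
descending times. Model selection maximizes the validation C-index; the VAE
stage instead minimizes validation reconstruction loss (inference-mode BCE
with `ẑ = μ`).

### Attribution

In inference mode each batch norm is a fixed elementwise affine map, which
is folded into the *following* linear layer; the network becomes an
alternating chain of linear steps and elementwise nonlinearities. DeepLIFT
multipliers propagate backward through this chain: the linear rule for
affine steps, the rescale rule (`Δout/Δin`, with the analytic derivative
when `|Δin| < 1e-7`) for nonlinearities. Summation-to-delta is asserted for
every (explained, reference) pair at 1e-4 relative tolerance — it is
structural for this rule set, so a violation indicates a wiring bug.
SHAP values average the per-pair attributions over a reference sample
(100 low-risk patients by default); overall contribution is the mean
absolute SHAP over 100 high-risk patients. Rankings use magnitudes only;
signs are reported but not used, since positive and negative contributions
to different latent features do not cancel meaningfully.

Pathway-node values are defined as the pathway layer's post-activation
(post-ReLU, post-batch-norm) outputs — the values actually concatenated
forward — so gene→pathway and pathway→latent attributions compose
consistently with the full encoder chain. "Top 10" contributor lists pool
genes and miRNAs jointly.

## Synthetic cohorts

`generate_cohort` draws `z ~ N(0, I)` (n × d_true) and produces:

- genes partitioned into contiguous pathway blocks, each block loading on
  one or two latent factors (round-robin assignment, loading magnitudes
  uniform in `loading_scale·[0.5, 1]` with random signs);
- miRNAs loading on the shared factor subset plus miRNA-specific factors
  (`shared_fraction` controls how many factors drive both blocks);
- expression = `logistic(loadings·z + N(0, noise_sd²))`, guaranteeing the
  (0,1) support the BCE reconstruction requires;
- clinical covariates: age ~ U(0,1) and a late-stage indicator
  (Bernoulli 0.4);
- survival: Weibull proportional hazards via inverse-transform sampling,
  `T = (−log U / (scale·e^{PI_true}))^{1/shape}`, with independent
  exponential censoring whose rate is found by bisection so the realized
  censoring fraction matches `censoring_rate_target`.

Defaults (n = 600, 400 genes, 80 miRNAs, 25 pathways, d_true = 8,
shared_fraction = 0.5, noise_sd = 0.5, Weibull shape 1.5, censoring target
0.5) are desk-scale stand-ins for a mid-sized cancer cohort: a gene:miRNA
ratio above 4, pathway sizes in the teens, roughly half the patients
censored (between the extremes of the breast- and ovarian-cancer cohorts
discussed in the power analysis), and enough latent signal that the true
prognostic index reaches a C-index near 0.87. `strong_signal()` raises the
latent effect weights to (1.5, −1.2, 1.0) for recovery experiments.

`planted_signal_config` builds the ground-truth cohort for attribution
tests: the survival weights sit on the two *gene-specific* factors, whose
only gene-side carriers are a planted module. The module contains two hub
genes (each the strong single carrier of one survival factor, members of
both planted pathways) and two dedicated pathways whose gene loadings span
orthogonal sign-pattern combinations of the two factors. The orthogonal
split matters: a scalar pathway node transmits one linear combination of
the factors, so two nodes spanning complementary combinations are needed
for both factors to pass the mask bottleneck — without this, training can
collapse both nodes onto the same combination and the recovery experiment
measures luck rather than attribution quality.

What the generator does **not** emulate: real marginal expression
distributions (log-FPKM tails, zero inflation), overlapping real pathway
topologies, batch effects, or informative censoring. Passing tests
therefore show the pipeline recovers the structure it assumes, not that it
matches any real cohort-level accuracy.

## Preprocessing protocol

Min-max normalization to [0,1] per feature, per split (training, validation
and test sets are each normalized on their own statistics by default; a
`reference_stats` argument supports applying tuning-set statistics with
clipping instead). Features with normalized tuning-set sample variance
(n−1 divisor) below 0.02 are removed; constant features are always removed
(detected by zero range, since floating-point variance of a constant column
is not exactly zero). Pathways are filtered to 15–300 member genes *after*
intersection with the dataset gene list, because the mask columns must
reflect realized connections; genes in no surviving pathway are dropped.
Splits: 20% test (floored), remaining tuning set split 4:1 into
train/validation (validation floored) — 64%/16%/20% of the whole at n = 100.
Splits are unstratified, matching the protocol's plain random extraction;
event-stratified splitting would be a one-line extension.

## Training protocol

Per repeat (default 10): re-split the fixed tuning set 4:1 with a seed
derived from the master seed by a counter scheme
(`master·10007 + 31·r + 1 mod 2³¹`); grid-search the VAE by validation
reconstruction loss and the survival net by validation C-index; refit both
on the full tuning set with the winning settings; evaluate once on the
held-out test set. Test ids are asserted disjoint from every training
split. Matched-split variants are compared by two-sided Wilcoxon
signed-rank (exact null for ≤ 25 non-zero differences, normal approximation
with continuity correction above).

Default optimizer settings: Adam, VAE lr 1e-3 (batch 64), survival net
lr 1e-2 (full batch). Layers feeding a ReLU are initialized with bias 0.1 so
no unit is dead at initialization — a dead masked pathway node has an
identically zero gradient and never recovers, which silently severs every
gene routed through it. Hyperparameter grids default to singletons
(d_latent 16, hidden widths 64/16, dropout 0, λ = 0) and are meant to be
widened by the user; the library makes no claim that these defaults are
optimal for any real dataset.

Problem sizes in the test suite (cohorts of 150–1000 samples, 80–400 genes,
VAE runs of 6–150 epochs) were chosen so the full suite exercises every
stage end to end in about a minute of CPU; the statistical conclusions the
tests assert (concordance gains, attribution recovery) are stable at these
sizes across the seeds we examined.

## Numerical and design choices

- Variance uses the sample (n−1) divisor.
- The C-index implements the pair-counting formula literally: score
  ties and time ties contribute nothing; a `tie_credit` flag provides the
  Harrell 0.5-credit variant. Cross-checked against an O(n²) enumeration
  and scikit-survival.
- Univariate Cox fits use Newton iteration on the Breslow partial
  likelihood with numerically estimated curvature, Wald intervals and a
  likelihood-ratio p-value; monotone likelihood (|β| > 15) is flagged and
  the interval reported as unbounded. Efron ties are not implemented.
- Kaplan–Meier and log-rank delegate to lifelines; Benjamini–Hochberg to
  statsmodels; the Wilcoxon test wraps scipy with the exact/approximate
  cutover at n = 25.
- The Schoenfeld detectable-HR bound is
  `exp((z_{1−α/2} + z_{power})/√n_events)` with its exact reciprocal as the
  lower bound; quantiles at double precision, rounding only for display.
- Median PI for even n is the mean of the two central order statistics; a
  PI exactly equal to the median is labeled low-risk.
- BCE clamp ε = 1e-7; attribution near-zero-Δ threshold 1e-7; batch-norm
  ε = 1e-5 with momentum 0.1 and biased batch variance.
- The L2 penalties enter the losses as explicit parameter-norm terms over
  all learnable parameters (including batch-norm scales), taking the loss
  expressions literally rather than using optimizer weight decay.

## Known limitations

- DeepSHAP scores inherit the training run's stochasticity: two VAE fits of
  equal reconstruction quality can distribute encoder weight differently
  across correlated carrier genes, shifting individual gene ranks (the
  planted-module experiments mitigate this by making each planted gene
  non-redundant). Seeds for the 100/100 sampling are therefore logged and
  configurable.
- Mini-batch VAE training with batch norm skips size-1 remainder batches.
- The decoder's pathway-level hidden layer mirrors the encoder by
  inference from the transposed-mask constraint; an architecture without it
  would also satisfy the stated wiring.
- No time-varying effects, discrete-time heads, time-dependent AUC or
  calibration metrics; no enrichment analysis of identified genes.
- The cross-dataset workflow (align features, apply a foreign PI_med) is
  exposed through `align_cohorts` and `assign_risk_groups`'s two-cohort
  signature rather than a dedicated orchestration entry point.
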