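# pathsurv

Pathway-masked multi-omics variational autoencoding for cancer prognosis,
with a Cox partial-likelihood network and DeepSHAP interpretation.

## The problem

Bulk gene-expression and miRNA-expression profiles are high-dimensional
(thousands of features) while survival cohorts are small (hundreds of
patients, often with few observed deaths). Fitting a hazard model directly
to the omics features overfits badly, and regularized linear models miss
non-linear structure. `pathsurv` implements a two-stage deep-learning
pipeline for this setting:

1. **KL-annealed pathway-masked VAE.** An encoder maps the gene layer to a
   pathway layer through *mask-constrained* connections — a gene node feeds a
   pathway node only if the gene belongs to that pathway — concatenates the
   pathway activations with the miRNA layer ("entangle" integration), and
   produces a Gaussian posterior `N(μ, σ²)` over `d` latent variables via the
   reparameterization `ẑ = μ + σ·ε`. The decoder mirrors the structure, with
   the transposed mask on the last gene layer. The loss is

   `L = BCE(x_gene, x̂_gene) + BCE(x_miRNA, x̂_miRNA) + β·KL(N(μ,σ²) ‖ N(0,I)) + λ₁‖θ₁‖₂`

   with β following a cyclical annealing schedule that ramps 0→1 over the
   first `cutting_ratio` fraction of each cycle (preventing posterior
   collapse), then holds at 1.

2. **Survival network.** The latent means μ are concatenated with clinical
   covariates (age, stage dummies, …) and fed through one tanh hidden layer
   to a bias-free linear unit producing a prognostic index `PI` — an estimate
   of the Cox log-risk function. Training minimizes the average negative log
   partial likelihood (Breslow ties) with an L2 penalty:

   `l(θ₂) = −(1/n_E) Σ_{i: E_i=1} [PI_i − log Σ_{j∈R(T_i)} e^{PI_j}] + λ₂‖θ₂‖₂`

   Patients with `PI > PI_med` (the tuning-cohort median) form the predicted
   high-risk group.

3. **DeepSHAP interpretation.** Batch norms are folded into adjacent linear
   layers; DeepLIFT-rescale multipliers are propagated against a low-risk
   reference population, satisfying summation-to-delta
   (`Σ_k C_{Δx_k Δt} = Δt`) exactly per pair. Attribution targets include the
   PI, each latent mean μ_i, and each pathway node; features in the top-10
   contributor list of more than one top latent feature are reported as key
   input factors (genes/miRNAs) or key pathway factors.

Evaluation uses the concordance index in its literal pair-counting form
(a pair is comparable iff `T_i > T_j` and patient j died; concordant iff
`η_i < η_j`), Kaplan–Meier curves with log-rank tests, matched-split
Wilcoxon signed-rank comparisons, univariate Cox screens with
Benjamini–Hochberg correction, and Schoenfeld detectable-hazard-ratio
power bounds.

Because public cohorts are not redistributable here, the package ships a
synthetic-cohort generator (`pathsurv.synthetic`) producing the statistical
structure the model assumes: partially shared latent factors driving both
omics blocks, pathway-structured gene loadings, clinical covariates, and
Weibull proportional-hazards survival with calibrated censoring. The
networks are implemented in NumPy with analytic gradients (checked against
finite differences) and an Adam optimizer; the models involved are small
enough that no GPU framework is needed.

## Worked example

```sh
python examples/train_and_evaluate.py
```

prints (numbers from an actual run):

```
variance filter dropped 0 genes
VAE reconstruction loss: 339.2 -> 321.1 over 30 epochs
best validation C-index: 0.901
test C-index: 0.835
risk groups at tuning-median PI -0.038: 45 high / 55 low
log-rank chi-square 58.82, p = 1.7e-14
```

The test C-index (0.835) approaches the ceiling set by the cohort's true
prognostic index (≈0.87 at this signal strength), and the log-rank p-value
shows the median-PI split separates the survival curves of the held-out
patients. The other examples cover cohort simulation
(`simulate_cohort.py`), DeepSHAP recovery of a planted gene module
(`interpret_attributions.py`), and the event-count power analysis
(`power_analysis.py`).

A thin CLI wraps the same functions:

```sh
pathsurv simulate --n-samples 600 --seed 1 --out cohort/
pathsurv run-protocol --data cohort/ --out report.json
pathsurv evaluate --pi pi.tsv --survival cohort/survival.tsv --out eval.json
```

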