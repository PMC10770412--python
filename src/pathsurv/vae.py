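"""Pathway-masked multi-omics variational autoencoder with KL-annealing.

The encoder maps the gene layer to a pathway layer through a mask-constrained
affine transform (a gene node connects to a pathway node only if the gene
belongs to that pathway), concatenates the pathway activations with the
miRNA layer, and produces means mu and log-variances log sigma^2 of the
latent code. The decoder mirrors this: a shared hidden layer, a fully
connected miRNA branch, and a gene branch whose last transform uses the
transposed mask. Batch normalization is applied after every activation
except at the latent bottleneck.

Loss = BCE(x_gene, xhat_gene) + BCE(x_miRNA, xhat_miRNA)
       + beta * KL(N(mu, sigma^2) || N(0, I)) + lambda1 * ||theta||_2,

with beta following a cyclical annealing schedule that ramps 0 -> 1 over the
first ``cutting_ratio`` fraction of each cycle and stays at 1 for the rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import PathwayMask
from .nn import Adam, BatchNorm, Linear, MaskedLinear, ReLU

__all__ = [
    "VaeArchitecture",
    "AnnealingSchedule",
    "VaeLossTerms",
    "KLPMVAE",
    "ConcatenateVAE",
    "reparameterize",
    "gaussian_kl",
    "bce_sum",
    "vae_loss",
    "beta_schedule",
    "train_kl_pmvae",
    "extract_latent",
]

BCE_EPS = 1e-7

INTEGRATIONS = ("entangle", "concatenate", "gene_only", "miRNA_only")


@dataclass
class VaeArchitecture:
    """Structural description of one KL-PMVAE network.

    ``integration`` selects which omics blocks are wired in. For
    ``miRNA_only`` no pathway mask is needed; every other variant requires one.
    """

    mask: PathwayMask | None
    n_miRNA: int = 0
    integration: str = "entangle"
    d_latent: int = 16
    hidden_width: int = 128
    use_batchnorm: bool = True

    def __post_init__(self):
        if self.integration not in INTEGRATIONS:
            raise ValueError(f"unknown integration {self.integration!r}")
        if self.d_latent < 1:
            raise ValueError("d_latent must be >= 1")
        if self.integration != "miRNA_only" and self.mask is None:
            raise ValueError("gene-bearing variants need a pathway mask")
        if self.integration in ("entangle", "miRNA_only", "concatenate") and self.n_miRNA < 1:
            raise ValueError("miRNA-bearing variants need n_miRNA >= 1")


@dataclass
class AnnealingSchedule:
    n_epochs: int
    n_cycles: int
    cutting_ratio: float
    beta_path: np.ndarray


@dataclass
class VaeLossTerms:
    bce_gene: float
    bce_miRNA: float
    kl: float
    l2_penalty: float
    total: float
    beta: float = 1.0


def reparameterize(mu: np.ndarray, logvar: np.ndarray, epsilon: np.ndarray) -> np.ndarray:
    """zhat = mu + sigma * epsilon with sigma = exp(logvar / 2)."""
    epsilon = np.asarray(epsilon, dtype=float)
    if epsilon.shape != np.shape(mu):
        raise ValueError("epsilon shape must match mu")
    return mu + np.exp(0.5 * np.asarray(logvar, dtype=float)) * epsilon


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Mean over samples of KL(N(mu, sigma^2) || N(0, I)), closed form."""
    mu = np.atleast_2d(mu)
    logvar = np.atleast_2d(logvar)
    per_sample = 0.5 * np.sum(mu**2 + np.exp(logvar) - logvar - 1.0, axis=1)
    return float(per_sample.mean())


def bce_sum(x: np.ndarray, xhat: np.ndarray) -> float:
    """Binary cross-entropy summed over features, averaged over samples.

    Reconstructions are clamped to (BCE_EPS, 1 - BCE_EPS) so targets of 0/1
    with a saturated reconstruction never produce an infinite loss.
    """
    xhat = np.clip(xhat, BCE_EPS, 1 - BCE_EPS)
    per_sample = -np.sum(x * np.log(xhat) + (1 - x) * np.log(1 - xhat), axis=1)
    return float(per_sample.mean())


def vae_loss(x_gene, x_miRNA, xhat_gene, xhat_miRNA, mu, logvar,
             beta: float = 1.0, lambda1: float = 0.0, l2_norm: float = 0.0) -> VaeLossTerms:
    """Compound VAE objective; any omics block may be absent (pass None)."""
    bg = bce_sum(x_gene, xhat_gene) if x_gene is not None else 0.0
    bm = bce_sum(x_miRNA, xhat_miRNA) if x_miRNA is not None else 0.0
    kl = gaussian_kl(mu, logvar)
    total = bg + bm + beta * kl + lambda1 * l2_norm
    return VaeLossTerms(bg, bm, kl, lambda1 * l2_norm, total, beta)


def beta_schedule(n_epochs: int, n_cycles: int, cutting_ratio: float) -> AnnealingSchedule:
    """Cyclical KL-annealing path.

    Epochs are divided into ``n_cycles`` equal cycles (remainder folded into
    the last). Within a cycle of length L, ``beta(e) = min(1, e / (cutting_ratio * L))``
    for 0-based epoch index e; ``cutting_ratio = 0`` means beta == 1 throughout.
    If ``cutting_ratio * L < 1`` the ramp degenerates to a single beta=0 epoch
    followed by 1.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if not 0 <= cutting_ratio <= 1:
        raise ValueError("cutting_ratio must be in [0, 1]")
    if n_epochs < 0:
        raise ValueError("n_epochs must be >= 0")
    betas = np.ones(n_epochs)
    if cutting_ratio > 0 and n_epochs > 0:
        base = n_epochs // n_cycles
        lengths = [base] * n_cycles
        lengths[-1] += n_epochs - base * n_cycles
        start = 0
        for L in lengths:
            if L == 0:
                continue
            e = np.arange(L)
            betas[start:start + L] = np.minimum(1.0, e / (cutting_ratio * L))
            start += L
    return AnnealingSchedule(n_epochs, n_cycles, cutting_ratio, betas)


class KLPMVAE:
    """One VAE network (entangle, gene_only or miRNA_only wiring)."""

    def __init__(self, arch: VaeArchitecture, seed: int = 0):
        if arch.integration == "concatenate":
            raise ValueError("use ConcatenateVAE for the concatenate strategy")
        self.arch = arch
        rng = np.random.default_rng(seed)
        H, d = arch.hidden_width, arch.d_latent
        self.has_gene = arch.integration != "miRNA_only"
        self.has_mirna = arch.integration != "gene_only"
        bn = arch.use_batchnorm

        # layers feeding a ReLU start with a small positive bias so no unit
        # is dead at initialization (a dead pathway node never recovers:
        # its gradient is identically zero)
        relu_bias = 0.1

        if self.has_gene:
            mask = arch.mask.mask
            self.n_genes, self.n_pathways = mask.shape
            self.enc_gene = MaskedLinear(mask, rng)
            self.enc_gene.b += relu_bias
            self.enc_gene_act = ReLU()
            self.enc_gene_bn = BatchNorm(self.n_pathways) if bn else None
            enc_in = self.n_pathways + (arch.n_miRNA if self.has_mirna else 0)
        else:
            self.n_genes = self.n_pathways = 0
            enc_in = arch.n_miRNA

        self.enc_hidden = Linear(enc_in, H, rng)
        self.enc_hidden.b += relu_bias
        self.enc_hidden_act = ReLU()
        self.enc_hidden_bn = BatchNorm(H) if bn else None
        self.head_mu = Linear(H, d, rng)
        self.head_logvar = Linear(H, d, rng)

        self.dec_hidden = Linear(d, H, rng)
        self.dec_hidden.b += relu_bias
        self.dec_hidden_act = ReLU()
        self.dec_hidden_bn = BatchNorm(H) if bn else None
        if self.has_mirna:
            self.dec_mirna = Linear(H, arch.n_miRNA, rng)
        if self.has_gene:
            self.dec_path = Linear(H, self.n_pathways, rng)
            self.dec_path.b += relu_bias
            self.dec_path_act = ReLU()
            self.dec_path_bn = BatchNorm(self.n_pathways) if bn else None
            self.dec_gene = MaskedLinear(arch.mask.mask.T, rng)

    # ------------------------------------------------------------------ wiring

    def _layers(self):
        names = ["enc_gene", "enc_gene_bn", "enc_hidden", "enc_hidden_bn",
                 "head_mu", "head_logvar", "dec_hidden", "dec_hidden_bn",
                 "dec_mirna", "dec_path", "dec_path_bn", "dec_gene"]
        for n in names:
            layer = getattr(self, n, None)
            if layer is not None:
                yield n, layer

    def param_handles(self):
        handles = []
        for _, layer in self._layers():
            if hasattr(layer, "params"):
                handles.extend(layer.params())
        return handles

    def l2_norm(self) -> float:
        sq = sum(float((getattr(layer, name) ** 2).sum()) for name, layer in self.param_handles())
        return float(np.sqrt(sq))

    def get_state(self):
        state = {}
        for n, layer in self._layers():
            for attr in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                v = getattr(layer, attr, None)
                if v is not None:
                    state[f"{n}.{attr}"] = v.copy()
        return state

    def set_state(self, state):
        for n, layer in self._layers():
            for attr in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                key = f"{n}.{attr}"
                if key in state:
                    setattr(layer, attr, state[key].copy())

    # ----------------------------------------------------------------- forward

    def encode(self, x_gene, x_miRNA, training: bool = False):
        """Return (mu, logvar); caches activations for backward()."""
        parts = []
        if self.has_gene:
            if x_gene is None or x_gene.shape[1] != self.n_genes:
                raise ValueError("gene input does not match the pathway mask")
            p = self.enc_gene.forward(np.atleast_2d(x_gene), training)
            p = self.enc_gene_act.forward(p, training)
            if self.enc_gene_bn is not None:
                p = self.enc_gene_bn.forward(p, training)
            self._pathway_act = p
            parts.append(p)
        if self.has_mirna:
            if x_miRNA is None or x_miRNA.shape[1] != self.arch.n_miRNA:
                raise ValueError("miRNA input width mismatch")
            parts.append(np.atleast_2d(x_miRNA))
        h = np.concatenate(parts, axis=1)
        h = self.enc_hidden.forward(h, training)
        h = self.enc_hidden_act.forward(h, training)
        if self.enc_hidden_bn is not None:
            h = self.enc_hidden_bn.forward(h, training)
        mu = self.head_mu.forward(h, training)
        logvar = self.head_logvar.forward(h, training)
        return mu, logvar

    def decode(self, zhat, training: bool = False):
        """Return (xhat_gene, xhat_miRNA); absent branch yields None."""
        zhat = np.atleast_2d(zhat)
        if zhat.shape[1] != self.arch.d_latent:
            raise ValueError("zhat must have d_latent columns")
        h = self.dec_hidden.forward(zhat, training)
        h = self.dec_hidden_act.forward(h, training)
        if self.dec_hidden_bn is not None:
            h = self.dec_hidden_bn.forward(h, training)
        xhat_m = None
        if self.has_mirna:
            self._mirna_logits = self.dec_mirna.forward(h, training)
            xhat_m = _sigmoid(self._mirna_logits)
        xhat_g = None
        if self.has_gene:
            q = self.dec_path.forward(h, training)
            q = self.dec_path_act.forward(q, training)
            if self.dec_path_bn is not None:
                q = self.dec_path_bn.forward(q, training)
            self._gene_logits = self.dec_gene.forward(q, training)
            xhat_g = _sigmoid(self._gene_logits)
        return xhat_g, xhat_m

    # ---------------------------------------------------------------- training

    def loss_and_grads(self, x_gene, x_miRNA, beta: float, lambda1: float,
                       rng: np.random.Generator, training: bool = True):
        """One forward/backward pass; gradients land in each layer's d-attrs."""
        n = (x_gene if x_gene is not None else x_miRNA).shape[0]
        mu, logvar = self.encode(x_gene, x_miRNA, training)
        eps = rng.standard_normal(mu.shape)
        z = reparameterize(mu, logvar, eps)
        xhat_g, xhat_m = self.decode(z, training)
        l2 = self.l2_norm()
        terms = vae_loss(x_gene if self.has_gene else None,
                         x_miRNA if self.has_mirna else None,
                         xhat_g, xhat_m, mu, logvar, beta, lambda1, l2)

        # backward: BCE grads enter at the pre-sigmoid logits
        dz = np.zeros_like(z)
        dh_dec = 0.0
        if self.has_gene:
            dlogit_g = (np.clip(xhat_g, BCE_EPS, 1 - BCE_EPS) - x_gene) / n
            dq = self.dec_gene.backward(dlogit_g)
            if self.dec_path_bn is not None:
                dq = self.dec_path_bn.backward(dq)
            dq = self.dec_path_act.backward(dq)
            dh_dec = dh_dec + self.dec_path.backward(dq)
        if self.has_mirna:
            dlogit_m = (np.clip(xhat_m, BCE_EPS, 1 - BCE_EPS) - x_miRNA) / n
            dh_dec = dh_dec + self.dec_mirna.backward(dlogit_m)
        if self.dec_hidden_bn is not None:
            dh_dec = self.dec_hidden_bn.backward(dh_dec)
        dh_dec = self.dec_hidden_act.backward(dh_dec)
        dz += self.dec_hidden.backward(dh_dec)

        sigma = np.exp(0.5 * logvar)
        dmu = dz + beta * mu / n
        dlogvar = dz * eps * 0.5 * sigma + beta * 0.5 * (sigma**2 - 1.0) / n

        dh = self.head_mu.backward(dmu) + self.head_logvar.backward(dlogvar)
        if self.enc_hidden_bn is not None:
            dh = self.enc_hidden_bn.backward(dh)
        dh = self.enc_hidden_act.backward(dh)
        dcat = self.enc_hidden.backward(dh)
        if self.has_gene:
            dp = dcat[:, : self.n_pathways]
            if self.enc_gene_bn is not None:
                dp = self.enc_gene_bn.backward(dp)
            dp = self.enc_gene_act.backward(dp)
            self.enc_gene.backward(dp)

        if lambda1 > 0 and l2 > 0:
            for name, layer in self.param_handles():
                g = getattr(layer, "d" + name, None)
                p = getattr(layer, name)
                add = lambda1 * p / l2
                setattr(layer, "d" + name, add if g is None else g + add)
        return terms

    def reconstruction_loss(self, x_gene, x_miRNA) -> float:
        """Inference-mode BCE with zhat = mu (no sampling); model selection metric."""
        mu, _ = self.encode(x_gene, x_miRNA, training=False)
        xhat_g, xhat_m = self.decode(mu, training=False)
        loss = 0.0
        if self.has_gene:
            loss += bce_sum(x_gene, xhat_g)
        if self.has_mirna:
            loss += bce_sum(x_miRNA, xhat_m)
        return loss


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def train_kl_pmvae(train, valid, arch: VaeArchitecture, schedule: AnnealingSchedule,
                   lr: float = 1e-3, batch_size: int = 64, lambda1: float = 0.0,
                   seed: int = 0):
    """Train a KL-PMVAE by Adam, returning the epoch with lowest validation
    reconstruction loss.

    ``train``/``valid`` are ``(x_gene, x_miRNA)`` tuples (either may be None
    for single-omics variants). Returns ``(model, history)`` where history is
    a list of per-epoch dicts with the training :class:`VaeLossTerms` and the
    validation reconstruction loss. Fully deterministic under ``seed``.
    """
    xg_tr, xm_tr = train
    xg_va, xm_va = valid
    model = KLPMVAE(arch, seed=seed)
    rng = np.random.default_rng(seed + 1)
    opt = Adam(model.param_handles(), lr=lr)
    n = (xg_tr if xg_tr is not None else xm_tr).shape[0]

    history = []
    best = (np.inf, model.get_state())
    for epoch in range(schedule.n_epochs):
        beta = float(schedule.beta_path[epoch])
        order = rng.permutation(n)
        epoch_terms = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            if len(idx) < 2 and arch.use_batchnorm:
                continue  # batch statistics undefined for a single sample
            bg = xg_tr[idx] if xg_tr is not None else None
            bm = xm_tr[idx] if xm_tr is not None else None
            terms = model.loss_and_grads(bg, bm, beta, lambda1, rng)
            if not np.isfinite(terms.total):
                raise FloatingPointError(
                    f"VAE loss diverged (non-finite) at epoch {epoch}"
                )
            opt.step()
            epoch_terms.append(terms)
        val_recon = model.reconstruction_loss(xg_va, xm_va)
        history.append({
            "epoch": epoch,
            "beta": beta,
            "train": epoch_terms[-1] if epoch_terms else None,
            "train_bce": float(np.mean([t.bce_gene + t.bce_miRNA for t in epoch_terms]))
            if epoch_terms else np.nan,
            "valid_recon": val_recon,
        })
        if val_recon < best[0]:
            best = (val_recon, model.get_state())
    model.set_state(best[1])
    return model, history


def extract_latent(model, x_gene, x_miRNA) -> np.ndarray:
    """Latent means mu in inference mode (running batch-norm stats, no noise)."""
    if isinstance(model, ConcatenateVAE):
        return model.extract_latent(x_gene, x_miRNA)
    mu, _ = model.encode(x_gene, x_miRNA, training=False)
    return mu


class ConcatenateVAE:
    """The concatenate integration strategy: two independent single-omics VAEs.

    The gene VAE keeps the pathway mask; the miRNA VAE is fully connected.
    The latent export is the column concatenation of the two mu matrices.
    """

    def __init__(self, gene_model: KLPMVAE, mirna_model: KLPMVAE):
        self.gene_model = gene_model
        self.mirna_model = mirna_model

    @classmethod
    def train(cls, train, valid, mask: PathwayMask, n_miRNA: int,
              schedule: AnnealingSchedule, d_latent: int = 16, hidden_width: int = 128,
              lr: float = 1e-3, batch_size: int = 64, lambda1: float = 0.0, seed: int = 0):
        xg_tr, xm_tr = train
        xg_va, xm_va = valid
        arch_g = VaeArchitecture(mask=mask, integration="gene_only",
                                 d_latent=d_latent, hidden_width=hidden_width)
        arch_m = VaeArchitecture(mask=None, n_miRNA=n_miRNA, integration="miRNA_only",
                                 d_latent=d_latent, hidden_width=hidden_width)
        gm, hist_g = train_kl_pmvae((xg_tr, None), (xg_va, None), arch_g, schedule,
                                    lr=lr, batch_size=batch_size, lambda1=lambda1, seed=seed)
        mm, hist_m = train_kl_pmvae((None, xm_tr), (None, xm_va), arch_m, schedule,
                                    lr=lr, batch_size=batch_size, lambda1=lambda1,
                                    seed=seed + 10007)
        return cls(gm, mm), {"gene": hist_g, "miRNA": hist_m}

    def extract_latent(self, x_gene, x_miRNA) -> np.ndarray:
        mu_g, _ = self.gene_model.encode(x_gene, None, training=False)
        mu_m, _ = self.mirna_model.encode(None, x_miRNA, training=False)
        return np.concatenate([mu_g, mu_m], axis=1)

    def reconstruction_loss(self, x_gene, x_miRNA) -> float:
        return (self.gene_model.reconstruction_loss(x_gene, None)
                + self.mirna_model.reconstruction_loss(None, x_miRNA))
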