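"""DeepLIFT-rescale attributions with a low-risk reference population.

Trained networks are first *folded*: in inference mode batch normalization
is a fixed elementwise affine map, which is absorbed into the next linear
layer, leaving a chain of linear steps and elementwise nonlinearities.
DeepLIFT then propagates multipliers backward: linear steps use the linear
rule, nonlinearities the rescale rule (multiplier = delta-output /
delta-input, falling back to the analytic derivative when |delta-input| is
below 1e-7). Each attribution vector satisfies summation-to-delta: the
attributions over the inputs sum to the difference-from-reference of the
target neuron; this is asserted on every call.

Attribution targets supported: the prognostic index through the survival
net (optionally composed with the encoder down to genes/miRNAs/clinical),
each latent mean mu_i through the encoder, and each pathway node (its
post-activation value) from the gene layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import BatchNorm, Linear, ReLU, Sigmoid, Tanh

__all__ = [
    "LinearStep",
    "ActStep",
    "AffineStep",
    "Chain",
    "fold_inference_transforms",
    "lfsurv_chain",
    "encoder_chain",
    "gene_pathway_chain",
    "pathway_latent_chain",
    "composed_chain",
    "deeplift_attributions",
    "deepshap_scores",
    "AttributionTable",
    "KeyFactorReport",
    "rank_latent_features",
    "identify_kif",
    "sample_risk_groups",
]

DELTA_EPS = 1e-7
SUM_TO_DELTA_RTOL = 1e-4

_ACT_FUNCS = {
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float)),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "sigmoid": (lambda x: 1.0 / (1.0 + np.exp(-x)),
                lambda x: (s := 1.0 / (1.0 + np.exp(-x))) * (1 - s)),
}


@dataclass
class LinearStep:
    W: np.ndarray
    b: np.ndarray

    def forward(self, x):
        return x @ self.W + self.b


@dataclass
class ActStep:
    """Elementwise nonlinearity; ``kinds`` gives the activation per unit so a
    step may apply relu to one block of a concatenation and identity to the
    rest."""

    kinds: np.ndarray  # array of strings, one per unit

    def forward(self, x):
        out = np.empty_like(x)
        for kind in np.unique(self.kinds):
            m = self.kinds == kind
            out[..., m] = _ACT_FUNCS[kind][0](x[..., m])
        return out

    def derivative(self, x):
        out = np.empty_like(x)
        for kind in np.unique(self.kinds):
            m = self.kinds == kind
            out[..., m] = _ACT_FUNCS[kind][1](x[..., m])
        return out


@dataclass
class AffineStep:
    """Exact elementwise affine map a * x + c (an unfolded batch norm)."""

    a: np.ndarray
    c: np.ndarray

    def forward(self, x):
        return self.a * x + self.c


@dataclass
class Chain:
    steps: list

    @property
    def n_outputs(self):
        for step in reversed(self.steps):
            if isinstance(step, LinearStep):
                return step.W.shape[1]
            if isinstance(step, (ActStep,)):
                return len(step.kinds)
            if isinstance(step, AffineStep):
                return len(step.a)
        raise ValueError("empty chain")

    def forward(self, x):
        """Return the list of step inputs plus the final output."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        acts = [x]
        for step in self.steps:
            x = step.forward(x)
            acts.append(x)
        return acts

    def __call__(self, x):
        return self.forward(x)[-1]


def fold_inference_transforms(layers) -> Chain:
    """Fold inference-mode batch norms into the adjacent (following) linear
    layer and return an attribution-ready chain.

    ``layers`` is the network's layer sequence, possibly annotated: plain
    :class:`~pathsurv.nn.Linear`/:class:`BatchNorm`/activation objects, or
    already-built steps (which pass through, making the fold idempotent).
    A trailing batch norm with no following linear stays as an AffineStep.
    Folded and original networks agree to float precision; a zero running
    variance is rejected by BatchNorm's epsilon never being zero, but a
    non-finite affine raises here.
    """
    pending: tuple | None = None  # (a, c) affine awaiting a linear to fold into
    steps = []

    def flush():
        nonlocal pending
        if pending is not None:
            steps.append(AffineStep(a=pending[0].copy(), c=pending[1].copy()))
            pending = None

    for layer in layers:
        if isinstance(layer, (LinearStep, ActStep, AffineStep)):
            if isinstance(layer, LinearStep) and pending is not None:
                a, c = pending
                steps.append(LinearStep(W=a[:, None] * layer.W, b=layer.b + c @ layer.W))
                pending = None
            else:
                flush()
                steps.append(layer)
        elif isinstance(layer, Linear):
            W, b = layer.W, (layer.b if layer.b is not None else np.zeros(layer.W.shape[1]))
            if pending is not None:
                a, c = pending
                W, b = a[:, None] * W, b + c @ W
                pending = None
            steps.append(LinearStep(W=W.copy(), b=np.asarray(b, dtype=float).copy()))
        elif isinstance(layer, BatchNorm):
            a, c = layer.inference_affine()
            if not (np.all(np.isfinite(a)) and np.all(np.isfinite(c))):
                raise ValueError("batch-norm running statistics are degenerate")
            if pending is not None:  # two adjacent affines compose
                a0, c0 = pending
                a, c = a * a0, a * c0 + c
            pending = (a, c)
        elif isinstance(layer, ReLU):
            flush()
            steps.append(_act_step("relu", _width(steps)))
        elif isinstance(layer, Tanh):
            flush()
            steps.append(_act_step("tanh", _width(steps)))
        elif isinstance(layer, Sigmoid):
            flush()
            steps.append(_act_step("sigmoid", _width(steps)))
        else:
            raise TypeError(f"cannot fold layer of type {type(layer).__name__}")
    flush()
    return Chain(steps)


def _width(steps):
    if not steps:
        raise ValueError("activation cannot be the first chain step")
    last = steps[-1]
    if isinstance(last, LinearStep):
        return last.W.shape[1]
    if isinstance(last, ActStep):
        return len(last.kinds)
    return len(last.a)


def _act_step(kind, n):
    return ActStep(kinds=np.array([kind] * n))


# --------------------------------------------------------------------- builders

def lfsurv_chain(model) -> Chain:
    """features -> PI chain for a trained LFSurv (dropout off at inference)."""
    return fold_inference_transforms([model.hidden, model.act, model.out])


def _bn_affine(bn, n, offset=0, total=None):
    """Extend a batch norm over ``n`` units to a wider concatenated layer."""
    total = n if total is None else total
    a = np.ones(total)
    c = np.zeros(total)
    if bn is not None:
        ab, cb = bn.inference_affine()
        a[offset:offset + n] = ab
        c[offset:offset + n] = cb
    return AffineStep(a=a, c=c)


def encoder_chain(vae, head: str = "mu") -> Chain:
    """Omics input -> latent head chain for a trained KL-PMVAE.

    Input order is [genes, miRNA] for the entangle variant, genes only for
    gene_only, miRNA only for miRNA_only.
    """
    head_layer = vae.head_mu if head == "mu" else vae.head_logvar
    layers = []
    if vae.has_gene:
        G, P = vae.n_genes, vae.n_pathways
        M = vae.arch.n_miRNA if vae.has_mirna else 0
        W1 = np.zeros((G + M, P + M))
        W1[:G, :P] = vae.enc_gene.W
        if M:
            W1[G:, P:] = np.eye(M)
        b1 = np.concatenate([vae.enc_gene.b, np.zeros(M)])
        layers.append(LinearStep(W=W1, b=b1))
        kinds = np.array(["relu"] * P + ["identity"] * M)
        layers.append(ActStep(kinds=kinds))
        if vae.enc_gene_bn is not None:
            layers.append(_bn_affine(vae.enc_gene_bn, P, offset=0, total=P + M))
    layers.append(vae.enc_hidden)
    layers.append(ReLU())
    if vae.enc_hidden_bn is not None:
        layers.append(vae.enc_hidden_bn)
    layers.append(head_layer)
    return fold_inference_transforms(layers)


def gene_pathway_chain(vae) -> Chain:
    """Gene layer -> pathway-node values (post ReLU and batch norm)."""
    if not vae.has_gene:
        raise ValueError("this VAE has no gene branch")
    layers = [vae.enc_gene, ReLU()]
    if vae.enc_gene_bn is not None:
        layers.append(vae.enc_gene_bn)
    return fold_inference_transforms(layers)


def pathway_latent_chain(vae, head: str = "mu") -> Chain:
    """[pathway-node values, miRNA] -> latent head (the encoder tail)."""
    head_layer = vae.head_mu if head == "mu" else vae.head_logvar
    layers = [vae.enc_hidden, ReLU()]
    if vae.enc_hidden_bn is not None:
        layers.append(vae.enc_hidden_bn)
    layers.append(head_layer)
    return fold_inference_transforms(layers)


def composed_chain(vae, surv_model, n_clinical: int) -> Chain:
    """[omics input, clinical] -> PI through encoder mu then LFSurv.

    Clinical covariates ride through the encoder part of the chain as
    identity coordinates and join the latent means at the survival net.
    """
    enc = encoder_chain(vae, head="mu")
    p_in = enc.steps[0].W.shape[0]
    d = enc.n_outputs
    steps = []
    for step in enc.steps:
        if isinstance(step, LinearStep):
            n_in, n_out = step.W.shape
            W = np.zeros((n_in + n_clinical, n_out + n_clinical))
            W[:n_in, :n_out] = step.W
            W[n_in:, n_out:] = np.eye(n_clinical)
            steps.append(LinearStep(W=W, b=np.concatenate([step.b, np.zeros(n_clinical)])))
        elif isinstance(step, ActStep):
            steps.append(ActStep(kinds=np.concatenate(
                [step.kinds, np.array(["identity"] * n_clinical)])))
        else:
            steps.append(AffineStep(a=np.concatenate([step.a, np.ones(n_clinical)]),
                                    c=np.concatenate([step.c, np.zeros(n_clinical)])))
    surv = lfsurv_chain(surv_model)
    if surv.steps[0].W.shape[0] != d + n_clinical:
        raise ValueError("survival net input width does not match mu + clinical")
    steps.extend(surv.steps)
    return fold_inference_transforms(steps)


# ------------------------------------------------------------------- attribution

def deeplift_attributions(chain: Chain, x, x_ref, target: int) -> np.ndarray:
    """DeepLIFT-rescale attributions of input features for one target neuron.

    ``x`` is one explained row, ``x_ref`` one or more reference rows; returns
    an array with one attribution vector per reference row (summation-to-delta
    holds for each row before any averaging).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_ref = np.atleast_2d(np.asarray(x_ref, dtype=float))
    if x.shape[0] != 1:
        raise ValueError("pass a single explained row")
    if x.shape[1] != x_ref.shape[1]:
        raise ValueError("x and x_ref must have the same width")
    acts = chain.forward(x)
    acts_ref = chain.forward(x_ref)
    if not all(np.all(np.isfinite(a)) for a in acts + acts_ref):
        raise FloatingPointError("non-finite activations during attribution")

    n_ref = x_ref.shape[0]
    m = np.zeros((n_ref, chain.n_outputs))
    m[:, target] = 1.0
    for step, a_in, r_in in zip(reversed(chain.steps), reversed(acts[:-1]),
                                reversed(acts_ref[:-1])):
        if isinstance(step, LinearStep):
            m = m @ step.W.T
        elif isinstance(step, AffineStep):
            m = m * step.a
        else:  # rescale rule
            d_in = a_in - r_in  # broadcast: (n_ref, n)
            d_out = step.forward(a_in) - step.forward(r_in)
            small = np.abs(d_in) < DELTA_EPS
            slope = np.where(small, step.derivative(np.broadcast_to(a_in, d_in.shape)),
                             d_out / np.where(small, 1.0, d_in))
            m = m * slope
        # a_in shape (1, n); broadcasting against (n_ref, n) handled above
    contrib = m * (x - x_ref)

    delta_t = acts[-1][0, target] - acts_ref[-1][:, target]
    total = contrib.sum(axis=1)
    tol = 1e-8 + SUM_TO_DELTA_RTOL * np.abs(delta_t)
    if np.any(np.abs(total - delta_t) > tol):
        raise AssertionError("summation-to-delta violated beyond tolerance")
    return contrib


@dataclass
class AttributionTable:
    explained_sample_ids: list
    reference_sample_ids: list
    target: str
    feature_ids: list
    shap: np.ndarray            # explained x features (mean over references)
    overall: np.ndarray = field(default=None)  # per-feature mean |SHAP|

    def __post_init__(self):
        if self.overall is None:
            self.overall = np.abs(self.shap).mean(axis=0)


def deepshap_scores(chain: Chain, explained, references, target: int,
                    explained_ids=None, reference_ids=None,
                    feature_ids=None, target_name: str | None = None) -> AttributionTable:
    """SHAP values: per explained sample the mean DeepLIFT attribution over
    the reference rows; overall contribution = mean |SHAP| over explained."""
    explained = np.atleast_2d(np.asarray(explained, dtype=float))
    references = np.atleast_2d(np.asarray(references, dtype=float))
    if explained.size == 0 or references.size == 0:
        raise ValueError("explained and reference sets must be non-empty")
    shap = np.empty_like(explained)
    for i in range(explained.shape[0]):
        shap[i] = deeplift_attributions(chain, explained[i:i + 1], references,
                                        target).mean(axis=0)
    p = explained.shape[1]
    return AttributionTable(
        explained_sample_ids=list(explained_ids) if explained_ids is not None
        else [str(i) for i in range(explained.shape[0])],
        reference_sample_ids=list(reference_ids) if reference_ids is not None
        else [str(i) for i in range(references.shape[0])],
        target=target_name if target_name is not None else str(target),
        feature_ids=list(feature_ids) if feature_ids is not None
        else [f"f{j}" for j in range(p)],
        shap=shap,
    )


def sample_risk_groups(groups, n_explained: int = 100, n_reference: int = 100,
                       seed: int = 0):
    """Seeded draw of high-risk (explained) and low-risk (reference) ids.

    If a group is smaller than requested, every member is used with a warning.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(groups.sample_ids)
    labels = np.asarray(groups.labels)
    high, low = ids[labels == "high"], ids[labels == "low"]

    def draw(pool, k, name):
        if len(pool) < k:
            warnings.warn(f"only {len(pool)} {name} samples available "
                          f"(requested {k}); using all", UserWarning, stacklevel=3)
            return list(pool)
        return list(rng.choice(pool, size=k, replace=False))

    return draw(high, n_explained, "high-risk"), draw(low, n_reference, "low-risk")


@dataclass
class KeyFactorReport:
    top_latents: list
    per_latent_top: dict       # latent target -> ordered top-k feature ids
    key_factors: dict          # feature id -> number of top-k lists it appears in (>= 2)


def rank_latent_features(table: AttributionTable) -> list:
    """Feature ids sorted by overall contribution, descending; ties broken by
    feature id for determinism."""
    order = sorted(range(len(table.feature_ids)),
                   key=lambda j: (-table.overall[j], table.feature_ids[j]))
    return [table.feature_ids[j] for j in order]


def identify_kif(per_latent_tables, top_k: int = 10) -> KeyFactorReport:
    """Key factors: inputs ranking in the top-``top_k`` contributors for more
    than one latent feature.

    Applied to gene/miRNA attributions this yields Key Input Factors; applied
    to pathway-node attributions, Key Pathway Factors.
    """
    tables = list(per_latent_tables)
    if len(tables) < 2:
        warnings.warn("need >= 2 latent targets to identify key factors; "
                      "returning an empty set", UserWarning, stacklevel=2)
        per = {t.target: rank_latent_features(t)[:top_k] for t in tables}
        return KeyFactorReport(top_latents=[t.target for t in tables],
                               per_latent_top=per, key_factors={})
    per = {}
    counts = {}
    for t in tables:
        top = rank_latent_features(t)[:top_k]
        per[t.target] = top
        for f in top:
            counts[f] = counts.get(f, 0) + 1
    kif = {f: c for f, c in counts.items() if c >= 2}
    return KeyFactorReport(top_latents=[t.target for t in tables],
                           per_latent_top=per, key_factors=kif)
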