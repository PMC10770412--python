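"""Cox partial-likelihood network mapping [latent features, clinical] to a
prognostic index (PI).

One hidden layer with tanh activation and dropout, then a bias-free linear
output unit — the bias is omitted because the Cox log-risk function has no
intercept. Training minimizes the average negative log partial likelihood
(Breslow convention for tied event times) with an L2 parameter-norm penalty.
Higher PI means higher predicted hazard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SurvivalTable
from .nn import Adam, Dropout, Linear, Tanh

__all__ = [
    "SurvNetSpec",
    "PrognosticIndex",
    "RiskGroups",
    "LFSurv",
    "cox_partial_loss",
    "cox_loss",
    "train_lfsurv",
    "assign_risk_groups",
]


@dataclass
class SurvNetSpec:
    n_inputs: int
    hidden_width: int = 16
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.n_inputs < 1 or self.hidden_width < 1:
            raise ValueError("n_inputs and hidden_width must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class PrognosticIndex:
    sample_ids: list
    pi: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float).reshape(-1)
        if len(self.sample_ids) != self.pi.shape[0]:
            raise ValueError("one PI value per sample required")
        if not np.all(np.isfinite(self.pi)):
            raise ValueError("PI values must be finite")


@dataclass
class RiskGroups:
    pi_med: float
    sample_ids: list
    labels: list  # "high" / "low" per sample


class LFSurv:
    """features -> hidden(tanh, dropout) -> linear output with no bias."""

    def __init__(self, spec: SurvNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.hidden = Linear(spec.n_inputs, spec.hidden_width, rng)
        self.act = Tanh()
        self.dropout = Dropout(spec.dropout_rate)
        self.out = Linear(spec.hidden_width, 1, rng, bias=False)

    def forward(self, x, training: bool = False, rng=None) -> np.ndarray:
        x = np.atleast_2d(x)
        if x.shape[1] != self.spec.n_inputs:
            raise ValueError(
                f"expected {self.spec.n_inputs} input features, got {x.shape[1]}"
            )
        h = self.hidden.forward(x, training)
        h = self.act.forward(h, training)
        h = self.dropout.forward(h, training, rng=rng)
        return self.out.forward(h, training)[:, 0]

    def backward(self, dpi: np.ndarray) -> None:
        g = self.out.backward(dpi.reshape(-1, 1))
        g = self.dropout.backward(g)
        g = self.act.backward(g)
        self.hidden.backward(g)

    def param_handles(self):
        return self.hidden.params() + self.out.params()

    def l2_norm(self) -> float:
        sq = sum(float((getattr(layer, n) ** 2).sum()) for n, layer in self.param_handles())
        return float(np.sqrt(sq))

    def get_state(self):
        return {"hidden.W": self.hidden.W.copy(), "hidden.b": self.hidden.b.copy(),
                "out.W": self.out.W.copy()}

    def set_state(self, state):
        self.hidden.W = state["hidden.W"].copy()
        self.hidden.b = state["hidden.b"].copy()
        self.out.W = state["out.W"].copy()


def forward_pi(features, spec_or_model, sample_ids=None) -> PrognosticIndex:
    """Inference-mode PI for a feature matrix (dropout disabled)."""
    model = spec_or_model
    pi = model.forward(np.atleast_2d(features), training=False)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(pi))]
    return PrognosticIndex(sample_ids=list(sample_ids), pi=pi)


def cox_partial_loss(pi: np.ndarray, time: np.ndarray, event: np.ndarray,
                     return_grad: bool = False):
    """Average negative log partial likelihood (Breslow ties), optionally with
    its gradient with respect to PI.

    loss = -(1/n_events) * sum_{i: event} [ PI_i - log sum_{j: T_j >= T_i} exp(PI_j) ]

    The risk set of an event includes every subject with T_j >= T_i, so tied
    events share an identical risk set. Log-sum-exp is computed stably.
    """
    pi = np.asarray(pi, dtype=float).reshape(-1)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("partial likelihood undefined: no events present")

    order = np.argsort(-time, kind="stable")  # descending time
    t_sorted = time[order]
    pi_sorted = pi[order]
    c = pi.max()
    cum = np.logaddexp.accumulate(pi_sorted - c) + c  # lse over {T >= t_sorted[k]} prefix
    # for ties, every member of a tie block uses the lse at the block's end
    block_end = np.arange(len(t_sorted))
    k = len(t_sorted) - 1
    while k > 0:
        if t_sorted[k - 1] == t_sorted[k]:
            block_end[k - 1] = block_end[k]
        k -= 1
    lse_sorted = cum[block_end]
    lse = np.empty_like(lse_sorted)
    lse[order] = lse_sorted

    loss = -(pi[event == 1] - lse[event == 1]).sum() / n_events
    if not return_grad:
        return loss

    # d loss / d pi_k = -(1/nE) [ event_k - exp(pi_k) * sum_{events i: T_k >= T_i} 1/S_i ]
    inv_s_sorted = np.where(event[order] == 1, np.exp(-lse_sorted), 0.0)
    # subject k (descending order position q) is in the risk set of any event
    # with position >= start of its tie block
    block_start = np.arange(len(t_sorted))
    k = 1
    while k < len(t_sorted):
        if t_sorted[k] == t_sorted[k - 1]:
            block_start[k] = block_start[k - 1]
        k += 1
    suffix = np.cumsum(inv_s_sorted[::-1])[::-1]
    cum_inv = suffix[block_start]
    grad_sorted = -(event[order] - np.exp(pi_sorted) * cum_inv) / n_events
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return loss, grad


def cox_loss(pi: PrognosticIndex, surv: SurvivalTable, lambda2: float = 0.0,
             model: LFSurv | None = None) -> float:
    """Penalized Cox loss for a PrognosticIndex aligned to a SurvivalTable."""
    if list(pi.sample_ids) != list(surv.sample_ids):
        surv = surv.subset(pi.sample_ids)
    base = cox_partial_loss(pi.pi, surv.time, surv.event)
    if lambda2 > 0 and model is not None:
        base += lambda2 * model.l2_norm()
    return float(base)


def train_lfsurv(train, valid, spec: SurvNetSpec, lr: float = 1e-2,
                 n_epochs: int = 200, lambda2: float = 0.0, seed: int = 0):
    """Full-batch Adam training of LFSurv; selects the epoch with the highest
    validation C-index.

    ``train``/``valid`` are ``(features, SurvivalTable)`` pairs. Full-batch
    updates keep the risk sets of the partial likelihood exact (mini-batches
    would truncate them). Returns ``(model, history)``.
    """
    from .evaluate import concordance_index  # local import avoids a cycle

    x_tr, surv_tr = train
    x_va, surv_va = valid
    if surv_tr.n_events == 0 or surv_va.n_events == 0:
        raise ValueError("both train and validation sets need at least one event")
    x_tr = np.atleast_2d(np.asarray(x_tr, dtype=float))
    x_va = np.atleast_2d(np.asarray(x_va, dtype=float))

    model = LFSurv(spec, seed=seed)
    rng = np.random.default_rng(seed + 1)
    opt = Adam(model.param_handles(), lr=lr)
    history = []
    best = (-np.inf, model.get_state())
    if n_epochs == 0:
        return model, history
    for epoch in range(n_epochs):
        pi = model.forward(x_tr, training=True, rng=rng)
        loss, dpi = cox_partial_loss(pi, surv_tr.time, surv_tr.event, return_grad=True)
        if not np.isfinite(loss):
            raise FloatingPointError(f"Cox loss diverged at epoch {epoch}")
        model.backward(dpi)
        if lambda2 > 0:
            norm = model.l2_norm()
            if norm > 0:
                for name, layer in model.param_handles():
                    g = getattr(layer, "d" + name)
                    setattr(layer, "d" + name, g + lambda2 * getattr(layer, name) / norm)
        opt.step()
        pi_va = model.forward(x_va, training=False)
        cres = concordance_index(
            PrognosticIndex(list(surv_va.sample_ids), pi_va), surv_va
        )
        history.append({"epoch": epoch, "train_loss": float(loss),
                        "valid_cindex": cres.c_index})
        if cres.c_index > best[0]:
            best = (cres.c_index, model.get_state())
    model.set_state(best[1])
    return model, history


def assign_risk_groups(tuning_pi: PrognosticIndex, target_pi: PrognosticIndex) -> RiskGroups:
    """Label target samples high-risk iff PI > median(tuning PI).

    The median uses the mean of the two central order statistics for even n;
    a PI exactly equal to the median goes to the low-risk group. The tuning
    cohort may differ from the labeled cohort (cross-dataset thresholds).
    """
    if len(tuning_pi.pi) == 0:
        raise ValueError("tuning PI is empty")
    pi_med = float(np.median(tuning_pi.pi))
    labels = ["high" if v > pi_med else "low" for v in target_pi.pi]
    return RiskGroups(pi_med=pi_med, sample_ids=list(target_pi.sample_ids), labels=labels)
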