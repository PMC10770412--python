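"""Survival evaluation statistics.

The concordance index is implemented as a literal pair count: a pair (i, j)
is comparable iff T_i > T_j and patient j's death was observed; it is
concordant iff eta_i < eta_j. Score ties contribute nothing
to the numerator (a ``tie_credit`` flag enables the Harrell 0.5 variant).
Kaplan-Meier curves and the log-rank test delegate to lifelines; the
Wilcoxon signed-rank test wraps scipy with an exact/normal cutover at n=25;
univariate Cox regression is a Newton solver on the Breslow partial
likelihood with Wald intervals and a likelihood-ratio p-value; and the
detectable-hazard-ratio bound follows Schoenfeld's sample-size formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import SurvivalTable
from .survnet import PrognosticIndex, RiskGroups, cox_partial_loss

__all__ = [
    "ConcordanceResult",
    "KMEstimate",
    "TestResult",
    "UnivariateCoxResult",
    "concordance_index",
    "km_estimate",
    "logrank_test",
    "wilcoxon_signed_rank",
    "univariate_cox",
    "bh_adjust",
    "schoenfeld_detectable_hr",
]


@dataclass
class ConcordanceResult:
    c_index: float
    n_comparable_pairs: int
    n_concordant: float


@dataclass
class KMEstimate:
    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function evaluation."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str


@dataclass
class UnivariateCoxResult:
    coef: float
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    separation: bool = False


def concordance_index(pi: PrognosticIndex, surv: SurvivalTable,
                      tie_credit: bool = False) -> ConcordanceResult:
    """Concordance between a risk score and right-censored survival times.

    numerator   = sum_{i,j} 1{eta_i < eta_j} 1{T_i > T_j} delta_j
    denominator = sum_{i,j} 1{T_i > T_j} delta_j

    With ``tie_credit=True`` tied scores among comparable pairs count 0.5.
    """
    if list(pi.sample_ids) != list(surv.sample_ids):
        surv = surv.subset(pi.sample_ids)
    eta = pi.pi
    t, d = surv.time, surv.event
    longer = t[:, None] > t[None, :]           # T_i > T_j
    comparable = longer & (d[None, :] == 1)    # delta_j = 1
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (all censored or all times tied)")
    lower_score = eta[:, None] < eta[None, :]  # eta_i < eta_j
    n_conc = float((comparable & lower_score).sum())
    if tie_credit:
        n_conc += 0.5 * float((comparable & (eta[:, None] == eta[None, :])).sum())
    return ConcordanceResult(c_index=n_conc / n_comp,
                             n_comparable_pairs=n_comp, n_concordant=n_conc)


def km_estimate(surv: SurvivalTable) -> KMEstimate:
    """Product-limit survival estimate over the distinct event times."""
    from lifelines import KaplanMeierFitter

    if len(surv.sample_ids) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, surv.event)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    if len(event_rows) == 0:
        return KMEstimate(np.array([]), np.array([]), np.array([], dtype=int),
                          np.array([], dtype=int))
    times = event_rows.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    probs = np.array([float(sf.loc[t]) for t in times])
    return KMEstimate(
        event_times=times,
        survival_prob=probs,
        at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        events=event_rows["observed"].to_numpy(dtype=int),
    )


def logrank_test(groups: RiskGroups, surv: SurvivalTable) -> TestResult:
    """Two-group log-rank chi-square test (1 df) comparing KM curves."""
    from lifelines.statistics import logrank_test as _lr

    surv = surv.subset(groups.sample_ids)
    labels = np.asarray(groups.labels)
    if len(set(labels)) < 2:
        raise ValueError("log-rank test needs two non-empty groups")
    hi = labels == "high"
    if surv.n_events == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _lr(surv.time[hi], surv.time[~hi], surv.event[hi], surv.event[~hi])
    return TestResult(statistic=float(res.test_statistic),
                      p_value=float(res.p_value), method="log-rank")


def wilcoxon_signed_rank(a, b) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for matched samples.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 remaining pairs and the normal approximation with continuity
    correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matched samples must have equal length")
    diff = a - b
    nz = diff[diff != 0]
    if len(nz) == 0:
        warnings.warn("all differences are zero; p = 1", UserWarning, stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, method="wilcoxon-signed-rank")
    if len(nz) < 5:
        warnings.warn("fewer than 5 non-zero differences; test has little power",
                      UserWarning, stacklevel=2)
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", correction=True, method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method=f"wilcoxon-signed-rank ({method})")


def univariate_cox(covariate, surv: SurvivalTable, alpha: float = 0.05,
                   max_iter: int = 100) -> UnivariateCoxResult:
    """Single-covariate Cox PH fit: Breslow partial likelihood by Newton
    iteration; Wald confidence interval; likelihood-ratio p-value.

    Monotone likelihood (perfect separation) is flagged and the confidence
    interval reported as unbounded.
    """
    x = np.asarray(covariate, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("covariate is constant")
    if surv.n_events == 0:
        raise ValueError("no events")
    t, d = surv.time, surv.event

    def negloglik(beta):
        return cox_partial_loss(beta * x, t, d) * surv.n_events

    beta, separation = 0.0, False
    for _ in range(max_iter):
        h = 1e-5
        g = (negloglik(beta + h) - negloglik(beta - h)) / (2 * h)
        hess = (negloglik(beta + h) - 2 * negloglik(beta) + negloglik(beta - h)) / h**2
        if hess <= 0:
            break
        step = g / hess
        beta -= np.clip(step, -2.0, 2.0)
        if abs(beta) > 15:
            separation = True
            break
        if abs(step) < 1e-10:
            break
    h = 1e-5
    hess = (negloglik(beta + h) - 2 * negloglik(beta) + negloglik(beta - h)) / h**2
    z = stats.norm.ppf(1 - alpha / 2)
    if separation or hess <= 0:
        warnings.warn("monotone partial likelihood: confidence interval unbounded",
                      UserWarning, stacklevel=2)
        se = np.inf
        separation = True
    else:
        se = 1.0 / np.sqrt(hess)
    lrt = 2.0 * (negloglik(0.0) - negloglik(beta))
    p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    return UnivariateCoxResult(
        coef=float(beta),
        hazard_ratio=float(np.exp(beta)),
        ci_lower=float(np.exp(beta - z * se)),
        ci_upper=float(np.exp(beta + z * se)),
        p_value=p,
        separation=separation,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def schoenfeld_detectable_hr(n_events: int, alpha: float = 0.05,
                             power: float = 0.8):
    """Detectable hazard-ratio bounds for a standardized covariate.

    log HR = (z_{1-alpha/2} + z_{power}) / sqrt(n_events); returns
    ``(hr_upper, hr_lower)`` with hr_lower = 1 / hr_upper exactly.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    log_hr = (stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)) / np.sqrt(n_events)
    return float(np.exp(log_hr)), float(np.exp(-log_hr))
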