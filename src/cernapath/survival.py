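"""Prognostic evaluation of subpathway gene signatures.

A signature of k genes is turned into a per-patient risk score

    risk = sum_i beta_i * Exp(i)

where beta_i is the gene's univariate Cox proportional-hazards
coefficient estimated on the training set.  Patients are split at the
median risk score (ties go to the low-risk group) and the two groups are
compared with the standard two-group log-rank test (1 df).

The univariate Cox fit maximises the Breslow partial likelihood by
Newton's method; monotone-separation or non-convergence is flagged and
the gene receives beta = 0 so a single pathological gene cannot sink a
whole signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

__all__ = [
    "RiskModel",
    "StratificationResult",
    "univariate_cox",
    "fit_risk_model",
    "risk_scores",
    "logrank_split",
]

logger = logging.getLogger(__name__)


@dataclass
class RiskModel:
    """Gene signature with per-gene univariate Cox coefficients."""

    genes: list[str]
    betas: np.ndarray
    flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.genes) != self.betas.size:
            raise ValueError("genes and betas must have equal length")


@dataclass
class StratificationResult:
    scores: pd.Series
    groups: pd.Series  # "high" / "low"
    logrank_chi2: float
    logrank_p: float
    zero_event_group: bool = False


def univariate_cox(
    x,
    time,
    event,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[float, bool]:
    """Univariate Cox coefficient via Newton on the Breslow partial likelihood.

    Returns ``(beta, converged)``; a monotone-separation or
    non-convergent fit returns ``(0.0, False)`` with a warning.  Requires
    >= 2 events and a non-constant covariate.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if x.shape != time.shape or x.shape != event.shape:
        raise ValueError("x, time and event must have equal length")
    if event.sum() < 2:
        raise ValueError("at least 2 events required")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant (non-identifiable)")

    # sort descending by time so risk sets are cumulative prefixes
    order = np.argsort(-time, kind="stable")
    xs, ts, es = x[order], time[order], event[order]

    def derivatives(beta: float) -> tuple[float, float, float]:
        eta = beta * xs
        eta -= eta.max()  # overflow guard; cancels in the ratios
        w = np.exp(eta)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * xs)
        s2 = np.cumsum(w * xs * xs)
        # Breslow: every tied death at t uses the full risk set at t.
        # With descending times, risk set of row i is rows [0..j] where j is
        # the last row sharing time ts[i].
        uniq, last = np.unique(-ts, return_index=True)
        idx_last = np.empty(ts.size, dtype=int)
        bounds = np.append(last[1:], ts.size)
        for start, end in zip(last, bounds):
            idx_last[start:end] = end - 1
        deaths = es == 1
        j = idx_last[deaths]
        xi = xs[deaths]
        ll = float(np.sum(beta * xi - np.log(s0[j])))
        score = float(np.sum(xi - s1[j] / s0[j]))
        info = float(np.sum(s2[j] / s0[j] - (s1[j] / s0[j]) ** 2))
        return ll, score, info

    beta = 0.0
    for _ in range(max_iter):
        _, score, info = derivatives(beta)
        if info <= 0 or not np.isfinite(score):
            logger.warning("Cox fit: non-positive information; beta set to 0")
            return 0.0, False
        step = score / info
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(beta) > 50:  # monotone separation
            logger.warning("Cox fit: separation detected; beta set to 0")
            return 0.0, False
        if abs(step) < tol:
            return float(beta), True
    logger.warning("Cox fit: no convergence in %d iterations; beta set to 0",
                   max_iter)
    return 0.0, False


def fit_risk_model(genes, expr: pd.DataFrame, time, event) -> RiskModel:
    """Univariate Cox coefficient per signature gene on the training set."""
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    betas = []
    flagged = []
    for g in genes:
        beta, ok = univariate_cox(expr.loc[g].to_numpy(), time, event)
        betas.append(beta)
        if not ok:
            flagged.append(g)
    return RiskModel(genes=list(genes), betas=np.array(betas), flagged=flagged)


def risk_scores(model: RiskModel, expr: pd.DataFrame) -> pd.Series:
    """Per-patient linear risk score sum_i beta_i * Exp(i)."""
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    sub = expr.loc[model.genes].to_numpy(dtype=float)
    return pd.Series(model.betas @ sub, index=expr.columns, name="risk_score")


def logrank_split(scores: pd.Series, time, event) -> StratificationResult:
    """Median-split the risk scores and run the two-group log-rank test.

    Patients with score > median are "high" risk; ties at the median go
    to the low group.  A group with zero events is flagged (the p-value
    is still computed).
    """
    scores = pd.Series(scores)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    median = float(np.median(scores.to_numpy()))
    high = scores.to_numpy() > median
    if high.all() or (~high).all():
        raise ValueError("median split left one group empty")
    groups = pd.Series(np.where(high, "high", "low"), index=scores.index)
    zero_events = event[high].sum() == 0 or event[~high].sum() == 0
    if zero_events:
        warnings.warn("a risk group has zero events; log-rank p is fragile",
                      stacklevel=2)
    res = logrank_test(time[high], time[~high], event[high], event[~high])
    return StratificationResult(
        scores=scores,
        groups=groups,
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
        zero_event_group=bool(zero_events),
    )
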