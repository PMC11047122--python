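"""Gene-signature survival risk scoring.

A Cox proportional-hazards model is fit on tumor expression of the
signature genes (partial likelihood with Breslow tie handling, Newton
iterations).  The per-sample risk score is the linear predictor
``score_s = sum_i C_i * E_{i,s}``; samples at or above the median score form
the high-risk group and the two groups are compared with the two-sample
log-rank test.  Patient age (recorded in days) is classified as early onset
at or under 18,250 days (about 50 years).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from scipy import stats


class ConvergenceError(RuntimeError):
    """The Cox Newton iterations failed to converge."""


@dataclass
class RiskModel:
    """Cox coefficients C1..Ck for the signature genes."""

    gene_ids: List[str]
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValueError("duplicate gene ids in risk model")
        if len(self.gene_ids) != self.coefficients.size:
            raise ValueError("one coefficient per gene required")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")


def classify_age_days(age_days: float) -> str:
    """'early' at or under 18,250 days (~50 years), else 'late'."""
    if age_days < 0:
        raise ValueError(f"negative age: {age_days}")
    return "early" if age_days <= 18250 else "late"


def _cox_loglik(beta, X, time, event):
    """Breslow partial log-likelihood, gradient and information matrix."""
    order = np.argsort(-time, kind="stable")  # decreasing time
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    w = np.exp(eta)
    # running risk-set sums (samples with time >= t are prefixes in this order)
    cw = np.cumsum(w)
    cwx = np.cumsum(w[:, None] * Xs, axis=0)
    cwxx = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    # risk set of subject i includes all ties at the same time
    idx = np.searchsorted(-ts, -ts, side="right") - 1
    ll, grad, info = 0.0, np.zeros(X.shape[1]), np.zeros((X.shape[1],) * 2)
    for i in np.flatnonzero(es):
        j = idx[i]
        s0, s1, s2 = cw[j], cwx[j], cwxx[j]
        ll += eta[i] - np.log(s0)
        mu = s1 / s0
        grad += Xs[i] - mu
        info += s2 / s0 - np.outer(mu, mu)
    return ll, grad, info


def fit_cox(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> RiskModel:
    """Fit the Cox model for signature genes (genes x samples expression).

    ``surv`` has columns ``time`` and ``event`` indexed by sample.  Breslow
    tie handling; Newton iterations stop when the gradient norm drops below
    ``tol``.  Raises on fewer than 10 events, constant genes, singular
    information (e.g. duplicated covariates), separation, or
    non-convergence.
    """
    samples = [s for s in expr.columns if s in surv.index]
    if len(samples) < expr.shape[1]:
        missing = set(expr.columns) - set(samples)
        raise KeyError(f"samples without survival records: {sorted(missing)[:5]}")
    X = expr[samples].to_numpy(dtype=float).T  # samples x genes
    time = surv.loc[samples, "time"].to_numpy(dtype=float)
    event = surv.loc[samples, "event"].to_numpy(dtype=bool)
    if event.sum() < 10:
        raise ValueError(f"only {int(event.sum())} events; need >= 10")
    const = [g for g, col in zip(expr.index, X.T) if np.ptp(col) == 0]
    if const:
        raise ValueError(f"constant gene(s): {', '.join(map(str, const))}")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    Z = (X - center) / scale
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, grad, info = _cox_loglik(beta, Z, time, event)
        if np.linalg.norm(grad) < tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix (collinear genes?)") from exc
        # step-halving to keep the partial likelihood increasing
        for _ in range(30):
            cand = beta + step
            ll_new = _cox_loglik(cand, Z, time, event)[0]
            if ll_new >= ll - 1e-12:
                break
            step = step / 2
        beta = beta + step
        if np.max(np.abs(beta)) > 50:
            raise ValueError("separation detected: coefficients diverging")
        ll_old = ll
    else:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")
    del ll_old
    return RiskModel(gene_ids=list(expr.index), coefficients=beta / scale)


def compute_risk_score(model: RiskModel, expr: pd.DataFrame) -> pd.Series:
    """score_s = sum_i C_i * E_{i,s} over the model's genes."""
    missing = [g for g in model.gene_ids if g not in expr.index]
    if missing:
        raise KeyError(f"model gene(s) missing from expression: {', '.join(missing)}")
    E = expr.loc[model.gene_ids].to_numpy(dtype=float)
    return pd.Series(model.coefficients @ E, index=expr.columns, name="risk_score")


def median_split(scores: pd.Series | Sequence[float]) -> pd.Series:
    """'high' iff score >= median (midpoint of central order stats for even n)."""
    s = pd.Series(scores)
    if s.size < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(np.median(s.to_numpy(dtype=float)))
    return pd.Series(
        np.where(s.to_numpy(dtype=float) >= med, "high", "low"),
        index=s.index,
        name="risk_group",
    )


def logrank_test(groups: pd.Series, surv: pd.DataFrame) -> Tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value.

    Sums observed-minus-expected events for group 1 over distinct event
    times with the hypergeometric variance of the risk-set draw.
    """
    labels = pd.Series(groups)
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {names}")
    time = surv.loc[labels.index, "time"].to_numpy(dtype=float)
    event = surv.loc[labels.index, "event"].to_numpy(dtype=bool)
    g1 = (labels == names[0]).to_numpy()
    if not event.any():
        raise ValueError("no events in either group")
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
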