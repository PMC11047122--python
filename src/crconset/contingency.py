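"""Exact and chi-square 2x2 contingency statistics and the age-correlation filter.

The Fisher odds ratio is the conditional maximum-likelihood estimate under
the noncentral hypergeometric likelihood with all margins fixed, and the 95%
confidence interval inverts the one-sided tail probabilities at 0.025 per
side — the convention of R's ``fisher.test``.  The sample odds ratio
(ad/bc) is reported alongside for transparency.  The 2x2 chi-square applies
the Yates continuity correction, clamped at zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio


@dataclass(frozen=True)
class TwoByTwo:
    """Counts (a, b / c, d): row 1 = feature present, column 1 = condition present."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("2x2 cells must be non-negative")
        if self.total == 0:
            raise ValueError("2x2 total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    or_cmle: float
    ci_low: float
    ci_high: float
    or_sample: float


def fisher_exact_2x2(t: TwoByTwo) -> FisherResult:
    """Fisher's exact test with conditional-MLE odds ratio and 95% CI.

    The two-sided p sums hypergeometric probabilities no larger than the
    observed table's.  Zero-cell tables yield a 0 or infinite point estimate
    with the corresponding one-sided CI bound.
    """
    arr = t.as_array()
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    res = _scipy_odds_ratio(arr, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    if t.b * t.c == 0:
        or_sample = math.inf if t.a * t.d > 0 else math.nan
    else:
        or_sample = (t.a * t.d) / (t.b * t.c)
    return FisherResult(
        p_two_sided=p,
        or_cmle=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        or_sample=or_sample,
    )


def chi_square_2x2_yates(
    t: TwoByTwo, correction: bool = True
) -> Tuple[float, float]:
    """Pearson 2x2 chi-square with Yates continuity correction (1 df).

    The correction clamps |ad - bc| - n/2 at zero.  A zero row or column
    margin yields statistic 0, p 1 with a warning.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("2x2 table has a zero margin; no association testable")
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    return float(stat), float(p)


def overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> Tuple[FisherResult, TwoByTwo]:
    """Fisher test of the overlap of two gene sets within a universe.

    Builds the table (|A&B|, |A-B| / |B-A|, |universe-(A|B)|) and delegates
    to :func:`fisher_exact_2x2`.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    stray = (a | b) - u
    if stray:
        raise ValueError(
            f"elements outside the universe: {', '.join(sorted(stray)[:5])}"
        )
    table = TwoByTwo(
        len(a & b), len(a - b), len(b - a), len(u - (a | b))
    )
    return fisher_exact_2x2(table), table


def pearson_age_correlation(
    expr: pd.DataFrame, age_days, alpha: float = 0.05
) -> Set[str]:
    """Genes whose tumor expression correlates linearly with age at p < alpha.

    ``expr`` is genes x samples; ``age_days`` aligns with the columns.
    Constant-expression genes are excluded with a warning (correlation
    undefined).
    """
    age = np.asarray(age_days, dtype=float)
    if expr.shape[1] != age.size:
        raise ValueError("age vector length must match sample count")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(age) == 0:
        raise ValueError("ages must vary")
    hits: Set[str] = set()
    skipped = []
    for gene, row in expr.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            skipped.append(gene)
            continue
        _, p = stats.pearsonr(vals, age)
        if p < alpha:
            hits.add(gene)
    if skipped:
        warnings.warn(
            f"{len(skipped)} constant-expression gene(s) excluded from the "
            "age-correlation test"
        )
    return hits
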