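"""Wilcoxon signed-rank and rank-sum wrappers with fixed conventions.

Conventions match the defaults of the R statistical environment: the paired
test drops zero differences and uses the exact null distribution when there
are at most 25 nonzero pairs and no tied absolute differences, otherwise a
normal approximation with continuity correction; the unpaired rank-sum test
is exact for small tie-free samples, otherwise normal with continuity
correction.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

EXACT_LIMIT = 25


def paired_wilcoxon(x, y=None) -> float:
    """Two-sided signed-rank p-value for paired samples (or differences).

    Pass either paired arrays ``x, y`` (tests x - y) or a single array of
    differences.
    """
    d = np.asarray(x, dtype=float) if y is None else np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks_tied = len(np.unique(np.abs(d))) < d.size
    if d.size <= EXACT_LIMIT and not ranks_tied:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return float(res.pvalue)


def rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    if not ties and x.size <= EXACT_LIMIT and y.size <= EXACT_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)
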