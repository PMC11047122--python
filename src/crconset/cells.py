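"""Cell-type deconvolution score summaries.

Operates on tables of per-sample enrichment scores for 64 reference cell
types (composite immune/stroma aggregates excluded).  Provides
lymphoid/myeloid/other proportion aggregation, paired and unpaired
score comparisons, ranking of top differential cell types between cohorts,
and a PCA embedding of samples over top-variance features.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .ranktests import paired_wilcoxon, rank_sum

GROUPS = ("lymphoid", "myeloid", "other")


def default_cell_grouping() -> Dict[str, str]:
    """The packaged 64-type lymphoid/myeloid/other grouping.

    Follows the deconvolution tool's published lineage annotations
    (lymphoid and myeloid progenitors grouped with their lineage; stem,
    stromal and epithelial types under "other").  Fully overridable via
    any two-column TSV.
    """
    path = resources.files("crconset.data").joinpath("cell_groups.tsv")
    grouping = {}
    for line in path.read_text().splitlines()[1:]:
        if line.strip():
            cell, group = line.split("\t")
            grouping[cell] = group
    return grouping


def group_proportions(
    scores: pd.DataFrame, grouping: Optional[Dict[str, str]] = None
) -> pd.DataFrame:
    """Per-sample proportions: group score sum over total score sum.

    Returns samples x (lymphoid, myeloid, other); rows sum to 1.
    """
    grouping = grouping or default_cell_grouping()
    missing = [t for t in scores.index if t not in grouping]
    if missing:
        raise ValueError(f"cell types missing from grouping: {missing[:5]}")
    if (scores.to_numpy() < 0).any():
        raise ValueError("negative cell scores")
    totals = scores.sum(axis=0)
    dead = totals.index[totals == 0]
    if len(dead):
        raise ValueError(f"all-zero sample(s): {', '.join(map(str, dead))}")
    out = {}
    labels = pd.Series({t: grouping[t] for t in scores.index})
    for grp in GROUPS:
        members = labels.index[labels == grp]
        out[grp] = scores.loc[members].sum(axis=0) / totals
    return pd.DataFrame(out)[list(GROUPS)]


def compare_scores(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: str,
) -> pd.Series:
    """Two-sided rank-test p-values per row (cell type or group proportion).

    ``contrast`` is ``"paired_tumor_normal"`` (signed-rank within matched
    pairs; requires complete pairs and at least 3 of them) or
    ``"unpaired_cohort"`` (rank-sum between early and late samples).
    """
    if contrast == "paired_tumor_normal":
        patients = sorted(meta["patient_id"].unique())
        t_cols, n_cols = [], []
        for p in patients:
            sub = meta[meta["patient_id"] == p]
            tum = sub.index[sub["tissue"] == "tumor"]
            nor = sub.index[sub["tissue"] == "normal"]
            if len(tum) != 1 or len(nor) != 1:
                raise ValueError(f"patient {p!r} lacks a complete tumor/normal pair")
            t_cols.append(tum[0])
            n_cols.append(nor[0])
        if len(patients) < 3:
            raise ValueError(f"only {len(patients)} pairs; need >= 3")
        return pd.Series(
            {
                row: paired_wilcoxon(
                    scores.loc[row, t_cols].to_numpy(),
                    scores.loc[row, n_cols].to_numpy(),
                )
                for row in scores.index
            },
            name="p_value",
        )
    if contrast == "unpaired_cohort":
        early = meta.index[meta["cohort"] == "early"]
        late = meta.index[meta["cohort"] == "late"]
        early = [s for s in early if s in scores.columns]
        late = [s for s in late if s in scores.columns]
        if not early or not late:
            raise ValueError("both cohorts must be present")
        return pd.Series(
            {
                row: rank_sum(
                    scores.loc[row, early].to_numpy(),
                    scores.loc[row, late].to_numpy(),
                )
                for row in scores.index
            },
            name="p_value",
        )
    raise ValueError(f"unknown contrast {contrast!r}")


def top_differential_cells(
    scores: pd.DataFrame, meta: pd.DataFrame, k: int = 5
) -> pd.DataFrame:
    """Cell types ranked by unpaired cohort test p (ties by |median diff|).

    Returns the top k with columns p_value, median_diff and a
    ``significant`` flag (p < 0.05); when nothing is significant the ranking
    is still reported, flagged non-significant.
    """
    if k > scores.shape[0]:
        warnings.warn(f"k={k} exceeds {scores.shape[0]} cell types; clamped")
        k = scores.shape[0]
    if k < 0:
        raise ValueError("k must be non-negative")
    p = compare_scores(scores, meta, "unpaired_cohort")
    early = [s for s in meta.index[meta["cohort"] == "early"] if s in scores.columns]
    late = [s for s in meta.index[meta["cohort"] == "late"] if s in scores.columns]
    diff = scores[early].median(axis=1) - scores[late].median(axis=1)
    ranked = pd.DataFrame({"p_value": p, "median_diff": diff})
    ranked["abs_diff"] = ranked["median_diff"].abs()
    ranked = ranked.sort_values(
        ["p_value", "abs_diff"], ascending=[True, False]
    ).drop(columns="abs_diff")
    ranked["significant"] = ranked["p_value"] < 0.05
    return ranked.head(k)


def pca_embed(
    matrix: pd.DataFrame, n_top: int = 5000, n_components: int = 2
) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples over the top-variance features.

    ``matrix`` is features x samples.  The ``n_top`` highest-variance rows
    are selected, rows are centered, and samples are projected onto the
    leading principal components (ordered by decreasing variance
    explained).  Returns (samples x components coordinates, variance
    explained ratios).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    variances = matrix.var(axis=1)
    if (variances == 0).all():
        raise ValueError("constant matrix: PCA undefined")
    top = variances.sort_values(ascending=False).index[: min(n_top, len(variances))]
    X = matrix.loc[top].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    # SVD of features x samples: right singular vectors give sample scores
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, s.size)
    coords = (Vt[:n_components].T * s[:n_components])
    total_var = (s**2).sum()
    var_explained = (s[:n_components] ** 2) / total_var
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=matrix.columns, columns=cols), var_explained


def mean_impute_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean-impute missing values per row (for PSI matrices ahead of PCA)."""
    frac = float(matrix.isna().to_numpy().mean())
    if frac:
        warnings.warn(f"mean-imputing {frac:.1%} missing values")
    return matrix.apply(lambda r: r.fillna(r.mean()), axis=1)
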