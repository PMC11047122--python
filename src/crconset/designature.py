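"""Cohort-specific differential-expression signature calling.

Implements the filter cascade that identifies genes differentially expressed
in early-onset tumors but not later-onset ones, and the paired
signed-rank refinement that narrows those candidates to a compact signature:

1. significance within a cohort: adjusted p < 0.05, |LFC| > 1 and mean
   normalized counts > 50;
2. cohort-uniqueness: the later-onset cohort is either clearly
   non-significant (padj > 0.2, |LFC| < 0.7, mean counts > 50) or the two
   cohorts' fold changes differ by more than 1.5 with the early-onset effect
   dominating (larger magnitude, or significant in opposite directions);
3. refinement: paired tumor-vs-normal signed-rank test per cohort; a gene is
   kept when significant early (p < 0.05) and either clearly null late
   (p > 0.25) or significant late but in the opposite direction or with a
   median per-patient LFC difference above 1.5.

Normalization here is a deliberately simple stand-in — log2 of
median-of-ratios-normalized counts plus one; every downstream rule operates
on whatever normalized matrix it is given.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .io import PairedExpressionMatrix
from .ranktests import paired_wilcoxon

logger = logging.getLogger(__name__)


@dataclass
class UniqueGeneCall:
    """A gene called differentially expressed in the early cohort only."""

    gene_id: str
    direction: str  # up | down
    rule_fired: str  # locrc_not_significant | lfc_difference
    eo_stats: Tuple[float, float, float]  # (base_mean, lfc, padj)
    lo_stats: Tuple[float, float, float]


@dataclass
class SignatureGene:
    """A unique gene surviving the paired signed-rank refinement."""

    gene_id: str
    eo_wilcoxon_p: float
    lo_wilcoxon_p: float
    eo_median_lfc: float
    lo_median_lfc: float
    qualifying_rule: str  # lo_nonsig | opposite_direction | lfc_difference


def size_factors(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios column size factors.

    Computed over genes with nonzero counts in every sample, each sample's
    factor being the median ratio of its counts to the per-gene geometric
    mean.
    """
    counts = raw.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    zero_samples = raw.columns[counts.sum(axis=0) == 0]
    if len(zero_samples):
        raise ValueError(f"all-zero sample(s): {', '.join(map(str, zero_samples))}")
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has nonzero counts in all samples")
    log_geo = np.log(counts[allpos]).mean(axis=1)
    ratios = np.log(counts[allpos]) - log_geo[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=raw.columns)


def normalize_counts(raw: pd.DataFrame, meta: pd.DataFrame) -> PairedExpressionMatrix:
    """log2(size-factor-normalized count + 1) expression with paired metadata.

    All-zero gene rows are retained and flagged in
    ``result.values.attrs["all_zero_genes"]``.
    """
    sf = size_factors(raw)
    norm = raw.div(sf, axis=1)
    values = np.log2(norm + 1.0)
    all_zero = [g for g in raw.index if (raw.loc[g] == 0).all()]
    if all_zero:
        warnings.warn(f"{len(all_zero)} all-zero gene row(s) retained but flagged")
    values.attrs["all_zero_genes"] = all_zero
    values.attrs["size_factors"] = sf.to_dict()
    return PairedExpressionMatrix(values, meta.copy())


def per_patient_lfc(expr: PairedExpressionMatrix) -> pd.DataFrame:
    """Per-patient log2 fold change: tumor minus normal, per gene.

    Returns a genes x patients DataFrame.
    """
    cols = {}
    for patient in expr.patients:
        sub = expr.meta[expr.meta["patient_id"] == patient]
        if sorted(sub["tissue"]) != ["normal", "tumor"]:
            raise ValueError(f"patient {patient!r} is not a complete pair")
        t = expr.values[expr.sample_of(patient, "tumor")]
        n = expr.values[expr.sample_of(patient, "normal")]
        cols[patient] = t - n
    return pd.DataFrame(cols)


def call_significant(
    table: pd.DataFrame, cfg: PipelineConfig | None = None
) -> Dict[str, Set[str]]:
    """Per-cohort significant gene sets.

    up: padj < 0.05 and LFC > 1 and base_mean > 50 (strict); down likewise
    with LFC < -1.  Missing padj is non-significant.
    """
    cfg = cfg or PipelineConfig()
    padj_ok = table["padj"].notna() & (table["padj"] < cfg.de_padj)
    mean_ok = table["base_mean"] > cfg.de_base_mean
    up = set(table.index[padj_ok & mean_ok & (table["lfc"] > cfg.de_lfc)])
    down = set(table.index[padj_ok & mean_ok & (table["lfc"] < -cfg.de_lfc)])
    return {"up": up, "down": down}


def _lo_not_significant(row: pd.Series, cfg: PipelineConfig) -> bool:
    return (
        pd.notna(row["padj"])
        and row["padj"] > cfg.lo_nonsig_padj
        and abs(row["lfc"]) < cfg.lo_nonsig_lfc
        and row["base_mean"] > cfg.lo_nonsig_base_mean
    )


def call_unique_degs(
    eo: pd.DataFrame, lo: pd.DataFrame, cfg: PipelineConfig | None = None
) -> List[UniqueGeneCall]:
    """Genes significant early-onset and either null or divergent later-onset.

    A gene in the early cohort's significant up/down set is unique when the
    later-onset table satisfies the non-significance rule, or the
    LFC-difference rule fires: |LFC_eo - LFC_lo| > 1.5 with the early effect
    of larger magnitude, or the two cohorts significant in opposite
    directions.  Genes present in only one table are excluded and logged.
    """
    cfg = cfg or PipelineConfig()
    eo_sig = call_significant(eo, cfg)
    lo_sig = call_significant(lo, cfg)
    calls: List[UniqueGeneCall] = []
    for direction in ("up", "down"):
        for gene in sorted(eo_sig[direction]):
            if gene not in lo.index:
                logger.info("gene %s absent from the later-onset table; excluded", gene)
                continue
            eo_row, lo_row = eo.loc[gene], lo.loc[gene]
            if cfg.lfc_difference_on_abs:
                diff = abs(abs(eo_row["lfc"]) - abs(lo_row["lfc"]))
            else:
                diff = abs(eo_row["lfc"] - lo_row["lfc"])
            opposite = (direction == "up" and gene in lo_sig["down"]) or (
                direction == "down" and gene in lo_sig["up"]
            )
            dominant = abs(eo_row["lfc"]) > abs(lo_row["lfc"])
            lfc_rule = diff > cfg.lfc_difference and (dominant or opposite)
            if _lo_not_significant(lo_row, cfg):
                rule = "locrc_not_significant"
            elif lfc_rule:
                rule = "lfc_difference"
            else:
                continue
            calls.append(
                UniqueGeneCall(
                    gene_id=gene,
                    direction=direction,
                    rule_fired=rule,
                    eo_stats=(eo_row["base_mean"], eo_row["lfc"], eo_row["padj"]),
                    lo_stats=(lo_row["base_mean"], lo_row["lfc"], lo_row["padj"]),
                )
            )
    return calls


def refine_signature(
    candidates: Sequence[UniqueGeneCall],
    eo_expr: PairedExpressionMatrix,
    lo_expr: PairedExpressionMatrix,
    cfg: PipelineConfig | None = None,
) -> List[SignatureGene]:
    """Paired signed-rank refinement of unique-gene candidates.

    For each candidate, tumor vs normal is tested within each cohort on
    per-patient log fold changes.  Retained when p_eo < 0.05 and either
    p_lo > 0.25, or p_lo < 0.05 with opposite median per-patient LFC signs
    or an absolute median-LFC difference above 1.5.
    """
    cfg = cfg or PipelineConfig()
    eo_lfc = per_patient_lfc(eo_expr)
    lo_lfc = per_patient_lfc(lo_expr)
    for name, mat in (("early", eo_lfc), ("late", lo_lfc)):
        if mat.shape[1] < 5:
            raise ValueError(
                f"{name} cohort has {mat.shape[1]} pairs; need >= 5 for the "
                "signed-rank refinement"
            )
    out: List[SignatureGene] = []
    for cand in candidates:
        gene = cand.gene_id
        if gene not in eo_lfc.index or gene not in lo_lfc.index:
            raise KeyError(f"candidate gene {gene!r} missing from an expression matrix")
        d_eo = eo_lfc.loc[gene].to_numpy()
        d_lo = lo_lfc.loc[gene].to_numpy()
        p_eo = paired_wilcoxon(d_eo)
        p_lo = paired_wilcoxon(d_lo)
        med_eo = float(np.median(d_eo))
        med_lo = float(np.median(d_lo))
        if p_eo >= cfg.wilcoxon_eo_p:
            continue
        if p_lo > cfg.wilcoxon_lo_p:
            rule = "lo_nonsig"
        elif p_lo < cfg.wilcoxon_eo_p and med_eo * med_lo < 0:
            rule = "opposite_direction"
        elif p_lo < cfg.wilcoxon_eo_p and abs(med_eo - med_lo) > cfg.lfc_difference:
            rule = "lfc_difference"
        else:
            continue
        out.append(
            SignatureGene(
                gene_id=gene,
                eo_wilcoxon_p=p_eo,
                lo_wilcoxon_p=p_lo,
                eo_median_lfc=med_eo,
                lo_median_lfc=med_lo,
                qualifying_rule=rule,
            )
        )
    return out


def de_table_from_counts(raw: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Summarize paired counts into a DE result table (stand-in caller).

    base_mean is the mean of size-factor-normalized counts, LFC the mean
    per-patient tumor-minus-normal difference of log2 normalized values, and
    padj the Benjamini-Hochberg-adjusted paired t-test p-value.  This exists
    so the filter cascade can be exercised end-to-end on synthetic counts;
    it makes no claim of equivalence with any published DE model.
    """
    expr = normalize_counts(raw, meta)
    sf = pd.Series(expr.values.attrs["size_factors"])
    norm_counts = raw.div(sf, axis=1)
    lfc = per_patient_lfc(expr)
    mean_lfc = lfc.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_1samp(lfc.to_numpy(), 0.0, axis=1)
    pvals = pd.Series(t_res.pvalue, index=lfc.index)
    pvals[lfc.std(axis=1) == 0] = np.nan
    ok = pvals.notna()
    padj = pd.Series(np.nan, index=pvals.index)
    padj[ok] = stats.false_discovery_control(pvals[ok], method="bh")
    return pd.DataFrame(
        {
            "base_mean": norm_counts.mean(axis=1),
            "lfc": mean_lfc,
            "padj": padj,
        }
    )
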