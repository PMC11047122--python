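"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is a pure function of its spec (including the seed): the
same spec yields bit-identical outputs.  The defaults emulate the study
conditions: 21 early-onset and 22 later-onset patients, each contributing a
matched tumor/normal pair; 22 planted uniquely-upregulated and 26
uniquely-downregulated genes; 82 early-significant, 191 late-significant
and 49 shared cross-caller splice events; negative-binomial counts with
dispersion 0.1 and library sizes log-uniform over a 4-fold range; ~30%
independent censoring for survival times.

The junction-peptide ground truth is computed here by direct string
concatenation and a local codon table, independent of the pipeline's BED12
extraction path, so it can serve as an oracle for that path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cells import default_cell_grouping
from .config import PipelineConfig
from .designature import UniqueGeneCall
from .events import Interval, SpliceEvent
from .io import (
    PairedExpressionMatrix,
    write_rmats_table,
    write_whippet_diff,
)

EVENT_TYPE_CYCLE = ("SE", "SE", "SE", "MXE", "A5SS", "SE", "A3SS", "SE", "RI", "SE")


@dataclass
class SimulationSpec:
    """Study-condition parameters for all generators."""

    # cohort design
    n_early: int = 21
    n_late: int = 22
    # expression
    n_genes: int = 2000
    n_unique_up: int = 22
    n_unique_down: int = 26
    unique_lfc: float = 3.0
    n_signature: int = 8
    nb_dispersion: float = 0.1
    libsize_fold_range: float = 4.0
    # splicing
    n_splice_early: int = 82
    n_splice_late: int = 191
    n_splice_shared: int = 49
    n_rmats_only: int = 20
    n_whippet_only: int = 15
    n_splice_decoys: int = 40
    # toy genome / peptides
    n_peptide_events: int = 12
    chrom_length: int = 20000
    flank_nt: int = 27
    # survival
    surv_baseline_hazard: float = 1.0 / 1000.0  # per day
    surv_censoring: float = 0.3
    true_coefficients: Tuple[float, ...] = (1.5, -1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    # cell scores
    planted_cell_shifts: Dict[Tuple[str, str, str], float] = field(
        default_factory=lambda: {("aDC", "early", "tumor"): 2.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_unique_up + self.n_unique_down > self.n_genes:
            raise ValueError("planted gene counts exceed total genes")
        if self.n_signature > self.n_unique_up + self.n_unique_down:
            raise ValueError("signature count exceeds unique-gene count")
        if self.n_splice_shared > min(self.n_splice_early, self.n_splice_late):
            raise ValueError("shared splice events exceed a cohort total")
        for name in ("nb_dispersion", "libsize_fold_range", "surv_baseline_hazard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Planted truth accompanying each generated dataset."""

    unique_up: List[str] = field(default_factory=list)
    unique_down: List[str] = field(default_factory=list)
    signature_genes: List[str] = field(default_factory=list)
    splice_early_keys: List[Tuple[str, int]] = field(default_factory=list)
    splice_late_keys: List[Tuple[str, int]] = field(default_factory=list)
    splice_shared_keys: List[Tuple[str, int]] = field(default_factory=list)
    peptides: List[dict] = field(default_factory=list)
    true_coefficients: Optional[np.ndarray] = None
    cell_shifts: Dict[Tuple[str, str, str], float] = field(default_factory=dict)


def _meta_frame(cohort: str, n: int, prefix: str) -> pd.DataFrame:
    rows = []
    for i in range(n):
        pid = f"{prefix}{i + 1:02d}"
        rows.append((f"{pid}_T", pid, "tumor", cohort))
        rows.append((f"{pid}_N", pid, "normal", cohort))
    return pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "tissue", "cohort"]
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# Paired negative-binomial counts with planted cohort-specific effects
# ---------------------------------------------------------------------------


def simulate_paired_counts(
    spec: SimulationSpec,
) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Paired tumor/normal NB counts with early-cohort-only planted effects.

    Planted genes carry the spec's log2 fold change in early-onset tumors
    only; library sizes are log-uniform over the spec's fold range with a
    mild patient random effect.  Returns (counts genes x samples, sample
    metadata, ground truth).
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    meta = pd.concat(
        [_meta_frame("early", spec.n_early, "E"), _meta_frame("late", spec.n_late, "L")]
    )
    up = genes[: spec.n_unique_up]
    down = genes[spec.n_unique_up : spec.n_unique_up + spec.n_unique_down]
    base = np.exp(rng.normal(np.log(60.0), 1.0, size=spec.n_genes))
    planted_idx = np.arange(spec.n_unique_up + spec.n_unique_down)
    base[planted_idx] = np.maximum(base[planted_idx], 150.0)  # keep mean counts > 50
    lfc = np.zeros(spec.n_genes)
    lfc[: spec.n_unique_up] = spec.unique_lfc
    lfc[spec.n_unique_up : spec.n_unique_up + spec.n_unique_down] = -spec.unique_lfc

    lib = {}
    for patient in meta["patient_id"].unique():
        pat_eff = np.exp(rng.normal(0.0, 0.1))
        for tissue in ("tumor", "normal"):
            lo, hi = 1.0, spec.libsize_fold_range
            lib[f"{patient}_{tissue[0].upper()}"] = pat_eff * np.exp(
                rng.uniform(np.log(lo), np.log(hi))
            )
    counts = {}
    r = 1.0 / spec.nb_dispersion
    for sample, row in meta.iterrows():
        mu = base * lib[sample]
        if row["tissue"] == "tumor" and row["cohort"] == "early":
            mu = mu * np.power(2.0, lfc)
        p = r / (r + mu)
        counts[sample] = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=genes)
    truth = GroundTruth(unique_up=list(up), unique_down=list(down))
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# Deterministic expression matrices with a planted refinement signature
# ---------------------------------------------------------------------------


def _signed_rank_pattern(n: int, n_pos: int, scale: float = 0.1) -> np.ndarray:
    """Differences with the ``n_pos`` largest magnitudes positive.

    Magnitudes are distinct multiples of ``scale`` so the exact signed-rank
    distribution applies without ties; the resulting two-sided p falls in
    the borderline band (between 0.05 and 0.25 for the default cohort
    sizes), which is what the non-signature candidates need.
    """
    mags = scale * np.arange(1, n + 1)
    signs = np.concatenate([-np.ones(n - n_pos), np.ones(n_pos)])
    return mags * signs


def simulate_expression_with_signature(
    spec: SimulationSpec,
) -> Tuple[PairedExpressionMatrix, PairedExpressionMatrix, List[UniqueGeneCall], GroundTruth]:
    """Expression matrices whose signed-rank refinement outcome is planted.

    All candidate genes are strongly changed in early-onset tumors.  The
    planted signature genes have exactly zero tumor-minus-normal difference
    in the later-onset cohort (signed-rank p = 1, clearly null), while the
    non-signature candidates carry a later-onset difference pattern whose
    exact signed-rank p lands in the borderline band (0.05, 0.25] that the
    refinement rule excludes.  Returns (early matrix, late matrix,
    candidate calls, truth).
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_cand = spec.n_unique_up + spec.n_unique_down
    genes = [f"G{i + 1:05d}" for i in range(n_cand)]
    sig = sorted(rng.choice(genes, size=spec.n_signature, replace=False).tolist())
    meta_e = _meta_frame("early", spec.n_early, "E")
    meta_l = _meta_frame("late", spec.n_late, "L")

    def build(meta: pd.DataFrame, diffs: Dict[str, np.ndarray]) -> PairedExpressionMatrix:
        patients = sorted(meta["patient_id"].unique())
        vals = pd.DataFrame(0.0, index=genes, columns=list(meta.index))
        baseline = rng.uniform(5.0, 9.0, size=len(genes))
        for g_i, gene in enumerate(genes):
            for p_i, pat in enumerate(patients):
                n_col, t_col = f"{pat}_N", f"{pat}_T"
                vals.loc[gene, n_col] = baseline[g_i]
                vals.loc[gene, t_col] = baseline[g_i] + diffs[gene][p_i]
        return PairedExpressionMatrix(vals, meta.copy())

    # early cohort: all candidates clearly changed (distinct magnitudes, one sign)
    eo_diffs = {}
    for i, gene in enumerate(genes):
        sign = 1.0 if i < spec.n_unique_up else -1.0
        eo_diffs[gene] = sign * (2.0 + 0.01 * np.arange(1, spec.n_early + 1))
    # late cohort: zero for signature genes, borderline pattern otherwise
    n_pos = _borderline_n_pos(spec.n_late)
    lo_diffs = {}
    for gene in genes:
        if gene in sig:
            lo_diffs[gene] = np.zeros(spec.n_late)
        else:
            lo_diffs[gene] = _signed_rank_pattern(spec.n_late, n_pos)
    eo_expr = build(meta_e, eo_diffs)
    lo_expr = build(meta_l, lo_diffs)
    candidates = [
        UniqueGeneCall(
            gene_id=g,
            direction="up" if i < spec.n_unique_up else "down",
            rule_fired="locrc_not_significant",
            eo_stats=(200.0, float(np.mean(eo_diffs[g])), 1e-6),
            lo_stats=(200.0, float(np.mean(lo_diffs[g])), 0.9),
        )
        for i, g in enumerate(genes)
    ]
    truth = GroundTruth(
        unique_up=genes[: spec.n_unique_up],
        unique_down=genes[spec.n_unique_up :],
        signature_genes=sig,
    )
    return eo_expr, lo_expr, candidates, truth


def _borderline_n_pos(n: int) -> int:
    """Number of top-magnitude positive diffs putting the exact signed-rank
    two-sided p inside (0.05, 0.25]."""
    from scipy.stats import wilcoxon

    for n_pos in range(n, 0, -1):
        p = wilcoxon(_signed_rank_pattern(n, n_pos), method="exact").pvalue
        if 0.05 < p <= 0.25:
            return n_pos
    raise ValueError(f"no borderline pattern for n={n}")


# ---------------------------------------------------------------------------
# Dual-caller splice tables
# ---------------------------------------------------------------------------


def _make_event(
    idx: int,
    event_type: str,
    delta_psi: float,
    fdr: float,
    n_tumor: int,
    n_normal: int,
    rng: np.random.Generator,
    coverage_mean: float = 35.0,
    gene: Optional[str] = None,
) -> SpliceEvent:
    chrom = f"chr{idx % 5 + 1}"
    start = 1000 + (idx // 5) * 1000
    length = 60 + (idx * 37) % 150
    region = Interval(start, start + length)
    up = Interval(start - 400, start - 200)
    down = Interval(region.end + 200, region.end + 400)
    ijc = rng.poisson(coverage_mean * 0.6, size=n_tumor) + 1
    sjc = rng.poisson(coverage_mean * 0.4, size=n_tumor) + 1
    ijc_n = rng.poisson(coverage_mean * 0.6, size=n_normal) + 1
    sjc_n = rng.poisson(coverage_mean * 0.4, size=n_normal) + 1
    return SpliceEvent(
        caller="event_level",
        event_type=event_type,
        chrom=chrom,
        strand="+" if idx % 2 == 0 else "-",
        region=region,
        region2=Interval(down.end + 200, down.end + 300) if event_type == "MXE" else None,
        upstream_exon=None if event_type == "A3SS" else up,
        downstream_exon=down,
        delta_psi=float(delta_psi),
        significance=float(fdr),
        gene_id=gene or f"SG{idx + 1:04d}",
        event_id=str(idx + 1),
        ijc_tumor=tuple(int(x) for x in ijc),
        sjc_tumor=tuple(int(x) for x in sjc),
        ijc_normal=tuple(int(x) for x in ijc_n),
        sjc_normal=tuple(int(x) for x in sjc_n),
    )


def _node_partner(ev: SpliceEvent, prob: float, delta_psi: float) -> SpliceEvent:
    """The node-level record matching ``ev`` under the harmonization rules.

    Node coordinates are written in the 1-based convention; for A3SS the end
    coordinate is shared and the start deliberately differs (the two callers
    describe alternative 3' sites from opposite ends).
    """
    if ev.event_type == "A3SS":
        region = Interval(ev.region.start + 17, ev.region.end)
    else:
        region = Interval(ev.region.start, ev.region.end + (11 if ev.event_type == "MXE" else 0))
    return SpliceEvent(
        caller="node_level",
        event_type="CE" if ev.event_type in ("SE", "MXE") else ev.event_type,
        chrom=ev.chrom,
        strand=ev.strand,
        region=region,
        delta_psi=float(delta_psi),
        significance=float(prob),
        gene_id=ev.gene_id,
        event_id=f"{ev.event_id}.n",
    )


def simulate_splice_tables(
    spec: SimulationSpec, out_dir: str | Path
) -> Tuple[Dict[str, Dict[str, Path]], GroundTruth]:
    """Write both caller dialects per cohort with planted significance.

    The planted event universe contains early-only, shared and late-only
    cross-caller-significant events, junction-count-only and
    node-level-only significant events (so concordance is below 1), and
    decoys failing one filter each.  Returns ({cohort: {"rmats_dir",
    "whippet"}}, ground truth) with the planted per-cohort match keys.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed + 2)
    n_early_only = spec.n_splice_early - spec.n_splice_shared
    n_late_only = spec.n_splice_late - spec.n_splice_shared
    categories = (
        ["early_only"] * n_early_only
        + ["shared"] * spec.n_splice_shared
        + ["late_only"] * n_late_only
        + ["rmats_only_early"] * spec.n_rmats_only
        + ["whippet_only_early"] * spec.n_whippet_only
        + ["decoy"] * spec.n_splice_decoys
    )
    truth = GroundTruth()
    cohort_events: Dict[str, Dict[str, list]] = {
        "early": {"rmats": [], "whippet": []},
        "late": {"rmats": [], "whippet": []},
    }
    n_t = {"early": spec.n_early, "late": spec.n_late}

    from .splicing import harmonize_key

    for idx, cat in enumerate(categories):
        etype = EVENT_TYPE_CYCLE[idx % len(EVENT_TYPE_CYCLE)]
        dpsi = float(rng.uniform(0.15, 0.5) * rng.choice([1.0, 1.0, -1.0]))
        sig_fdr = float(rng.uniform(0.001, 0.045))
        sig_prob = float(rng.uniform(0.75, 0.99))
        null_fdr, null_prob = 0.5, 0.3
        for cohort in ("early", "late"):
            significant = (
                (cat == "early_only" and cohort == "early")
                or (cat == "late_only" and cohort == "late")
                or cat == "shared"
            )
            fdr = sig_fdr if significant else null_fdr
            prob = sig_prob if significant else null_prob
            if cat == "rmats_only_early" and cohort == "early":
                fdr = sig_fdr  # junction-count caller alone calls it
            if cat == "whippet_only_early" and cohort == "early":
                prob = sig_prob
            if cat == "decoy":
                # fails exactly one junction-count filter, cycling through them
                mode = idx % 3
                fdr = 0.5 if mode == 0 else sig_fdr
                cov = 5.0 if mode == 1 else 35.0
                d = 0.05 if mode == 2 else dpsi
                ev = _make_event(
                    idx, etype, d, fdr, n_t[cohort], n_t[cohort], rng, coverage_mean=cov
                )
                prob = null_prob
            else:
                ev = _make_event(idx, etype, dpsi, fdr, n_t[cohort], n_t[cohort], rng)
            node = _node_partner(ev, prob, ev.delta_psi)
            if not (cat == "rmats_only_early" and cohort == "early"):
                cohort_events[cohort]["whippet"].append(node)
            if not (cat == "whippet_only_early" and cohort == "early"):
                cohort_events[cohort]["rmats"].append(ev)
            if significant:
                key = harmonize_key(ev)
                if cohort == "early":
                    truth.splice_early_keys.append(key)
                else:
                    truth.splice_late_keys.append(key)
                if cat == "shared" and cohort == "early":
                    truth.splice_shared_keys.append(key)

    paths: Dict[str, Dict[str, Path]] = {}
    for cohort in ("early", "late"):
        cdir = out_dir / cohort
        cdir.mkdir(parents=True, exist_ok=True)
        by_type: Dict[str, list] = {}
        for ev in cohort_events[cohort]["rmats"]:
            by_type.setdefault(ev.event_type, []).append(ev)
        for etype, evs in by_type.items():
            write_rmats_table(evs, cdir / f"{etype}.MATS.JC.txt", etype)
        write_whippet_diff(cohort_events[cohort]["whippet"], cdir / "whippet.diff")
        paths[cohort] = {"rmats_dir": cdir, "whippet": cdir / "whippet.diff"}
    return paths, truth


# ---------------------------------------------------------------------------
# Toy genome with planted junction peptides
# ---------------------------------------------------------------------------

_CODON = {}  # independent translation oracle, built from the standard code


def _build_codon_table() -> None:
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                _CODON[b1 + b2 + b3] = aas[i]
                i += 1


_build_codon_table()


def _oracle_translate(nt: str, frame: int) -> str:
    sub = nt[frame - 1 :]
    return "".join(
        _CODON.get(sub[i : i + 3], "X") for i in range(0, len(sub) - len(sub) % 3, 3)
    )


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def simulate_genome_with_events(
    spec: SimulationSpec, fasta_path: str | Path
) -> Tuple[List[SpliceEvent], GroundTruth]:
    """Random toy genome with planted cassette events and oracle peptides.

    Each planted skipped-exon event has flanking exons; the ground-truth
    junction peptide is built by directly concatenating the last
    ``flank_nt`` bases of the upstream exon, the variable exon and the first
    ``flank_nt`` bases of the downstream exon (reverse-complemented on the
    minus strand) and translating the three forward frames with a local
    codon table — a path fully independent of the pipeline's BED12
    extractor.
    """
    rng = np.random.default_rng(spec.seed + 3)
    chroms = {
        name: "".join(rng.choice(list("ACGT"), size=spec.chrom_length))
        for name in ("chr1", "chr2")
    }
    with open(fasta_path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    events: List[SpliceEvent] = []
    truth = GroundTruth()
    stride = 800  # > max event span (exons + introns), keeps events disjoint
    needed = 500 + ((spec.n_peptide_events + 1) // 2) * stride + 200
    if spec.chrom_length < needed:
        raise ValueError(
            f"chrom_length {spec.chrom_length} too short for "
            f"{spec.n_peptide_events} events; need >= {needed}"
        )
    for i in range(spec.n_peptide_events):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        origin = 500 + (i // 2) * stride
        up_len = int(rng.integers(40, 120))
        var_len = int(rng.integers(45, 90))
        down_len = int(rng.integers(40, 120))
        up = Interval(origin, origin + up_len)
        var = Interval(up.end + 150, up.end + 150 + var_len)
        down = Interval(var.end + 150, var.end + 150 + down_len)
        strand = "+" if i % 3 else "-"
        ev = SpliceEvent(
            caller="event_level",
            event_type="SE",
            chrom=chrom,
            strand=strand,
            region=var,
            upstream_exon=up,
            downstream_exon=down,
            delta_psi=float(rng.uniform(0.15, 0.5)),
            significance=float(rng.uniform(0.001, 0.04)),
            gene_id=f"PG{i + 1:03d}",
            event_id=f"pep{i + 1}",
            ijc_tumor=tuple(int(x) for x in rng.poisson(30, size=spec.n_early) + 1),
            sjc_tumor=tuple(int(x) for x in rng.poisson(15, size=spec.n_early) + 1),
            ijc_normal=tuple(int(x) for x in rng.poisson(30, size=spec.n_early) + 1),
            sjc_normal=tuple(int(x) for x in rng.poisson(15, size=spec.n_early) + 1),
        )
        events.append(ev)
        seq = chroms[chrom]
        f = spec.flank_nt
        nt = seq[up.end - min(f, up.length) : up.end] + seq[var.start : var.end] + seq[
            down.start : down.start + min(f, down.length)
        ]
        if strand == "-":
            nt = "".join(_RC[b] for b in reversed(nt))
        for frame in (1, 2, 3):
            pep = _oracle_translate(nt, frame)
            truth.peptides.append(
                {
                    "event_id": ev.event_id,
                    "chrom": chrom,
                    "strand": strand,
                    "frame": frame,
                    "peptide": pep,
                    "dropped_for_stop": "*" in pep,
                }
            )
    return events, truth


# ---------------------------------------------------------------------------
# Survival and cell scores
# ---------------------------------------------------------------------------


def simulate_survival(
    spec: SimulationSpec, scores: Sequence[float], seed_offset: int = 4
) -> pd.DataFrame:
    """Event times with hazard proportional to exp(score), uniform censoring.

    The censoring window is calibrated so roughly the spec's censoring
    fraction is censored at the baseline hazard.  Returns a table with
    ``time`` and ``event`` indexed like ``scores``.
    """
    s = pd.Series(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    rng = np.random.default_rng(spec.seed + seed_offset)
    lam = spec.surv_baseline_hazard * np.exp(s.to_numpy())
    t = rng.exponential(1.0 / lam)
    # with T ~ Exp(h0) and C ~ U(0, tau): P(censor) = (1 - e^-h0·tau)/(h0·tau)
    from scipy.optimize import brentq

    q = spec.surv_censoring
    x = brentq(lambda x: (1 - np.exp(-x)) / x - q, 1e-6, 1e3)
    tau = x / spec.surv_baseline_hazard
    c = rng.uniform(0, tau, size=len(s))
    return pd.DataFrame(
        {"time": np.minimum(t, c), "event": t <= c},
        index=s.index if s.index is not None else None,
    )


def simulate_cell_scores(
    spec: SimulationSpec,
) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Nonnegative 64-type score table with planted multiplicative shifts.

    Scores are gamma-distributed around per-type baselines; each planted
    (cell type, cohort, tissue) shift multiplies that stratum's mean.
    Returns (scores types x samples, sample metadata, truth).
    """
    rng = np.random.default_rng(spec.seed + 5)
    types = list(default_cell_grouping())
    meta = pd.concat(
        [_meta_frame("early", spec.n_early, "E"), _meta_frame("late", spec.n_late, "L")]
    )
    baseline = np.exp(rng.normal(np.log(0.05), 0.8, size=len(types)))
    scores = pd.DataFrame(0.0, index=types, columns=list(meta.index))
    for sample, row in meta.iterrows():
        mean = baseline.copy()
        for (ct, cohort, tissue), factor in spec.planted_cell_shifts.items():
            if row["cohort"] == cohort and row["tissue"] == tissue:
                mean[types.index(ct)] *= factor
        scores[sample] = rng.gamma(shape=8.0, scale=mean / 8.0)
    truth = GroundTruth(cell_shifts=dict(spec.planted_cell_shifts))
    return scores, meta, truth
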