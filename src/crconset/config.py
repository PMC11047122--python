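"""Pipeline configuration: every filter threshold in one place."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import yaml

#: the four common HLA class-I alleles used for 9-mer binding prediction
DEFAULT_ALLELES = ["HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01", "HLA-A*24:02"]


@dataclass
class PipelineConfig:
    """Thresholds and knobs for every pipeline stage.

    Defaults follow the study conditions: DE significance at adjusted
    p < 0.05, |LFC| > 1, mean normalized counts > 50; the later-onset
    "not significant" rule at padj > 0.2, |LFC| < 0.7, mean counts > 50;
    LFC-difference rule at 1.5; splice filters FDR < 0.05, |dPSI| > 0.1,
    tumor coverage > 20 (junction-count caller) and |dPSI| > 0.1 with
    probability > 0.7 (node-level caller); 27-nt flanks (9 codons) for
    junction peptides; strong binders at percent-rank <= 0.5.
    """

    # DE cascade
    de_padj: float = 0.05
    de_lfc: float = 1.0
    de_base_mean: float = 50.0
    lo_nonsig_padj: float = 0.2
    lo_nonsig_lfc: float = 0.7
    lo_nonsig_base_mean: float = 50.0
    lfc_difference: float = 1.5
    lfc_difference_on_abs: bool = False  # alternative |.|-difference reading
    wilcoxon_eo_p: float = 0.05
    wilcoxon_lo_p: float = 0.25
    # splice filters
    rmats_fdr: float = 0.05
    rmats_dpsi: float = 0.1
    rmats_coverage: float = 20.0
    whippet_dpsi: float = 0.1
    whippet_prob: float = 0.7
    strict_sign_match: bool = False
    # neoantigen construction
    flank_nt: int = 27
    strong_binder_rank: float = 0.5
    truncate_at_stop: bool = False
    hla_alleles: List[str] = field(default_factory=lambda: list(DEFAULT_ALLELES))
    # age split (days; ~50 years)
    age_cutoff_days: float = 18250.0
    # misc
    cell_grouping_path: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"threshold {f.name} must be finite")
        if self.flank_nt < 0:
            raise ValueError("flank_nt must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
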