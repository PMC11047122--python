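"""Domain types for alternative-splicing events and spliced genomic intervals.

All genomic intervals are stored internally as 0-based half-open
``[start, end)``; 1-based views exist only at format boundaries and in the
harmonized match keys used to intersect events across callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")

#: Caller flavors. "event_level" is the junction-count caller dialect
#: (rMATS-style, 0-based starts); "node_level" is the per-node dialect
#: (Whippet-style, 1-based inclusive coordinates).
CALLERS = ("event_level", "node_level")


@dataclass
class Interval:
    """0-based half-open genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval start {self.start} must be < end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SpliceEvent:
    """One alternative-splicing event from either caller.

    ``region`` is the variable region (the skipped exon for SE, the long exon
    for A5SS/A3SS, the retained intron for RI, the 5'-most alternative exon
    for MXE, with the second exon in ``region2``).  ``delta_psi`` follows the
    tumor-minus-normal sign convention.  ``significance`` holds the FDR for
    event_level events and the posterior probability for node_level events.
    """

    caller: str
    event_type: str
    chrom: str
    strand: str
    region: Interval
    delta_psi: float
    significance: float
    gene_id: str = ""
    event_id: str = ""
    region2: Optional[Interval] = None  # second MXE exon
    upstream_exon: Optional[Interval] = None
    downstream_exon: Optional[Interval] = None
    ijc_tumor: Optional[Tuple[int, ...]] = None
    sjc_tumor: Optional[Tuple[int, ...]] = None
    ijc_normal: Optional[Tuple[int, ...]] = None
    sjc_normal: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.caller not in CALLERS:
            raise ValueError(f"unknown caller {self.caller!r}")
        if abs(self.delta_psi) > 1 + 1e-12:
            raise ValueError(f"|delta PSI| must be <= 1, got {self.delta_psi}")
        if not 0 <= self.significance <= 1:
            raise ValueError(
                f"significance must be in [0, 1], got {self.significance}"
            )

    @property
    def mean_tumor_coverage(self) -> Optional[float]:
        """Mean over tumor replicates of inclusion + skipping junction counts."""
        if self.ijc_tumor is None or self.sjc_tumor is None:
            return None
        total = [i + s for i, s in zip(self.ijc_tumor, self.sjc_tumor)]
        return sum(total) / len(total) if total else None


@dataclass
class ReconciledEvent:
    """A caller-concordant event keyed by harmonized (chrom, 1-based coord)."""

    match_key: Tuple[str, int]
    event_level: SpliceEvent
    node_level: SpliceEvent
    significant_early: bool = False
    significant_late: bool = False

    @property
    def delta_psi(self) -> float:
        """Tumor-minus-normal PSI change, taken from the event-level caller."""
        return self.event_level.delta_psi


@dataclass
class Bed12Record:
    """A BED12 line: 0-based half-open with block (spliced-structure) fields."""

    chrom: str
    chrom_start: int
    chrom_end: int
    name: str
    score: int
    strand: str
    thick_start: int
    thick_end: int
    item_rgb: str
    block_count: int
    block_sizes: Sequence[int]
    block_starts: Sequence[int]

    def validate(self) -> None:
        """Check BED12 block arithmetic; raise ValueError on inconsistency."""
        if self.chrom_start < 0 or self.chrom_end <= self.chrom_start:
            raise ValueError("chromStart/chromEnd out of order")
        if self.block_count != len(self.block_sizes) or self.block_count != len(
            self.block_starts
        ):
            raise ValueError("blockCount disagrees with blockSizes/blockStarts")
        if self.block_count == 0:
            raise ValueError("at least one block required")
        if self.block_starts[0] != 0:
            raise ValueError("first blockStart must be 0")
        span = self.chrom_end - self.chrom_start
        prev_end = -1
        for bs, sz in zip(self.block_starts, self.block_sizes):
            if sz <= 0:
                raise ValueError("block sizes must be positive")
            if bs <= prev_end and prev_end >= 0:
                raise ValueError("blocks must be sorted and non-overlapping")
            prev_end = bs + sz - 1
        if self.block_starts[-1] + self.block_sizes[-1] != span:
            raise ValueError("last block must end at chromEnd - chromStart")

    def blocks_genomic(self) -> list[Interval]:
        """Blocks as absolute genomic 0-based half-open intervals."""
        return [
            Interval(self.chrom_start + bs, self.chrom_start + bs + sz)
            for bs, sz in zip(self.block_starts, self.block_sizes)
        ]
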