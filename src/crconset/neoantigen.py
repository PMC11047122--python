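"""Splice-junction neoantigen candidate construction.

Tumor-enriched splice events (variable region more included in tumor,
dPSI > 0) are converted to BED12 records whose three blocks are the last 27
nt of the upstream exon, the full variable region, and the first 27 nt of
the downstream exon — 27 nt = 9 codons, so junction-spanning 9-mers are
possible.  The spliced, strand-aware sequence is extracted from the genome,
translated over the three forward frames, frames containing a stop codon
are discarded whole, and every length-9 window of the surviving peptides is
scored against a pluggable MHC class-I binding-rank predictor.  A candidate
is a strong binder when its best percent-rank over any tested allele is at
most 0.5 (the predictor's top half-percent).

The binding predictor itself is not reimplemented: any callable
``(peptide_9mer, allele) -> percent_rank`` works, and a deterministic
hash-based mock ships for testing alongside a writer for
predictor-compatible peptide FASTA.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from Bio.Seq import Seq

from .config import DEFAULT_ALLELES, PipelineConfig
from .events import Bed12Record, Interval, ReconciledEvent, SpliceEvent


@dataclass
class PeptideCandidate:
    """A junction-spanning translated peptide with binding ranks."""

    event_key: Tuple[str, int]
    frame: int  # 1, 2 or 3
    peptide: str
    contains_stop: bool
    allele_ranks: Dict[str, float] = field(default_factory=dict)
    strong_binder: bool = False


def select_tumor_enriched(
    events: Sequence[ReconciledEvent | SpliceEvent],
) -> List[ReconciledEvent | SpliceEvent]:
    """Events whose variable region is more included in tumor (dPSI > 0)."""
    return [ev for ev in events if ev.delta_psi > 0]


def build_bed12_blocks(
    event: SpliceEvent,
    flank_nt: int = 27,
    region: Optional[Interval] = None,
    name: Optional[str] = None,
) -> Bed12Record:
    """BED12 record for one variable exon plus exon-adjacent flanks.

    Three blocks: the last ``flank_nt`` bases of the upstream exon, the full
    variable region, and the first ``flank_nt`` bases of the downstream
    exon.  Flanks are clamped (with a warning) to short exons; a missing
    flanking exon degrades to fewer blocks with a warning; ``flank_nt=0``
    yields the bare variable region.  ``region`` overrides the variable
    interval (used for the second MXE exon).
    """
    var = region or event.region
    blocks: List[Interval] = []
    if flank_nt > 0 and event.upstream_exon is not None:
        up = event.upstream_exon
        take = min(flank_nt, up.length)
        if take < flank_nt:
            warnings.warn(
                f"event {event.event_id}: upstream exon shorter than flank; "
                f"clamped to {take} nt"
            )
        blocks.append(Interval(up.end - take, up.end))
    elif flank_nt > 0:
        warnings.warn(f"event {event.event_id}: no upstream exon; flank omitted")
    blocks.append(var)
    if flank_nt > 0 and event.downstream_exon is not None:
        down = event.downstream_exon
        take = min(flank_nt, down.length)
        if take < flank_nt:
            warnings.warn(
                f"event {event.event_id}: downstream exon shorter than flank; "
                f"clamped to {take} nt"
            )
        blocks.append(Interval(down.start, down.start + take))
    elif flank_nt > 0:
        warnings.warn(f"event {event.event_id}: no downstream exon; flank omitted")
    blocks.sort(key=lambda b: b.start)
    for prev, nxt in zip(blocks, blocks[1:]):
        if nxt.start < prev.end:
            raise ValueError(f"event {event.event_id}: overlapping blocks")
    start = blocks[0].start
    end = blocks[-1].end
    rec = Bed12Record(
        chrom=event.chrom,
        chrom_start=start,
        chrom_end=end,
        name=name or f"{event.gene_id}|{event.chrom}:{var.start + 1}",
        score=0,
        strand=event.strand,
        thick_start=start,
        thick_end=end,
        item_rgb="0",
        block_count=len(blocks),
        block_sizes=tuple(b.length for b in blocks),
        block_starts=tuple(b.start - start for b in blocks),
    )
    rec.validate()
    return rec


def events_to_bed12(
    events: Sequence[ReconciledEvent | SpliceEvent], flank_nt: int = 27
) -> List[Bed12Record]:
    """One BED12 record per variable exon (MXE events emit two records)."""
    records = []
    for ev in events:
        sev = ev.event_level if isinstance(ev, ReconciledEvent) else ev
        records.append(build_bed12_blocks(sev, flank_nt))
        if sev.region2 is not None:
            records.append(
                build_bed12_blocks(
                    sev,
                    flank_nt,
                    region=sev.region2,
                    name=f"{sev.gene_id}|{sev.chrom}:{sev.region2.start + 1}|exon2",
                )
            )
    return records


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def extract_spliced_sequence(fasta: Mapping[str, object], record: Bed12Record) -> str:
    """Concatenate the record's blocks from the genome, strand-aware.

    Blocks are concatenated in genomic order and reverse-complemented for
    minus-strand records; output is uppercase with non-ACGT bases as N.
    ``fasta`` is any chrom -> sequence mapping (a pyfaidx ``Fasta`` or a
    plain dict of strings).
    """
    if record.chrom not in fasta:
        raise KeyError(f"chromosome {record.chrom!r} not in genome")
    chrom_seq = fasta[record.chrom]
    chrom_len = len(chrom_seq)
    parts = []
    for block in record.blocks_genomic():
        if block.start < 0 or block.end > chrom_len:
            raise ValueError(
                f"block [{block.start},{block.end}) outside {record.chrom} "
                f"(length {chrom_len})"
            )
        parts.append(str(chrom_seq[block.start : block.end]))
    seq = "".join(parts).upper()
    seq = "".join(b if b in "ACGT" else "N" for b in seq)
    if record.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def translate_three_frames(seq: str) -> Tuple[str, str, str]:
    """Translate the three forward frames (standard code, stops as '*').

    Frame f starts at offset f-1; the trailing partial codon is dropped.
    Sequences shorter than 3 nt yield empty peptides with a warning.
    """
    if len(seq) < 3:
        warnings.warn(f"sequence of length {len(seq)} < 3: empty translations")
        return ("", "", "")
    peptides = []
    for offset in range(3):
        sub = seq[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        peptides.append(str(Seq(sub).translate()) if sub else "")
    return tuple(peptides)


def candidates_from_records(
    records: Sequence[Bed12Record], fasta: Mapping[str, object]
) -> List[PeptideCandidate]:
    """Three-frame peptide candidates for each spliced BED12 record."""
    out = []
    for rec in records:
        nt = extract_spliced_sequence(fasta, rec)
        for frame, pep in enumerate(translate_three_frames(nt), start=1):
            out.append(
                PeptideCandidate(
                    event_key=(rec.chrom, rec.chrom_start + 1),
                    frame=frame,
                    peptide=pep,
                    contains_stop="*" in pep,
                )
            )
    return out


def drop_stop_peptides(
    candidates: Sequence[PeptideCandidate],
) -> List[PeptideCandidate]:
    """Remove whole peptides containing a stop codon, preserving order."""
    kept = [c for c in candidates if "*" not in c.peptide]
    if candidates and not kept:
        warnings.warn("all peptides contained stop codons")
    return kept


class MockBindingPredictor:
    """Deterministic hash-based stand-in for an MHC binding-rank predictor.

    Returns a percent rank in (0.5, 100] derived from the MD5 of
    (peptide, allele), so no 9-mer is a strong binder unless planted in
    ``strong`` (which maps (peptide, allele) or just peptide to a rank
    <= 0.5).
    """

    def __init__(self, strong: Optional[Mapping] = None):
        self.strong = dict(strong or {})

    def __call__(self, peptide: str, allele: str) -> float:
        if (peptide, allele) in self.strong:
            return float(self.strong[(peptide, allele)])
        if peptide in self.strong:
            return float(self.strong[peptide])
        h = hashlib.md5(f"{peptide}|{allele}".encode()).hexdigest()
        return 0.5 + (int(h[:12], 16) / 16**12) * 99.5


def rank_9mers(
    candidates: Sequence[PeptideCandidate],
    predictor: Callable[[str, str], float],
    alleles: Optional[Sequence[str]] = None,
    strong_rank: float = 0.5,
) -> List[PeptideCandidate]:
    """Score all 9-mer windows of each candidate against each allele.

    A candidate's per-allele rank is the minimum over its length-9 windows;
    it is a strong binder when the minimum over alleles is at most
    ``strong_rank`` (percent).  Peptides shorter than 9 aa are dropped with
    a warning.
    """
    alleles = list(alleles or DEFAULT_ALLELES)
    out = []
    for cand in candidates:
        if len(cand.peptide) < 9:
            warnings.warn(
                f"peptide of length {len(cand.peptide)} < 9 dropped "
                f"(event {cand.event_key})"
            )
            continue
        windows = [cand.peptide[i : i + 9] for i in range(len(cand.peptide) - 8)]
        ranks = {
            allele: min(predictor(w, allele) for w in windows) for allele in alleles
        }
        cand.allele_ranks = ranks
        cand.strong_binder = min(ranks.values()) <= strong_rank
        out.append(cand)
    return out
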