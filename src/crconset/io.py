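"""Readers and writers for the pipeline's external formats.

Covered dialects: per-gene DE result tables (TSV with ``baseMean``,
``log2FoldChange``, ``padj``), paired expression matrices with sample
metadata, junction-count ("event_level", rMATS-style) splice tables,
per-node ("node_level", Whippet-style) differential-splicing tables, BED12,
survival tables, cell-type score tables, and peptide FASTA.

Every reader converts coordinates to the internal 0-based half-open
convention at the boundary; every writer converts back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .events import Bed12Record, Interval, SpliceEvent, EVENT_TYPES


class TableFormatError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# DE result tables
# ---------------------------------------------------------------------------

#: column names of the DE-package result dialect -> internal names
_DE_COLUMNS = {"baseMean": "base_mean", "log2FoldChange": "lfc", "padj": "padj"}


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a per-gene DE result table.

    Returns a DataFrame indexed by ``gene_id`` with columns ``base_mean``,
    ``lfc`` and ``padj``.  Missing ``padj`` (``NA``) is preserved as NaN and
    treated as non-significant downstream, never as zero.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    first = df.columns[0]
    missing = [c for c in _DE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing DE columns {missing}")
    df = df.rename(columns={first: "gene_id", **_DE_COLUMNS})
    for col in ("base_mean", "lfc", "padj"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str) != "NA")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableFormatError(
                f"{path}: malformed numeric value {df[col].iloc[row]!r} "
                f"in column {col}, row {row + 2}"
            )
        df[col] = coerced
    dupes = df["gene_id"][df["gene_id"].duplicated()].unique()
    if len(dupes):
        raise TableFormatError(f"{path}: duplicate gene ids: {', '.join(dupes)}")
    if (df["base_mean"] < 0).any():
        raise TableFormatError(f"{path}: negative base_mean")
    return df.set_index("gene_id")[["base_mean", "lfc", "padj"]]


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DE table back in the result-table dialect (inverse of reader)."""
    out = table.reset_index()
    out.columns = ["gene_id", "baseMean", "log2FoldChange", "padj"]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Expression matrices with paired metadata
# ---------------------------------------------------------------------------


@dataclass
class PairedExpressionMatrix:
    """log2-scale expression (genes x samples) plus paired sample metadata.

    ``meta`` is indexed by sample id with columns ``patient_id``,
    ``tissue`` (tumor/normal) and ``cohort`` (early/late).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.values.columns) != set(self.meta.index):
            raise ValueError("expression columns and metadata samples disagree")
        for col in ("patient_id", "tissue", "cohort"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata missing column {col!r}")
        bad_tissue = set(self.meta["tissue"]) - {"tumor", "normal"}
        if bad_tissue:
            raise ValueError(f"unknown tissue labels: {bad_tissue}")
        counts = self.meta.groupby(["patient_id", "tissue"]).size()
        for patient, sub in self.meta.groupby("patient_id"):
            tissues = sorted(sub["tissue"])
            if tissues != ["normal", "tumor"]:
                raise ValueError(
                    f"patient {patient!r} lacks a complete tumor/normal pair"
                )
        del counts

    @property
    def patients(self) -> List[str]:
        return sorted(self.meta["patient_id"].unique())

    def sample_of(self, patient: str, tissue: str) -> str:
        sel = self.meta[
            (self.meta["patient_id"] == patient) & (self.meta["tissue"] == tissue)
        ]
        return sel.index[0]

    def subset_cohort(self, cohort: str) -> "PairedExpressionMatrix":
        meta = self.meta[self.meta["cohort"] == cohort]
        return PairedExpressionMatrix(self.values[meta.index], meta.copy())


def read_expression(path: str | Path, meta_path: str | Path) -> PairedExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    return PairedExpressionMatrix(values, meta)


def write_expression(
    expr: PairedExpressionMatrix, path: str | Path, meta_path: str | Path
) -> None:
    expr.values.to_csv(path, sep="\t")
    expr.meta.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# Junction-count (event_level) splice tables
# ---------------------------------------------------------------------------

_RMATS_COORDS = {
    "SE": (
        "exonStart_0base",
        "exonEnd",
        "upstreamES",
        "upstreamEE",
        "downstreamES",
        "downstreamEE",
    ),
    "A5SS": (
        "longExonStart_0base",
        "longExonEnd",
        "shortES",
        "shortEE",
        "flankingES",
        "flankingEE",
    ),
    "A3SS": (
        "longExonStart_0base",
        "longExonEnd",
        "shortES",
        "shortEE",
        "flankingES",
        "flankingEE",
    ),
    "MXE": (
        "1stExonStart_0base",
        "1stExonEnd",
        "2ndExonStart_0base",
        "2ndExonEnd",
        "upstreamES",
        "upstreamEE",
        "downstreamES",
        "downstreamEE",
    ),
    "RI": (
        "riExonStart_0base",
        "riExonEnd",
        "upstreamES",
        "upstreamEE",
        "downstreamES",
        "downstreamEE",
    ),
}

_RMATS_TAIL = (
    "IJC_SAMPLE_1",
    "SJC_SAMPLE_1",
    "IJC_SAMPLE_2",
    "SJC_SAMPLE_2",
    "IncFormLen",
    "SkipFormLen",
    "PValue",
    "FDR",
    "IncLevelDifference",
)


def _parse_counts(cell: str, where: str) -> tuple[int, ...]:
    try:
        return tuple(int(x) for x in str(cell).split(","))
    except ValueError as exc:
        raise TableFormatError(f"malformed count vector {cell!r} in {where}") from exc


def read_rmats_table(
    path: str | Path, event_type: str, sample_order: str = "tumor_normal"
) -> List[SpliceEvent]:
    """Read a junction-count differential-splicing table.

    ``sample_order`` says which group was SAMPLE_1 when the caller ran;
    the returned ``delta_psi`` is always tumor minus normal.  Coordinates in
    the file are 0-based starts / 1-based-inclusive-equivalent ends (i.e.
    half-open); they are stored unchanged as internal 0-based half-open.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    if sample_order not in ("tumor_normal", "normal_tumor"):
        raise ValueError(f"unknown sample order {sample_order!r}")
    df = pd.read_csv(path, sep="\t")
    needed = ("ID", "GeneID", "chr", "strand") + _RMATS_COORDS[event_type] + _RMATS_TAIL
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    events = []
    for _, row in df.iterrows():
        ijc1 = _parse_counts(row["IJC_SAMPLE_1"], f"{path} ID={row['ID']}")
        sjc1 = _parse_counts(row["SJC_SAMPLE_1"], f"{path} ID={row['ID']}")
        ijc2 = _parse_counts(row["IJC_SAMPLE_2"], f"{path} ID={row['ID']}")
        sjc2 = _parse_counts(row["SJC_SAMPLE_2"], f"{path} ID={row['ID']}")
        if len(ijc1) != len(sjc1) or len(ijc2) != len(sjc2):
            raise TableFormatError(
                f"{path} ID={row['ID']}: IJC/SJC replicate-count length mismatch"
            )
        c = _RMATS_COORDS[event_type]
        region = Interval(int(row[c[0]]), int(row[c[1]]))
        region2 = upstream = downstream = None
        if event_type == "MXE":
            region2 = Interval(int(row[c[2]]), int(row[c[3]]))
            upstream = Interval(int(row[c[4]]), int(row[c[5]]))
            downstream = Interval(int(row[c[6]]), int(row[c[7]]))
        elif event_type in ("SE", "RI"):
            upstream = Interval(int(row[c[2]]), int(row[c[3]]))
            downstream = Interval(int(row[c[4]]), int(row[c[5]]))
        else:  # A5SS/A3SS: one constitutive flanking exon
            flank = Interval(int(row[c[4]]), int(row[c[5]]))
            if flank.start >= region.end:
                downstream = flank
            else:
                upstream = flank
        delta = float(row["IncLevelDifference"])
        if sample_order == "tumor_normal":
            ijc_t, sjc_t, ijc_n, sjc_n = ijc1, sjc1, ijc2, sjc2
        else:
            ijc_t, sjc_t, ijc_n, sjc_n = ijc2, sjc2, ijc1, sjc1
            delta = -delta
        events.append(
            SpliceEvent(
                caller="event_level",
                event_type=event_type,
                chrom=str(row["chr"]),
                strand=str(row["strand"]),
                region=region,
                region2=region2,
                upstream_exon=upstream,
                downstream_exon=downstream,
                delta_psi=delta,
                significance=float(row["FDR"]),
                gene_id=str(row["GeneID"]),
                event_id=str(row["ID"]),
                ijc_tumor=ijc_t,
                sjc_tumor=sjc_t,
                ijc_normal=ijc_n,
                sjc_normal=sjc_n,
            )
        )
    return events


def write_rmats_table(
    events: Sequence[SpliceEvent],
    path: str | Path,
    event_type: str,
    sample_order: str = "tumor_normal",
) -> None:
    """Write events in the junction-count dialect (inverse of the reader)."""
    cols = ("ID", "GeneID", "geneSymbol", "chr", "strand") + _RMATS_COORDS[
        event_type
    ] + _RMATS_TAIL
    rows = []
    for ev in events:
        if ev.event_type != event_type:
            raise ValueError(f"event {ev.event_id} is {ev.event_type}, not {event_type}")
        c = {}
        names = _RMATS_COORDS[event_type]
        c[names[0]], c[names[1]] = ev.region.start, ev.region.end
        if event_type == "MXE":
            c[names[2]], c[names[3]] = ev.region2.start, ev.region2.end
            c[names[4]], c[names[5]] = ev.upstream_exon.start, ev.upstream_exon.end
            c[names[6]], c[names[7]] = ev.downstream_exon.start, ev.downstream_exon.end
        elif event_type in ("SE", "RI"):
            c[names[2]], c[names[3]] = ev.upstream_exon.start, ev.upstream_exon.end
            c[names[4]], c[names[5]] = ev.downstream_exon.start, ev.downstream_exon.end
        else:
            short = Interval(ev.region.start + 1, ev.region.end - 1)
            flank = ev.downstream_exon or ev.upstream_exon
            c[names[2]], c[names[3]] = short.start, short.end
            c[names[4]], c[names[5]] = flank.start, flank.end
        delta = ev.delta_psi if sample_order == "tumor_normal" else -ev.delta_psi
        ijc1, sjc1 = ev.ijc_tumor, ev.sjc_tumor
        ijc2, sjc2 = ev.ijc_normal, ev.sjc_normal
        if sample_order == "normal_tumor":
            ijc1, sjc1, ijc2, sjc2 = ijc2, sjc2, ijc1, sjc1
        rows.append(
            {
                "ID": ev.event_id,
                "GeneID": ev.gene_id,
                "geneSymbol": ev.gene_id,
                "chr": ev.chrom,
                "strand": ev.strand,
                **c,
                "IJC_SAMPLE_1": ",".join(map(str, ijc1)),
                "SJC_SAMPLE_1": ",".join(map(str, sjc1)),
                "IJC_SAMPLE_2": ",".join(map(str, ijc2)),
                "SJC_SAMPLE_2": ",".join(map(str, sjc2)),
                "IncFormLen": ev.region.length + 98,
                "SkipFormLen": 98,
                "PValue": ev.significance,
                "FDR": ev.significance,
                "IncLevelDifference": round(delta, 6),
            }
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_rmats_dir(
    path: str | Path, sample_order: str = "tumor_normal"
) -> List[SpliceEvent]:
    """Read every ``<TYPE>.MATS.JC.txt`` table in a caller output directory."""
    path = Path(path)
    events: List[SpliceEvent] = []
    for etype in EVENT_TYPES:
        f = path / f"{etype}.MATS.JC.txt"
        if f.exists():
            events.extend(read_rmats_table(f, etype, sample_order=sample_order))
    if not events:
        raise TableFormatError(f"{path}: no junction-count tables found")
    return events


# ---------------------------------------------------------------------------
# Node-level (Whippet-style) differential-splicing tables
# ---------------------------------------------------------------------------

_WHIPPET_COLUMNS = (
    "Gene",
    "Node",
    "Coord",
    "Strand",
    "Type",
    "Psi_A",
    "Psi_B",
    "DeltaPsi",
    "Probability",
)


def _parse_coord(coord: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive) into its parts."""
    try:
        chrom, span = coord.rsplit(":", 1)
        s, e = span.split("-")
        return chrom, int(s), int(e)
    except (ValueError, AttributeError) as exc:
        raise TableFormatError(f"unparseable Coord {coord!r}") from exc


def read_whippet_diff(
    path: str | Path, tumor_is_a: bool = True
) -> List[SpliceEvent]:
    """Read a node-level differential-splicing table.

    Coordinates are 1-based inclusive in the file and converted to internal
    0-based half-open.  ``DeltaPsi`` in the file is Psi_A - Psi_B;
    ``tumor_is_a`` says whether group A was the tumor group, so the returned
    ``delta_psi`` is always tumor minus normal.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _WHIPPET_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    events = []
    for _, row in df.iterrows():
        chrom, start1, end1 = _parse_coord(row["Coord"])
        prob = float(row["Probability"])
        if not 0 <= prob <= 1:
            raise TableFormatError(
                f"{path}: Probability {prob} outside [0, 1] for node {row['Node']}"
            )
        delta = float(row["DeltaPsi"])
        if not tumor_is_a:
            delta = -delta
        events.append(
            SpliceEvent(
                caller="node_level",
                event_type=str(row["Type"]),
                chrom=chrom,
                strand=str(row["Strand"]),
                region=Interval(start1 - 1, end1),
                delta_psi=delta,
                significance=prob,
                gene_id=str(row["Gene"]),
                event_id=str(row["Node"]),
            )
        )
    return events


def write_whippet_diff(
    events: Sequence[SpliceEvent], path: str | Path, tumor_is_a: bool = True
) -> None:
    """Write events in the node-level dialect (1-based inclusive Coord)."""
    rows = []
    for ev in events:
        delta = ev.delta_psi if tumor_is_a else -ev.delta_psi
        psi_b = 0.5 - delta / 2
        rows.append(
            {
                "Gene": ev.gene_id,
                "Node": ev.event_id,
                "Coord": f"{ev.chrom}:{ev.region.start + 1}-{ev.region.end}",
                "Strand": ev.strand,
                "Type": ev.event_type,
                "Psi_A": round(psi_b + delta, 6),
                "Psi_B": round(psi_b, 6),
                "DeltaPsi": round(delta, 6),
                "Probability": round(ev.significance, 6),
            }
        )
    pd.DataFrame(rows, columns=_WHIPPET_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------


def write_bed12(records: Iterable[Bed12Record], path: str | Path) -> None:
    """Write BED12; every record's block arithmetic is validated first."""
    records = list(records)
    for rec in records:
        rec.validate()
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        rec.chrom,
                        rec.chrom_start,
                        rec.chrom_end,
                        rec.name,
                        rec.score,
                        rec.strand,
                        rec.thick_start,
                        rec.thick_end,
                        rec.item_rgb,
                        rec.block_count,
                        ",".join(map(str, rec.block_sizes)),
                        ",".join(map(str, rec.block_starts)),
                    )
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> List[Bed12Record]:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 12:
                raise TableFormatError(f"{path}:{i}: expected 12 columns")
            rec = Bed12Record(
                chrom=parts[0],
                chrom_start=int(parts[1]),
                chrom_end=int(parts[2]),
                name=parts[3],
                score=int(parts[4]),
                strand=parts[5],
                thick_start=int(parts[6]),
                thick_end=int(parts[7]),
                item_rgb=parts[8],
                block_count=int(parts[9]),
                block_sizes=tuple(int(x) for x in parts[10].rstrip(",").split(",")),
                block_starts=tuple(int(x) for x in parts[11].rstrip(",").split(",")),
            )
            rec.validate()
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Survival, cell-score and gene-list tables
# ---------------------------------------------------------------------------


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival table: sample_id, time (days), event (0/1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    if (df["time"] < 0).any():
        raise TableFormatError(f"{path}: negative survival time")
    df["event"] = df["event"].astype(bool)
    return df[["time", "event"]]


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t")


def read_cell_scores(path: str | Path, meta_path: Optional[str | Path] = None):
    """Read a cell-type score table (types x samples), optionally with metadata."""
    scores = pd.read_csv(path, sep="\t", index_col=0)
    if (scores.to_numpy() < 0).any():
        raise TableFormatError(f"{path}: negative cell scores")
    if meta_path is None:
        return scores
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    return scores, meta


def read_cell_grouping(path: str | Path) -> dict:
    """Read a two-column cell type -> group (lymphoid/myeloid/other) TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: expected two columns")
    grouping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    bad = set(grouping.values()) - {"lymphoid", "myeloid", "other"}
    if bad:
        raise TableFormatError(f"{path}: unknown groups {bad}")
    return grouping


def read_gene_list(path: str | Path) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_peptide_fasta(
    peptides: Sequence[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    """Write (name, peptide) pairs as FASTA for a binding predictor."""
    with open(path, "w") as fh:
        for name, pep in peptides:
            fh.write(f">{name}\n")
            for i in range(0, len(pep), width):
                fh.write(pep[i : i + width] + "\n")


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
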