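"""Dual-caller differential-splicing reconciliation.

Each caller's events are filtered on its own significance conventions
(junction-count caller: FDR < 0.05, |dPSI| > 0.1, mean tumor coverage > 20
reads; node-level caller: |dPSI| > 0.1, probability > 0.7), coordinate
conventions are harmonized into a (chrom, 1-based coordinate) match key, and
only events significant in both callers are kept.  Cohort-unique events are
the set difference of the reconciled per-cohort sets on match keys.

Key harmonization: the junction-count caller reports 0-based starts, so one
is added to its variable-region start; the node-level caller's 1-based start
is used as is.  Alternative 3' splice-site events are the exception — the
two callers describe them from opposite ends, so their end coordinate is
matched instead.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from typing import Dict, Iterable, List, Sequence, Tuple

from .config import PipelineConfig
from .events import ReconciledEvent, SpliceEvent

logger = logging.getLogger(__name__)

MatchKey = Tuple[str, int]


def filter_rmats_events(
    events: Iterable[SpliceEvent], cfg: PipelineConfig | None = None
) -> List[SpliceEvent]:
    """Significant junction-count events: FDR, |dPSI| and coverage filters.

    Keeps events with FDR < 0.05, |dPSI| > 0.1 and mean tumor replicate
    coverage (inclusion + skipping junction counts) strictly above 20.
    Events without counts are dropped with a warning.
    """
    cfg = cfg or PipelineConfig()
    kept = []
    for ev in events:
        if ev.caller != "event_level":
            raise ValueError(f"expected event_level events, got {ev.caller}")
        cov = ev.mean_tumor_coverage
        if cov is None:
            warnings.warn(f"event {ev.event_id}: missing junction counts; dropped")
            continue
        if (
            ev.significance < cfg.rmats_fdr
            and abs(ev.delta_psi) > cfg.rmats_dpsi
            and cov > cfg.rmats_coverage
        ):
            kept.append(ev)
    return kept


def filter_whippet_events(
    events: Iterable[SpliceEvent], cfg: PipelineConfig | None = None
) -> List[SpliceEvent]:
    """Significant node-level events: |dPSI| > 0.1 and probability > 0.7."""
    cfg = cfg or PipelineConfig()
    for ev in events:
        if ev.caller != "node_level":
            raise ValueError(f"expected node_level events, got {ev.caller}")
    return [
        ev
        for ev in events
        if abs(ev.delta_psi) > cfg.whippet_dpsi
        and ev.significance > cfg.whippet_prob
    ]


def harmonize_key(event: SpliceEvent, use_end: bool = False) -> MatchKey:
    """Harmonized (chrom, 1-based coordinate) match key.

    Junction-count events: 0-based variable-region start plus one, except
    A3SS events which are keyed by the end coordinate.  Node-level events:
    the 1-based start (``use_end=True`` selects the end, for matching
    against an A3SS partner).  MXE events are keyed by the 5'-most
    alternative exon's start.
    """
    if event.caller == "event_level":
        if event.event_type == "A3SS":
            return (event.chrom, event.region.end)
        return (event.chrom, event.region.start + 1)
    if use_end:
        return (event.chrom, event.region.end)
    return (event.chrom, event.region.start + 1)


def _collapse_duplicates(
    events: Sequence[SpliceEvent], use_end: bool = False
) -> Dict[MatchKey, SpliceEvent]:
    """Keep one event per key: smallest FDR (event_level) / largest probability."""
    best: Dict[MatchKey, SpliceEvent] = {}
    for ev in events:
        key = harmonize_key(ev, use_end=use_end)
        cur = best.get(key)
        if cur is None:
            best[key] = ev
        elif ev.caller == "event_level":
            if ev.significance < cur.significance:
                best[key] = ev
        elif ev.significance > cur.significance:
            best[key] = ev
    if len(best) < len(list(events)):
        logger.info("collapsed %d duplicate keys", len(list(events)) - len(best))
    return best


def match_events(
    event_level_sig: Sequence[SpliceEvent],
    node_level_sig: Sequence[SpliceEvent],
    strict_sign: bool = False,
) -> List[ReconciledEvent]:
    """Intersect the two callers on harmonized match keys.

    One reconciled event per junction-count event whose key has at least one
    node-level event with the same key (multiple node matches collapse to
    the best one).  ``strict_sign`` additionally requires dPSI sign
    agreement.
    """
    ev_by_key = _collapse_duplicates(event_level_sig)
    node_start = _collapse_duplicates(node_level_sig, use_end=False)
    node_end = _collapse_duplicates(node_level_sig, use_end=True)
    out: List[ReconciledEvent] = []
    for key in sorted(ev_by_key):
        ev = ev_by_key[key]
        lookup = node_end if ev.event_type == "A3SS" else node_start
        node = lookup.get(key)
        if node is None:
            continue
        if strict_sign and ev.delta_psi * node.delta_psi < 0:
            continue
        if ev.event_type == "MXE":
            logger.info("MXE event %s keyed by its 5'-most exon start", ev.event_id)
        out.append(ReconciledEvent(match_key=key, event_level=ev, node_level=node))
    return out


def cohort_unique_events(
    early: Sequence[ReconciledEvent], late: Sequence[ReconciledEvent]
) -> List[ReconciledEvent]:
    """Early-cohort events whose match key is absent from the late set."""
    late_keys = {r.match_key for r in late}
    return [r for r in early if r.match_key not in late_keys]


def caller_concordance_rate(
    event_level_sig: Sequence[SpliceEvent],
    node_level_all: Sequence[SpliceEvent],
) -> Dict[str, float]:
    """Per-event-type fraction of significant junction-count events with a
    node-level key match.  Types with no events are omitted."""
    node_start = {harmonize_key(n) for n in node_level_all}
    node_end = {harmonize_key(n, use_end=True) for n in node_level_all}
    counts: Dict[str, list] = defaultdict(lambda: [0, 0])
    for ev in event_level_sig:
        key = harmonize_key(ev)
        pool = node_end if ev.event_type == "A3SS" else node_start
        counts[ev.event_type][0] += int(key in pool)
        counts[ev.event_type][1] += 1
    return {t: m / n for t, (m, n) in sorted(counts.items()) if n > 0}
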