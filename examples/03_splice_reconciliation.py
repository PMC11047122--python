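"""Reconcile two splicing callers and derive cohort-unique events.

Generates both caller dialects (junction-count tables with 0-based starts,
node-level tables with 1-based coordinates) for both cohorts, filters each
on its own significance convention, harmonizes coordinates into match keys,
intersects the callers, and subtracts the late-onset set.
"""

import tempfile

from crconset import io
from crconset.simulate import SimulationSpec, simulate_splice_tables
from crconset.splicing import (
    caller_concordance_rate,
    cohort_unique_events,
    filter_rmats_events,
    filter_whippet_events,
    match_events,
)

spec = SimulationSpec(seed=1)  # 82 early / 191 late / 49 shared planted
with tempfile.TemporaryDirectory() as tmp:
    paths, truth = simulate_splice_tables(spec, tmp)
    merged = {}
    for cohort in ("early", "late"):
        events = filter_rmats_events(io.read_rmats_dir(paths[cohort]["rmats_dir"]))
        nodes = filter_whippet_events(io.read_whippet_diff(paths[cohort]["whippet"]))
        merged[cohort] = match_events(events, nodes)
        print(f"{cohort}: {len(events)} junction-count significant, "
              f"{len(merged[cohort])} confirmed by the node-level caller")
    unique = cohort_unique_events(merged["early"], merged["late"])
    shared = {r.match_key for r in merged["early"]} & {
        r.match_key for r in merged["late"]}
    print(f"shared between cohorts: {len(shared)}")
    print(f"early-onset unique events: {len(unique)}")
    # 82 early-significant with 49 also significant late leaves 33 unique.

    all_nodes = io.read_whippet_diff(paths["early"]["whippet"])
    sig_events = filter_rmats_events(io.read_rmats_dir(paths["early"]["rmats_dir"]))
    for etype, rate in caller_concordance_rate(sig_events, all_nodes).items():
        print(f"concordance {etype}: {rate:.0%}")
    # The fraction of significant junction-count events whose harmonized key
    # has any node-level record at all (significant or not).
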