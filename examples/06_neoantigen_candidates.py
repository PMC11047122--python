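"""Build junction-spanning peptide candidates from tumor-enriched events.

Generates a toy genome with planted cassette events, builds three-block
BED12 records (27-nt exon flanks around each variable exon), extracts the
spliced strand-aware sequence, translates three frames, drops stop-containing
frames, and ranks all 9-mers with the deterministic mock binding predictor.
"""

import tempfile
from pathlib import Path

import pyfaidx

from crconset.io import write_bed12, write_peptide_fasta
from crconset.neoantigen import (
    MockBindingPredictor,
    candidates_from_records,
    drop_stop_peptides,
    events_to_bed12,
    rank_9mers,
    select_tumor_enriched,
)
from crconset.simulate import SimulationSpec, simulate_genome_with_events

spec = SimulationSpec(seed=1)
with tempfile.TemporaryDirectory() as tmp:
    fasta_path = Path(tmp) / "genome.fa"
    events, truth = simulate_genome_with_events(spec, fasta_path)
    enriched = select_tumor_enriched(events)
    print(f"{len(enriched)}/{len(events)} events are tumor-enriched (dPSI > 0)")

    records = events_to_bed12(enriched, flank_nt=spec.flank_nt)
    write_bed12(records, Path(tmp) / "events.bed12")
    genome = pyfaidx.Fasta(str(fasta_path))
    candidates = candidates_from_records(records, genome)
    kept = drop_stop_peptides(candidates)
    print(f"{len(candidates)} three-frame translations, "
          f"{len(kept)} free of stop codons")

    # plant one strong binder so the mock flags something
    strong_window = kept[0].peptide[:9] if kept else None
    predictor = MockBindingPredictor(strong={strong_window: 0.2})
    ranked = rank_9mers(kept, predictor)
    for cand in ranked:
        best = min(cand.allele_ranks.values())
        print(f"{cand.event_key[0]}:{cand.event_key[1]} frame {cand.frame} "
              f"len {len(cand.peptide)} best rank {best:.2f} "
              f"strong={cand.strong_binder}")
    write_peptide_fasta(
        [(f"{c.event_key[0]}:{c.event_key[1]}|f{c.frame}", c.peptide) for c in kept],
        Path(tmp) / "peptides.fa",
    )
    # peptides.fa is what an external MHC-binding predictor would consume;
    # a candidate is a strong binder at percent-rank <= 0.5 on any allele.
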