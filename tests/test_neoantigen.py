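"""Junction-peptide construction: BED12 blocks, extraction, translation, ranking."""

import numpy as np
import pytest

from crconset.events import Interval, SpliceEvent
from crconset.neoantigen import (
    MockBindingPredictor,
    PeptideCandidate,
    build_bed12_blocks,
    candidates_from_records,
    drop_stop_peptides,
    events_to_bed12,
    extract_spliced_sequence,
    rank_9mers,
    select_tumor_enriched,
    translate_three_frames,
)
from crconset.simulate import SimulationSpec, simulate_genome_with_events

# independent codon lookup used as a translation oracle
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR" "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG"
)
CODON = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}


def se_event(start=1000, end=1100, up=(700, 900), down=(1200, 1500), strand="+",
             dpsi=0.2):
    return SpliceEvent(
        caller="event_level", event_type="SE", chrom="chr1", strand=strand,
        region=Interval(start, end), delta_psi=dpsi, significance=0.01,
        gene_id="G", event_id="1",
        upstream_exon=Interval(*up), downstream_exon=Interval(*down),
        ijc_tumor=(30,), sjc_tumor=(10,), ijc_normal=(30,), sjc_normal=(10,),
    )


class TestSelectTumorEnriched:
    @pytest.mark.parametrize("dpsi,kept", [(0.2, True), (-0.2, False), (0.0, False)])
    def test_sign_rule(self, dpsi, kept):
        assert bool(select_tumor_enriched([se_event(dpsi=dpsi)])) is kept


class TestBed12Blocks:
    def test_three_block_worked_example(self):
        rec = build_bed12_blocks(se_event(), flank_nt=27)
        blocks = rec.blocks_genomic()
        assert [(b.start, b.end) for b in blocks] == [
            (873, 900), (1000, 1100), (1200, 1227)
        ]
        assert sum(rec.block_sizes) == 27 + 100 + 27 == 154

    def test_flank_zero_single_block(self):
        rec = build_bed12_blocks(se_event(), flank_nt=0)
        assert rec.block_count == 1
        assert (rec.chrom_start, rec.chrom_end) == (1000, 1100)

    def test_short_upstream_exon_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            rec = build_bed12_blocks(se_event(up=(890, 900)), flank_nt=27)
        assert rec.block_sizes[0] == 10

    def test_missing_flank_degrades_with_warning(self):
        e = se_event()
        e.upstream_exon = None
        with pytest.warns(UserWarning, match="upstream"):
            rec = build_bed12_blocks(e, flank_nt=27)
        assert rec.block_count == 2

    def test_mxe_emits_two_records(self):
        e = se_event()
        e.event_type = "MXE"
        e.region2 = Interval(1300, 1350)
        e.downstream_exon = Interval(1500, 1700)
        recs = events_to_bed12([e])
        assert len(recs) == 2


class TestExtraction:
    def test_plus_strand_concatenation(self):
        fasta = {"chr1": "ACGTTTGG"}
        rec = build_bed12_blocks(
            se_event(start=3, end=6, up=(0, 3), down=(6, 8)), flank_nt=3
        )
        # blocks [0,3)+[3,6)+[6,8) -> whole sequence
        assert extract_spliced_sequence(fasta, rec) == "ACGTTTGG"

    def test_two_block_plus_and_minus(self):
        from crconset.events import Bed12Record

        fasta = {"chr1": "ACGXXTTT"}
        rec = Bed12Record("chr1", 0, 8, "x", 0, "+", 0, 8, "0", 2, (3, 3), (0, 5))
        assert extract_spliced_sequence(fasta, rec) == "ACGTTT"
        rec_minus = Bed12Record("chr1", 0, 8, "x", 0, "-", 0, 8, "0", 2, (3, 3), (0, 5))
        # reverse complement of ACGTTT, built by hand: AAACGT
        assert extract_spliced_sequence(fasta, rec_minus) == "AAACGT"

    def test_non_acgt_passed_through_as_n(self):
        from crconset.events import Bed12Record

        fasta = {"chr1": "ACNTAG"}
        rec = Bed12Record("chr1", 0, 6, "x", 0, "+", 0, 6, "0", 1, (6,), (0,))
        assert extract_spliced_sequence(fasta, rec) == "ACNTAG"

    def test_out_of_bounds_block_rejected(self):
        from crconset.events import Bed12Record

        fasta = {"chr1": "ACGT"}
        rec = Bed12Record("chr1", 0, 8, "x", 0, "+", 0, 8, "0", 1, (8,), (0,))
        with pytest.raises(ValueError, match="outside"):
            extract_spliced_sequence(fasta, rec)

    def test_strand_symmetry_property(self, rng):
        """Extracting from the reverse-complemented genome with flipped strand
        and mirrored coordinates reproduces the original sequence."""
        from crconset.events import Bed12Record

        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(10):
            L = 60
            seq = "".join(rng.choice(list("ACGT"), size=L))
            s1, s2 = 5, 40
            rec = Bed12Record("c", s1, s2 + 10, "x", 0, "+", s1, s2 + 10, "0",
                              2, (8, 10), (0, s2 - s1))
            fwd = extract_spliced_sequence({"c": seq}, rec)
            rc_seq = seq.translate(comp)[::-1]
            # mirrored block coordinates on the reverse-complemented genome
            blocks = [(L - (s1 + 8), 8), (L - (s2 + 10), 10)]
            blocks.sort()
            start = blocks[0][0]
            end = blocks[-1][0] + blocks[-1][1]
            rec_rc = Bed12Record(
                "c", start, end, "x", 0, "-", start, end, "0", 2,
                (blocks[0][1], blocks[1][1]),
                (0, blocks[1][0] - start),
            )
            assert extract_spliced_sequence({"c": rc_seq}, rec_rc) == fwd


class TestTranslation:
    def test_codon_table(self):
        assert translate_three_frames("ATGGCC")[0] == "MA"

    def test_stop_rendered(self):
        assert translate_three_frames("ATGGCCTAA")[0] == "MA*"

    def test_frames_offset_and_partial_codon_dropped(self):
        f1, f2, f3 = translate_three_frames("ATGGCCA")
        assert (f1, f2, f3) == ("MA", "WP", "G")

    def test_too_short_warns(self):
        with pytest.warns(UserWarning):
            assert translate_three_frames("AT") == ("", "", "")

    def test_matches_codon_lookup_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 60))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            got = translate_three_frames(seq)
            for frame in (1, 2, 3):
                sub = seq[frame - 1:]
                expected = "".join(
                    CODON[sub[i : i + 3]]
                    for i in range(0, len(sub) - len(sub) % 3, 3)
                )
                assert got[frame - 1] == expected


class TestStopDropping:
    def test_mixed_list_filtered_in_order(self):
        cands = [
            PeptideCandidate(("c", 1), 1, "MA*", True),
            PeptideCandidate(("c", 1), 2, "MAW", False),
            PeptideCandidate(("c", 1), 3, "KLM", False),
        ]
        kept = drop_stop_peptides(cands)
        assert [c.peptide for c in kept] == ["MAW", "KLM"]

    def test_all_removed_warns(self):
        with pytest.warns(UserWarning):
            assert drop_stop_peptides([PeptideCandidate(("c", 1), 1, "M*", True)]) == []


class TestRanking:
    def test_window_counts(self):
        nine = PeptideCandidate(("c", 1), 1, "ACDEFGHIK", False)
        twenty = PeptideCandidate(("c", 1), 2, "ACDEFGHIKLMNPQRSTVWY", False)
        ranked = rank_9mers([nine, twenty], MockBindingPredictor())
        assert len(ranked) == 2
        # 20-mer has 12 windows; every window's rank >= its per-allele minimum
        assert all(0 < r <= 100 for r in ranked[1].allele_ranks.values())

    def test_short_peptide_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            ranked = rank_9mers([PeptideCandidate(("c", 1), 1, "SHORT", False)],
                                MockBindingPredictor())
        assert ranked == []

    def test_planted_strong_window_flagged(self):
        strong_window = "LLLLLLLLL"
        cands = [
            PeptideCandidate(("c", 1), 1, "AAAA" + strong_window + "AAAA", False),
            PeptideCandidate(("c", 2), 1, "ACDEFGHIKLMNP", False),
        ]
        predictor = MockBindingPredictor(strong={strong_window: 0.1})
        ranked = rank_9mers(cands, predictor)
        assert ranked[0].strong_binder is True
        assert ranked[1].strong_binder is False

    def test_number_of_windows_property(self, rng):
        for L in (9, 10, 17, 30):
            pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
            windows = [pep[i : i + 9] for i in range(len(pep) - 8)]
            assert len(windows) == max(0, L - 8)


class TestPipelineAgainstGeneratorOracle:
    def test_planted_peptides_match_both_strands(self, tmp_path):
        """Pipeline BED12+extraction+translation equals the generator's
        independent concatenation oracle for 100 fuzzed events."""
        import pyfaidx

        spec = SimulationSpec(seed=11, n_peptide_events=100, chrom_length=45_000)
        fasta_path = tmp_path / "genome.fa"
        events, truth = simulate_genome_with_events(spec, fasta_path)
        oracle = {
            (p["event_id"], p["frame"]): p["peptide"] for p in truth.peptides
        }
        strands = {p["event_id"]: p["strand"] for p in truth.peptides}
        assert {"+", "-"} <= set(strands.values())
        genome = pyfaidx.Fasta(str(fasta_path))
        for ev in events:
            rec = build_bed12_blocks(ev, flank_nt=spec.flank_nt)
            [cand1, cand2, cand3] = candidates_from_records([rec], genome)
            for cand in (cand1, cand2, cand3):
                assert cand.peptide == oracle[(ev.event_id, cand.frame)]

    def test_stop_frames_marked_dropped_in_truth(self, tmp_path):
        spec = SimulationSpec(seed=12, n_peptide_events=20)
        _, truth = simulate_genome_with_events(spec, tmp_path / "g.fa")
        for p in truth.peptides:
            assert p["dropped_for_stop"] == ("*" in p["peptide"])
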