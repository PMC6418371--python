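"""Splice-site creation detection, consensus scoring, canonical-site search."""

import io

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from paness.errors import ConfigurationError, ContextWindowError
from paness.paness_core import (
    ConsensusModel,
    PipelineConfig,
    SpliceSiteCandidate,
    consensus_similarity,
    enumerate_creations,
    enumerate_placements,
    nearest_canonical_site,
    run_paness,
    transcribed_strand_window,
)
from paness.synthetic_fixtures import brute_force_oracle
from paness.variant_filtering import FrequencySource
from paness.variant_io import GeneModel, GenomeSequence, VariantRecord


class TestTranscribedStrandWindow:
    def test_plus_strand_substitution(self):
        g = GenomeSequence({"c": "CAGGT"})
        assert transcribed_strand_window(g, "c", 3, 2, "+", alt="A") == "CAAGT"

    def test_minus_strand_is_reverse_complement(self):
        g = GenomeSequence({"c": "CAGGT"})
        plus = transcribed_strand_window(g, "c", 3, 2, "+", alt="A")
        minus = transcribed_strand_window(g, "c", 3, 2, "-", alt="A")
        assert minus == str(Seq(plus).reverse_complement())
        assert minus == "ACTTG"

    def test_window_off_chromosome_end_raises(self):
        g = GenomeSequence({"c": "CAGGT"})
        with pytest.raises(ContextWindowError):
            transcribed_strand_window(g, "c", 5, 2, "+")


# Hand enumeration over the 10-mer A A G A T T G C C A (positions 1..10),
# plus strand. A pair XY becomes GT via one SNV iff (X==G, Y->T) or
# (Y==T, X->G); it becomes AG iff (X==A, Y->G) or (Y==G, X->A); pairs that
# already read GT/AG at that placement are never novel.
HAND_SEQ = "AAGATTGCCA"
HAND_DONORS = {
    (4, "T"): [("donor", "variant_is_second_base", (3, 4))],
    (4, "G"): [("donor", "variant_is_first_base", (4, 5))],
    (5, "G"): [("donor", "variant_is_first_base", (5, 6)),
               ("acceptor", "variant_is_second_base", (4, 5))],
    (8, "T"): [("donor", "variant_is_second_base", (7, 8))],
}
HAND_ACCEPTORS = {
    (2, "G"): [("acceptor", "variant_is_second_base", (1, 2))],
    (6, "A"): [("acceptor", "variant_is_first_base", (6, 7))],
}


class TestEnumeratePlacements:
    def test_hand_enumerated_ten_mer(self):
        g = GenomeSequence({"c": HAND_SEQ})
        expected = {}
        for table in (HAND_DONORS, HAND_ACCEPTORS):
            for key, gains in table.items():
                expected.setdefault(key, []).extend(gains)
        for pos in range(1, 11):
            ref = HAND_SEQ[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = sorted(
                    (st_, reg, span)
                    for st_, reg, span, _ in enumerate_placements(g, "c", pos, ref, alt, "+")
                )
                assert got == sorted(expected.get((pos, alt), [])), (pos, ref, alt)

    def test_hand_enumeration_agrees_with_oracle(self):
        g = GenomeSequence({"c": HAND_SEQ})
        for pos in range(1, 11):
            ref = HAND_SEQ[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                for strand in "+-":
                    fast = sorted(
                        (s, r, sp)
                        for s, r, sp, _ in enumerate_placements(g, "c", pos, ref, alt, strand)
                    )
                    assert fast == brute_force_oracle(g, ("c", pos, ref, alt), strand)

    def test_novelty_is_absolute(self):
        # ref pair GA: A>T creates GT (novel); but where the ref pair is
        # already GT, re-creating it is impossible by definition (an SNV must
        # change a base) and near-matches are suppressed by the novelty rule
        g = GenomeSequence({"c": "AAGAAA"})
        gains = enumerate_placements(g, "c", 4, "A", "T", "+")
        assert [(s, r, sp) for s, r, sp, _ in gains] == [
            ("donor", "variant_is_second_base", (3, 4))
        ]

    def test_n_base_yields_nothing(self):
        g = GenomeSequence({"c": "AANGAA"})
        assert enumerate_placements(g, "c", 4, "G", "T", "+") == []

    def test_reference_mismatch_skipped(self):
        g = GenomeSequence({"c": "AAGAAA"})
        assert enumerate_placements(g, "c", 4, "C", "T", "+") == []

    def test_no_creation_for_inert_substitution(self):
        g = GenomeSequence({"c": "AATAGA"})  # neighbors A_G around pos 3
        assert enumerate_placements(g, "c", 3, "T", "C", "+") == []

    @settings(max_examples=100, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=4, max_size=30),
        pos_frac=st.floats(0, 1),
        alt=st.sampled_from("ACGT"),
        strand=st.sampled_from("+-"),
    )
    def test_matches_oracle_on_random_sequences(self, seq, pos_frac, alt, strand):
        g = GenomeSequence({"c": seq})
        pos = 1 + int(pos_frac * (len(seq) - 1))
        ref = seq[pos - 1]
        if ref == alt:
            return
        fast = sorted(
            (s, r, sp) for s, r, sp, _ in enumerate_placements(g, "c", pos, ref, alt, strand)
        )
        assert fast == brute_force_oracle(g, ("c", pos, ref, alt), strand)


class TestEnumerateCreations:
    def test_exon_final_g_to_a_creates_acceptor(self, worked_example):
        wx = worked_example
        v = VariantRecord(wx.model.chrom, wx.variant_pos, "G", "A")
        cands = enumerate_creations(v, wx.genome, wx.model)
        assert len(cands) == 1
        c = cands[0]
        assert c.site_type == "acceptor"
        assert c.register == "variant_is_first_base"
        assert c.dinucleotide_span == (wx.variant_pos, wx.variant_pos + 1)
        assert c.ref_dinucleotide == "GG"
        # the novel AG sits at consensus positions -2/-1 of the alt context
        assert c.alt_context[-3:-1] == "AG"

    def test_variant_outside_margin_not_evaluated(self, worked_example):
        wx = worked_example
        lo, _ = wx.model.span
        v = VariantRecord(wx.model.chrom, lo - 150, "A", "G")
        assert enumerate_creations(v, wx.genome, wx.model, margin=100) == []

    def test_candidate_invariant_rejects_non_novel(self):
        v = VariantRecord("c", 5, "G", "A")
        with pytest.raises(ValueError):
            SpliceSiteCandidate(
                variant=v, gene_id="g", transcript_id="t", strand="+",
                site_type="acceptor", register="variant_is_first_base",
                dinucleotide_span=(5, 6), alt_context="N" * 17,
                ref_dinucleotide="AG",
            )


def _toy_model(**overrides):
    kwargs = dict(
        gene_id="g", transcript_id="t", chrom="c", strand="+",
        exons=[(11, 20), (41, 50), (71, 80)],
    )
    kwargs.update(overrides)
    return GeneModel(**kwargs)


def _donor_candidate(span, strand="+"):
    v = VariantRecord("c", span[0], "A", "G")
    return SpliceSiteCandidate(
        variant=v, gene_id="g", transcript_id="t", strand=strand,
        site_type="donor", register="variant_is_first_base",
        dinucleotide_span=span, alt_context="N" * 9, ref_dinucleotide="AA",
    )


class TestNearestCanonical:
    GENOME = GenomeSequence({"c": "A" * 120})

    def test_distance_zero_at_canonical_placement(self):
        # donor candidate exactly at the exon-1 donor (intron bases 21-22)
        model = _toy_model()
        span, dist, ctx = nearest_canonical_site(_donor_candidate((21, 22)), model, self.GENOME)
        assert span == (21, 22)
        assert dist == 0
        assert len(ctx) == 9

    def test_single_exon_model_has_no_canonical_sites(self):
        model = _toy_model(exons=[(11, 80)])
        assert nearest_canonical_site(_donor_candidate((30, 31)), model, self.GENOME) == (
            None, None, None,
        )

    def test_equidistant_tie_breaks_upstream(self):
        # donors at 21 and 51; candidate first base 36 is 15 bp from both
        model = _toy_model()
        span, dist, _ = nearest_canonical_site(_donor_candidate((36, 37)), model, self.GENOME)
        assert span == (21, 22)
        assert dist == -15

    def test_minus_strand_distance_sign_follows_transcription(self):
        model = _toy_model(strand="-")
        # minus-strand donors sit at intron bases genomically below each exon
        # start; exon order is reversed, so the 5'-most donor is at pos 70
        cand = _donor_candidate((59, 60), strand="-")
        span, dist, _ = nearest_canonical_site(cand, model, self.GENOME)
        assert span == (69, 70)
        assert dist == -10


class TestConsensusSimilarity:
    def test_full_consensus_scores_one(self):
        assert consensus_similarity("CAGGTAAGT", "donor", ConsensusModel()) == pytest.approx(1.0)

    def test_all_t_donor_context_scores_t_positions_only(self):
        # T matches only the essential T (weight 0.25) and the final T
        # (extended weight 0.5/7)
        score = consensus_similarity("T" * 9, "donor", ConsensusModel())
        assert score == pytest.approx(0.25 + 0.5 / 7)

    def test_acceptor_full_consensus(self):
        assert consensus_similarity("T" * 12 + "CTAGG", "acceptor", ConsensusModel()) == (
            pytest.approx(1.0)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            consensus_similarity("GT", "donor", ConsensusModel())

    @settings(max_examples=100, derandomize=True)
    @given(ctx=st.text(alphabet="ACGTN", min_size=9, max_size=9))
    def test_score_bounded(self, ctx):
        assert 0.0 <= consensus_similarity(ctx, "donor", ConsensusModel()) <= 1.0

    def test_invariant_under_zero_weight_positions(self):
        weights = [0.0, 0.0, 0.0, 0.25, 0.25, 0.125, 0.125, 0.125, 0.125]
        model = ConsensusModel(donor_weights=weights)
        a = consensus_similarity("CAGGTAAGT", "donor", model)
        b = consensus_similarity("TTTGTAAGT", "donor", model)
        assert a == pytest.approx(b)

    def test_essential_positions_must_dominate(self):
        with pytest.raises(ConfigurationError):
            ConsensusModel(donor_weights=[0.3, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.05, 0.05])


EMPTY_VCF = """##fileformat=VCFv4.2
##contig=<ID=c,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


class TestRunPaness:
    def test_worked_example_yields_single_acceptor_row(self, worked_example):
        wx = worked_example
        rows, summary = run_paness(
            io.StringIO(wx.vcf_text), wx.genome, [wx.model],
            PipelineConfig(frequency=FrequencySource(mode="info_field", info_key="AF")),
        )
        assert summary["candidates"] == 1
        (row,) = rows
        assert row.site_type == "acceptor"
        assert (row.span_start, row.span_end) == (wx.variant_pos, wx.variant_pos + 1)
        assert row.maf == pytest.approx(8.1e-06, rel=1e-4)
        assert 0.0 <= row.consensus_score <= 1.0

    def test_empty_vcf_gives_empty_report_with_zero_counts(self, worked_example):
        wx = worked_example
        rows, summary = run_paness(io.StringIO(EMPTY_VCF), wx.genome, [wx.model])
        assert rows == []
        assert summary["input_records"] == 0
        assert summary["candidates"] == 0

    def test_variant_overlapping_no_transcript_yields_no_rows(self, worked_example):
        wx = worked_example
        vcf = (
            "##fileformat=VCFv4.2\n"
            f"##contig=<ID={wx.model.chrom},length={wx.genome.length(wx.model.chrom)}>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            f"{wx.model.chrom}\t2\t.\t{wx.genome.base(wx.model.chrom, 2)}\tT\t.\t.\t.\n"
        )
        rows, _ = run_paness(io.StringIO(vcf), wx.genome, [wx.model])
        assert rows == []

    def test_genome_wide_mode_reports_null_gene_fields(self, worked_example):
        wx = worked_example
        rows, _ = run_paness(
            io.StringIO(wx.vcf_text), wx.genome, [],
            PipelineConfig(genome_wide=True),
        )
        assert rows  # the acceptor creation is visible without transcript context
        assert all(r.gene_id == "" and r.transcript_id == "" for r in rows)
        plus = [r for r in rows if r.strand == "+"]
        assert any(r.site_type == "acceptor" for r in plus)
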