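"""VCF/GTF/TSV readers, report serialization, and domain-type invariants."""

import io

import pytest

from paness.errors import ContextWindowError, GeneModelError, VcfParseError
from paness.variant_io import (
    CandidateReportRow,
    GeneModel,
    GenomeSequence,
    Genotype,
    VariantRecord,
    VcfReadStats,
    read_candidates,
    read_gene_models,
    read_vcf,
    reverse_complement,
    write_candidates,
    write_gene_models_gtf,
    write_gene_models_tsv,
    write_vcf_text,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=16,length=90000000>
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tchild\tmom\tdad
"""


def _vcf(*rows):
    return io.StringIO(VCF_HEADER + "".join(r + "\n" for r in rows))


class TestReadVcf:
    def test_trio_genotypes_normalized(self):
        # homozygous proband, heterozygous carrier parents
        recs = read_vcf(_vcf("16\t28905928\t.\tG\tA\t.\tPASS\t.\tGT\t1/1\t0/1\t0/1"))
        assert len(recs) == 1
        v = recs[0]
        assert (v.chrom, v.pos, v.ref_allele, v.alt_allele) == ("16", 28905928, "G", "A")
        assert v.sample_genotypes == {
            "child": Genotype.HOM_ALT,
            "mom": Genotype.HET,
            "dad": Genotype.HET,
        }

    def test_non_snv_alleles_dropped_and_counted(self):
        stats = VcfReadStats()
        recs = read_vcf(
            _vcf(
                "16\t100\t.\tG\tGA\t.\t.\t.\tGT\t0/1\t0/0\t0/0",
                "16\t200\t.\tGC\tAT\t.\t.\t.\tGT\t0/1\t0/0\t0/0",
                "16\t300\t.\tG\tC\t.\t.\t.\tGT\t0/1\t0/0\t0/0",
            ),
            stats=stats,
        )
        assert [r.pos for r in recs] == [300]
        assert stats.dropped_non_snv == 2
        assert stats.input_records == 3

    def test_multiallelic_split_with_allele_matched_af(self):
        recs = read_vcf(_vcf("16\t100\t.\tG\tA,T\t.\t.\tAF=0.25,0.5\tGT\t1/2\t0/1\t0/2"))
        assert [(r.alt_allele, float(r.info["AF"])) for r in recs] == [("A", 0.25), ("T", 0.5)]
        a, t = recs
        # 1/2 proband carries one copy of each alt
        assert a.sample_genotypes["child"] == Genotype.HET
        assert t.sample_genotypes["child"] == Genotype.HET
        assert t.sample_genotypes["mom"] == Genotype.HOM_REF

    def test_missing_genotype(self):
        recs = read_vcf(_vcf("16\t100\t.\tG\tA\t.\t.\t.\tGT\t./.\t0/1\t0/1"))
        assert recs[0].sample_genotypes["child"] == Genotype.MISSING

    def test_malformed_header_raises(self):
        with pytest.raises(VcfParseError):
            read_vcf(io.StringIO("not a vcf\n"))

    def test_unknown_sample_requested(self):
        with pytest.raises(VcfParseError, match="nobody"):
            read_vcf(_vcf("16\t100\t.\tG\tA\t.\t.\t.\tGT\t0/1\t0/1\t0/1"),
                     sample_ids=["nobody"])

    def test_roundtrip_preserves_identity_and_genotypes(self):
        rows = [
            "16\t100\t.\tG\tA\t.\t.\tAF=0.001\tGT\t1/1\t0/1\t0/1",
            "16\t200\t.\tC\tT\t.\t.\t.\tGT\t0/1\t0/0\t./.",
        ]
        first = read_vcf(_vcf(*rows))
        text = write_vcf_text(first, ["child", "mom", "dad"])
        second = read_vcf(io.StringIO(text))
        assert [(v.key, v.sample_genotypes) for v in first] == [
            (v.key, v.sample_genotypes) for v in second
        ]


class TestVariantRecordInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="1", pos=0, ref_allele="A", alt_allele="C"),
            dict(chrom="1", pos=5, ref_allele="A", alt_allele="A"),
            dict(chrom="1", pos=5, ref_allele="AT", alt_allele="A"),
            dict(chrom="1", pos=5, ref_allele="A", alt_allele="N"),
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VariantRecord(**kwargs)

    def test_fixture_vcf_yields_only_valid_snvs(self, fixture_universe):
        _, _, vcf_text, _ = fixture_universe
        for v in read_vcf(io.StringIO(vcf_text)):
            assert v.ref_allele != v.alt_allele
            assert len(v.ref_allele) == len(v.alt_allele) == 1
            assert v.pos >= 1


class TestGenomeSequence:
    def test_fetch_is_half_open_and_bounds_checked(self):
        g = GenomeSequence({"c": "ACGTACGT"})
        assert g.fetch("c", 0, 4) == "ACGT"
        assert g.base("c", 5) == "A"
        with pytest.raises(ContextWindowError):
            g.fetch("c", -1, 4)
        with pytest.raises(ContextWindowError):
            g.fetch("c", 0, 9)
        with pytest.raises(ContextWindowError):
            g.fetch("missing", 0, 1)

    def test_fasta_roundtrip(self, tmp_path):
        g = GenomeSequence({"chrA": "ACGT" * 30, "chrB": "GGCC" * 10})
        path = tmp_path / "g.fa"
        g.to_fasta(path)
        g2 = GenomeSequence.from_fasta(path)
        assert g2.chrom_names == g.chrom_names
        assert all(g2.sequence(c) == g.sequence(c) for c in g.chrom_names)

    def test_reverse_complement(self):
        assert reverse_complement("CAAGT") == "ACTTG"
        assert reverse_complement("ACGTN") == "NACGT"


class TestGeneModels:
    def test_minimal_tsv_dialect(self):
        models = read_gene_models(io.StringIO("gene1\ttx1\tchr1\t+\t101-200,301-400\tCDS:121-380\n"))
        (m,) = models
        assert m.exons == [(101, 200), (301, 400)]
        assert (m.cds_start, m.cds_end) == (121, 380)

    def test_strand_aware_exon_numbering_from_gtf(self):
        gtf = (
            'chr1\tx\texon\t101\t200\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t301\t400\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
        )
        (m,) = read_gene_models(io.StringIO(gtf))
        assert m.strand == "-"
        assert m.exon(1) == (301, 400)  # 5'-most in transcription order
        assert m.exon(2) == (101, 200)

    def test_overlapping_exons_reject_model_but_keep_others(self):
        gtf = (
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "bad";\n'
            'chr1\tx\texon\t150\t250\t.\t+\t.\tgene_id "g"; transcript_id "bad";\n'
            'chr1\tx\texon\t501\t600\t.\t+\t.\tgene_id "g"; transcript_id "ok";\n'
            'chr1\tx\texon\t701\t800\t.\t+\t.\tgene_id "g"; transcript_id "ok";\n'
        )
        models = read_gene_models(io.StringIO(gtf))
        assert [m.transcript_id for m in models] == ["ok"]

    def test_no_parseable_transcript_raises(self):
        with pytest.raises(GeneModelError):
            read_gene_models(io.StringIO("gene1\ttx1\tchr1\t+\t200-100\n"))

    def test_tsv_and_gtf_writers_roundtrip(self, fixture_universe):
        _, models, _, _ = fixture_universe
        def key(m):
            return (m.transcript_id, m.chrom, m.strand, tuple(m.exons), m.cds_start, m.cds_end)
        via_tsv = read_gene_models(io.StringIO(write_gene_models_tsv(models)))
        via_gtf = read_gene_models(io.StringIO(write_gene_models_gtf(models)))
        expected = sorted(key(m) for m in models)
        assert sorted(key(m) for m in via_tsv) == expected
        assert sorted(key(m) for m in via_gtf) == expected

    def test_cds_outside_exons_rejected(self):
        m = GeneModel("g", "t", "c", "+", [(10, 20), (40, 50)], cds_start=25, cds_end=45)
        with pytest.raises(GeneModelError):
            m.validate()


class TestCandidateReport:
    def _row(self, **overrides):
        base = dict(
            chrom="chr1", pos=50, ref="G", alt="A", maf=1e-4, gene_id="g",
            transcript_id="t", site_type="acceptor", strand="+",
            register="variant_is_first_base", span_start=50, span_end=51,
            alt_context="X" * 17, canonical_context="Y" * 17,
            consensus_score=0.5, dist_to_canonical=-10,
        )
        base.update(overrides)
        return CandidateReportRow(**base)

    def test_empty_report_is_header_only(self):
        buf = io.StringIO()
        write_candidates([], buf)
        assert buf.getvalue().count("\n") == 1
        assert buf.getvalue().startswith("chrom\tpos\tref")

    def test_register_sort_contract(self):
        r1 = self._row(register="variant_is_second_base")
        r2 = self._row(register="variant_is_first_base")
        buf = io.StringIO()
        write_candidates([r1, r2], buf)
        lines = buf.getvalue().splitlines()[1:]
        assert "variant_is_first_base" in lines[0]
        assert "variant_is_second_base" in lines[1]

    def test_roundtrip(self):
        rows = [self._row(), self._row(pos=60, span_start=59, span_end=60,
                                       maf=None, dist_to_canonical=None)]
        buf = io.StringIO()
        write_candidates(rows, buf)
        assert read_candidates(io.StringIO(buf.getvalue())) == sorted(
            rows, key=lambda r: r.sort_key
        )
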