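"""Deterministic synthetic genomes, gene models, trio VCFs and planted
variants with ground truth, so the whole pipeline is testable offline.

The generators are first-class code, not test scaffolding: `make-fixtures` on
the command line writes the same files the tests consume. All outputs are
byte-identical for a fixed seed, and every planted variant is verified at
plant time against :func:`brute_force_oracle`, a deliberately naive
implementation kept separate from the optimized placement logic in
``paness_core``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np

from .errors import FixtureError
from .variant_io import (
    GeneModel,
    GenomeSequence,
    Genotype,
    VariantRecord,
    reverse_complement,
)

TRIO_SAMPLES = ("proband", "mother", "father")

_STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------

def generate_genome(
    seed: int, length: int, gc: float = 0.5, chrom: str = "chr1"
) -> GenomeSequence:
    """Random genome with the requested GC content, reproducible per seed."""
    if length < 1000:
        raise FixtureError("genome length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise FixtureError("gc must be in (0,1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list("ACGT")), size=length, p=probs)
    return GenomeSequence({chrom: "".join(bases)})


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) random non-stop codons + a random stop codon."""
    middle = []
    while len(middle) < n_codons - 2:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if codon in _STOP_CODONS:
            continue
        middle.append(codon)
    stop = _STOP_CODONS[int(rng.integers(0, 3))]
    return "ATG" + "".join(middle) + stop


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _build_transcript_layout(
    rng: np.random.Generator,
) -> tuple[list[int], list[int], int, int]:
    """(exon lengths, intron lengths, utr5, utr3) in transcription order."""
    n_exons = int(rng.integers(2, 9))
    exon_lengths = [int(rng.integers(40, 200)) for _ in range(n_exons)]
    intron_lengths = [int(rng.integers(60, 150)) for _ in range(n_exons - 1)]
    total = sum(exon_lengths)
    utr5 = int(rng.integers(5, 30))
    coding = total - utr5 - 5
    coding -= coding % 3
    if coding < 9:
        raise FixtureError("transcript too short for a CDS")
    utr3 = total - utr5 - coding
    return exon_lengths, intron_lengths, utr5, utr3


def generate_gene_models(
    genome: GenomeSequence, n_transcripts: int, seed: int
) -> list[GeneModel]:
    """Write valid transcripts (mixed strands, 2-8 exons, ATG..stop CDS,
    canonical GT/AG at every junction) into the genome and return the models.

    The genome is mutated in place: exon/intron sequences replace the random
    background at the chosen placements.
    """
    rng = np.random.default_rng(seed)
    models = []
    for chrom in genome.chrom_names:
        cursor = int(rng.integers(150, 400))
        for i in range(n_transcripts):
            for _attempt in range(20):
                try:
                    exon_lengths, intron_lengths, utr5, utr3 = _build_transcript_layout(rng)
                except FixtureError:
                    continue
                break
            else:
                raise FixtureError("could not draw a usable transcript layout")
            coding = sum(exon_lengths) - utr5 - utr3
            mrna = _random_seq(rng, utr5) + _random_coding(rng, coding // 3) + _random_seq(rng, utr3)
            strand = "+" if rng.random() < 0.5 else "-"

            piece, offsets = _assemble_piece(rng, mrna, exon_lengths, intron_lengths)
            start0 = cursor
            if start0 + len(piece) + 200 > genome.length(chrom):
                raise FixtureError(
                    f"genome too short: transcript {i + 1} needs {len(piece)} bp at {start0}"
                )
            written = piece if strand == "+" else reverse_complement(piece)
            genome._overwrite(chrom, start0, written)

            exons, cds_start, cds_end = _genomic_layout(
                start0, len(piece), strand, exon_lengths, offsets, utr5, coding
            )
            model = GeneModel(
                gene_id=f"gene{len(models) + 1}",
                transcript_id=f"tx{len(models) + 1}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
            model.validate()
            models.append(model)
            cursor = start0 + len(piece) + int(rng.integers(150, 400))
    return models


def _assemble_piece(rng, mrna, exon_lengths, intron_lengths):
    """Concatenate exon chunks of the mRNA with GT..AG introns; returns the
    transcription-order genomic piece and each exon's offset within it."""
    piece_parts, offsets = [], []
    pos = 0
    m = 0
    for idx, elen in enumerate(exon_lengths):
        offsets.append(pos)
        piece_parts.append(mrna[m:m + elen])
        m += elen
        pos += elen
        if idx < len(intron_lengths):
            ilen = intron_lengths[idx]
            piece_parts.append("GT" + _random_seq(rng, ilen - 4) + "AG")
            pos += ilen
    return "".join(piece_parts), offsets


def _genomic_layout(start0, piece_len, strand, exon_lengths, offsets, utr5, coding):
    """Genomic exon intervals (1-based closed, ascending) and CDS bounds."""
    def to_genomic(piece_off: int) -> int:
        if strand == "+":
            return start0 + piece_off + 1
        return start0 + piece_len - piece_off  # 1-based

    exons = []
    for off, elen in zip(offsets, exon_lengths):
        a, b = to_genomic(off), to_genomic(off + elen - 1)
        exons.append((min(a, b), max(a, b)))
    exons.sort()

    def mrna_to_piece(m: int) -> int:
        cum = 0
        for off, elen in zip(offsets, exon_lengths):
            if m < cum + elen:
                return off + (m - cum)
            cum += elen
        raise FixtureError("mRNA offset outside exons")

    g1 = to_genomic(mrna_to_piece(utr5))
    g2 = to_genomic(mrna_to_piece(utr5 + coding - 1))
    return exons, min(g1, g2), max(g1, g2)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_oracle(
    genome: GenomeSequence,
    variant: Union[VariantRecord, tuple[str, int, str, str]],
    strand: str,
) -> list[tuple[str, str, tuple[int, int]]]:
    """Naive reference check: build the full alternate chromosome string and
    report GT/AG dinucleotides, read on the given strand, that overlap the
    variant position and are absent at the same placement in the reference.

    Returns sorted (site_type, register, 1-based genomic span) tuples. Kept
    intentionally simple and independent of ``paness_core``.
    """
    if isinstance(variant, VariantRecord):
        chrom, pos, ref, alt = variant.chrom, variant.pos, variant.ref_allele, variant.alt_allele
    else:
        chrom, pos, ref, alt = variant
    ref_seq = genome.sequence(chrom)
    if ref_seq[pos - 1] != ref.upper():
        return []
    alt_seq = ref_seq[:pos - 1] + alt.upper() + ref_seq[pos:]

    gains = []
    for a in (pos - 1, pos):  # 1-based start of the two pairs containing pos
        if a < 1 or a + 1 > len(ref_seq):
            continue
        ref_pair_plus = ref_seq[a - 1:a + 1]
        alt_pair_plus = alt_seq[a - 1:a + 1]
        if strand == "+":
            ref_pair, alt_pair = ref_pair_plus, alt_pair_plus
            variant_is_first = pos == a
        else:
            ref_pair = reverse_complement(ref_pair_plus)
            alt_pair = reverse_complement(alt_pair_plus)
            variant_is_first = pos == a + 1
        if "N" in ref_pair or "N" in alt_pair:
            continue
        for site_type, target in (("donor", "GT"), ("acceptor", "AG")):
            if alt_pair == target and ref_pair != target:
                register = "variant_is_first_base" if variant_is_first else "variant_is_second_base"
                gains.append((site_type, register, (a, a + 1)))
    return sorted(gains)


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Ground truth for one planted variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    af: Optional[float]
    inheritance: str  # autosomal_recessive | de_novo | other
    kind: str  # creation | null | common_creation
    expected: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    # (site_type, register, span_start, span_end, transcript_id)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TruthTable:
    records: list[TruthRecord]
    seed: int

    def by_kind(self, kind: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == kind]

    def to_tsv(self) -> str:
        lines = [f"# paness_fixture_seed={self.seed}",
                 "chrom\tpos\tref\talt\taf\tinheritance\tkind\texpected"]
        for r in self.records:
            exp = ";".join(
                f"{t}|{reg}|{a}|{b}|{tid}" for t, reg, a, b, tid in r.expected
            )
            af = "" if r.af is None else repr(r.af)
            lines.append(
                f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{af}\t{r.inheritance}\t{r.kind}\t{exp}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "TruthTable":
        seed = 0
        records = []
        for line in text.splitlines():
            if line.startswith("# paness_fixture_seed="):
                seed = int(line.split("=", 1)[1])
                continue
            if not line.strip() or line.startswith("chrom\t") or line.startswith("#"):
                continue
            f = line.split("\t")
            expected = []
            if len(f) > 7 and f[7]:
                for part in f[7].split(";"):
                    t, reg, a, b, tid = part.split("|")
                    expected.append((t, reg, int(a), int(b), tid))
            records.append(
                TruthRecord(
                    chrom=f[0], pos=int(f[1]), ref=f[2], alt=f[3],
                    af=float(f[4]) if f[4] else None,
                    inheritance=f[5], kind=f[6], expected=expected,
                )
            )
        return cls(records, seed)


_GT = {
    "autosomal_recessive": ("1/1", "0/1", "0/1"),
    "de_novo": ("0/1", "0/0", "0/0"),
    "other": ("0/1", "0/1", "0/0"),
}


def _vcf_text(genome: GenomeSequence, records: list[TruthRecord], seed: int) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##paness_fixture_seed={seed}",
    ]
    for chrom in genome.chrom_names:
        lines.append(f"##contig=<ID={chrom},length={genome.length(chrom)}>")
    lines.append('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(TRIO_SAMPLES))
    for r in sorted(records, key=lambda x: (x.chrom, x.pos, x.alt)):
        info = "." if r.af is None else f"AF={r.af!r}"
        gts = _GT[r.inheritance]
        lines.append(
            "\t".join([r.chrom, str(r.pos), ".", r.ref, r.alt, ".", "PASS", info, "GT", *gts])
        )
    return "\n".join(lines) + "\n"


def plant_variants(
    genome: GenomeSequence,
    models: Sequence[GeneModel],
    n_creations: int,
    n_nulls: int,
    seed: int,
    n_common: int = 10,
    n_recessive: int = 5,
    margin: int = 100,
) -> tuple[str, TruthTable]:
    """Plant SNVs with known splice-creation status; returns (trio VCF text,
    truth table).

    * ``n_creations`` rare variants (AF <= 0.001 or absent) that verifiably
      create >= 1 novel GT/AG on their transcript's strand; the first
      ``n_recessive`` carry the recessive trio pattern (proband 1/1, parents
      0/1), the rest carry non-recessive patterns.
    * ``n_nulls`` variants that create nothing on either strand, with AF both
      below and above the gate.
    * ``n_common`` creation variants with AF > 0.001, which the frequency
      gate must remove.
    """
    rng = np.random.default_rng(seed)
    if not models:
        raise FixtureError("no models to plant into")
    used: set[tuple[str, int]] = set()
    records: list[TruthRecord] = []

    def expected_for(chrom: str, pos: int, ref: str, alt: str) -> list:
        exp = []
        for m in models:
            if m.chrom != chrom:
                continue
            lo, hi = m.span
            if lo - margin <= pos <= hi + margin:
                for site_type, register, span in brute_force_oracle(
                    genome, (chrom, pos, ref, alt), m.strand
                ):
                    exp.append((site_type, register, span[0], span[1], m.transcript_id))
        return sorted(exp)

    def draw(creates: bool) -> tuple[str, int, str, str, list]:
        for _ in range(20000):
            m = models[int(rng.integers(0, len(models)))]
            lo, hi = m.span
            pos = int(rng.integers(lo, hi + 1))
            if (m.chrom, pos) in used:
                continue
            ref = genome.base(m.chrom, pos)
            if ref == "N":
                continue
            alts = [b for b in "ACGT" if b != ref]
            rng.shuffle(alts)
            for alt in alts:
                gains_here = brute_force_oracle(genome, (m.chrom, pos, ref, alt), m.strand)
                if creates and gains_here:
                    exp = expected_for(m.chrom, pos, ref, alt)
                    used.add((m.chrom, pos))
                    return m.chrom, pos, ref, alt, exp
                if not creates:
                    both = brute_force_oracle(
                        genome, (m.chrom, pos, ref, alt), "+"
                    ) + brute_force_oracle(genome, (m.chrom, pos, ref, alt), "-")
                    if not both:
                        used.add((m.chrom, pos))
                        return m.chrom, pos, ref, alt, []
        raise FixtureError("insufficient plantable positions")

    patterns = itertools.cycle(["other", "de_novo"])
    for i in range(n_creations):
        chrom, pos, ref, alt, exp = draw(creates=True)
        if i % 5 == 4:
            af = None  # unseen in the reference population
        else:
            af = round(float(rng.uniform(1e-6, 9e-4)), 10)
        inheritance = "autosomal_recessive" if i < n_recessive else next(patterns)
        records.append(TruthRecord(chrom, pos, ref, alt, af, inheritance, "creation", exp))

    for i in range(n_common):
        chrom, pos, ref, alt, exp = draw(creates=True)
        af = round(float(rng.uniform(0.002, 0.05)), 6)
        records.append(TruthRecord(chrom, pos, ref, alt, af, next(patterns), "common_creation", exp))

    for i in range(n_nulls):
        chrom, pos, ref, alt, _ = draw(creates=False)
        af = round(float(rng.uniform(1e-6, 9e-4)), 10) if i % 2 == 0 else round(
            float(rng.uniform(0.002, 0.05)), 6)
        records.append(TruthRecord(chrom, pos, ref, alt, af, next(patterns), "null", []))

    truth = TruthTable(records, seed)
    return _vcf_text(genome, records, seed), truth


# ---------------------------------------------------------------------------
# Coordinate mirroring (strand-involution support)
# ---------------------------------------------------------------------------

def mirror_genome(genome: GenomeSequence) -> GenomeSequence:
    """Reverse complement of every chromosome."""
    return GenomeSequence(
        {c: reverse_complement(genome.sequence(c)) for c in genome.chrom_names}
    )


def mirror_pos(pos: int, length: int) -> int:
    return length - pos + 1


def mirror_span(span: tuple[int, int], length: int) -> tuple[int, int]:
    a, b = span
    return (mirror_pos(b, length), mirror_pos(a, length))


def mirror_variant(v: VariantRecord, length: int) -> VariantRecord:
    return VariantRecord(
        chrom=v.chrom,
        pos=mirror_pos(v.pos, length),
        ref_allele=reverse_complement(v.ref_allele),
        alt_allele=reverse_complement(v.alt_allele),
        sample_genotypes=dict(v.sample_genotypes),
        info=dict(v.info),
        maf=v.maf,
    )


def mirror_model(m: GeneModel, length: int) -> GeneModel:
    exons = sorted(mirror_span(e, length) for e in m.exons)
    cds = None if m.cds_start is None else mirror_span((m.cds_start, m.cds_end), length)
    return GeneModel(
        gene_id=m.gene_id,
        transcript_id=m.transcript_id,
        chrom=m.chrom,
        strand="-" if m.strand == "+" else "+",
        exons=exons,
        cds_start=None if cds is None else cds[0],
        cds_end=None if cds is None else cds[1],
    )


# ---------------------------------------------------------------------------
# Synthetic worked example
# ---------------------------------------------------------------------------

@dataclass
class WorkedExample:
    genome: GenomeSequence
    model: GeneModel
    vcf_text: str
    variant_pos: int  # genomic, 1-based
    exon_index: int  # the exon whose skipping is predicted


def synthetic_worked_example() -> WorkedExample:
    """SYNTHETIC stand-in for the published SERCA1 case, engineered so the
    known exon arithmetic holds by construction.

    This is not a real reference transcript sequence. It is a plus-strand, 14-exon
    coding transcript in which: exon 11 is 103 bp and spans coding positions
    c.1185..c.1287; the last base of exon 11 (c.1287, the third base of a GAG
    glutamate codon at residue 429) is a reference G followed by the canonical
    GT of intron 11, so a G>A variant there creates a novel AG acceptor pair
    across the exon|intron junction while remaining synonymous in the exonic
    frame; the exon 10|11 junction splits codon 395 (leucine) after its second
    base; and the sequence downstream of exon 11 is chosen so that skipping
    exon 11 shifts the frame to a proline at residue 396 with a stop codon at
    position 23 of the new frame, well upstream of the last exon-exon
    junction. Everything downstream of these constraints is arbitrary.
    """
    # coding sequence, c.1..c.1800 (codon n = c.(3n-2..3n))
    codons = ["ATG"]
    codons += ["GAT"] * 393          # codons 2..394
    codons += ["CTG", "CTG"]         # codons 395 (split by exon 10|11), 396
    codons += ["GAT"] * 32           # codons 397..428
    codons += ["GAG"]                # codon 429; c.1287 = G (variant base)
    cds = "".join(codons)            # c.1..1287
    assert len(cds) == 1287
    # c.1288 onward: new-frame Pro + 21 Ala + TAA at c.1355-1357, then
    # reference-frame Lys/Glu codons to the normal stop at c.1798-1800
    tail = "C" + "CCA" + "GCA" * 21 + "TAA" + "AA" + "GAA" * 146 + "TAA"
    cds = cds + tail
    assert len(cds) == 1800

    utr5, utr3 = "GCCACCGCCACCGCCACCGC", "GCTA" * 12 + "GC"  # 20 + 50 nt
    mrna = utr5 + cds + utr3
    exon_lengths = [140] + [118] * 8 + [120, 103, 120, 120, 323]
    assert sum(exon_lengths) == len(mrna) == 1870
    intron = "GT" + "CAGA" * 49 + "AG"  # 200 nt, canonical ends
    pieces, offsets, pos = [], [], 0
    m = 0
    for i, elen in enumerate(exon_lengths):
        offsets.append(pos)
        pieces.append(mrna[m:m + elen])
        m += elen
        pos += elen
        if i < len(exon_lengths) - 1:
            pieces.append(intron)
            pos += len(intron)
    piece = "".join(pieces)

    pad = "ACGT" * 75  # 300 nt
    chrom = "chr16_synthetic"
    genome = GenomeSequence({chrom: pad + piece + pad})
    start0 = len(pad)
    exons = [(start0 + off + 1, start0 + off + elen) for off, elen in zip(offsets, exon_lengths)]

    def mrna_to_genomic(m_off: int) -> int:
        cum = 0
        for off, elen in zip(offsets, exon_lengths):
            if m_off < cum + elen:
                return start0 + off + (m_off - cum) + 1
            cum += elen
        raise FixtureError("offset outside exons")

    cds_start = mrna_to_genomic(len(utr5))
    cds_end = mrna_to_genomic(len(utr5) + 1800 - 1)
    model = GeneModel(
        gene_id="SERCA1_like_synthetic",
        transcript_id="tx_serca1_synthetic",
        chrom=chrom,
        strand="+",
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )
    model.validate()

    variant_pos = mrna_to_genomic(len(utr5) + 1287 - 1)  # c.1287
    assert genome.base(chrom, variant_pos) == "G"
    assert genome.base(chrom, variant_pos + 1) == "G"  # intron +1 (of GT)

    vcf = "\n".join([
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={genome.length(chrom)}>",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(TRIO_SAMPLES),
        f"{chrom}\t{variant_pos}\t.\tG\tA\t.\tPASS\tAF=8.1e-06\tGT\t1/1\t0/1\t0/1",
    ]) + "\n"

    return WorkedExample(genome=genome, model=model, vcf_text=vcf,
                         variant_pos=variant_pos, exon_index=11)
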