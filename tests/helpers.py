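"""Independent oracles and small model builders used across test modules."""

from Bio.Seq import Seq

from paness.variant_io import GeneModel, GenomeSequence


def build_plus_transcript(chrom_pad, utr5, cds, utr3, exon_lengths, intron="GT" + "C" * 26 + "AG"):
    """Assemble a plus-strand genome + model from an mRNA split into exons."""
    mrna = utr5 + cds + utr3
    assert sum(exon_lengths) == len(mrna)
    pieces, offsets, pos, m = [], [], 0, 0
    for i, elen in enumerate(exon_lengths):
        offsets.append(pos)
        pieces.append(mrna[m:m + elen])
        m += elen
        pos += elen
        if i < len(exon_lengths) - 1:
            pieces.append(intron)
            pos += len(intron)
    piece = "".join(pieces)
    genome = GenomeSequence({"chrT": chrom_pad + piece + chrom_pad})
    start0 = len(chrom_pad)
    exons = [(start0 + off + 1, start0 + off + elen) for off, elen in zip(offsets, exon_lengths)]

    def to_genomic(m_off):
        cum = 0
        for off, elen in zip(offsets, exon_lengths):
            if m_off < cum + elen:
                return start0 + off + (m_off - cum) + 1
            cum += elen
        raise AssertionError("offset outside exons")

    model = GeneModel(
        gene_id="gT", transcript_id="txT", chrom="chrT", strand="+", exons=exons,
        cds_start=to_genomic(len(utr5)), cds_end=to_genomic(len(utr5) + len(cds) - 1),
    )
    model.validate()
    return genome, model


def biopython_skip_oracle(genome, model, exon_index):
    """Translate-and-diff reference for exon-skip consequences, built on
    Bio.Seq translation rather than the package's codon machinery.

    Returns (frame_preserving, first_altered_residue or None,
    stop_offset or None, stop_reached).
    """
    def coding_seq(skip=None):
        order = model.exons_in_transcription_order()
        parts = []
        for idx, (s, e) in enumerate(order, start=1):
            if idx == skip:
                continue
            lo, hi = max(s, model.cds_start), min(e, model.cds_end)
            if lo <= hi:
                parts.append((lo, hi))
        parts.sort()
        seq = "".join(genome.fetch(model.chrom, lo - 1, hi) for lo, hi in parts)
        return str(Seq(seq).reverse_complement()) if model.strand == "-" else seq

    s, e = model.exon(exon_index)
    coding_skipped = max(0, min(e, model.cds_end) - max(s, model.cds_start) + 1)
    frame_preserving = coding_skipped % 3 == 0
    if coding_skipped == 0:
        return (True, None, None, True)

    ref_cds, skip_cds = coding_seq(), coding_seq(skip=exon_index)
    ref = str(Seq(ref_cds).translate(to_stop=True))
    skip_full = str(Seq(skip_cds[:len(skip_cds) - len(skip_cds) % 3]).translate())
    stop_reached = "*" in skip_full
    skip = skip_full.split("*")[0]

    i = 0
    while i < min(len(ref), len(skip)) and ref[i] == skip[i]:
        i += 1
    if frame_preserving:
        first = None if (skip == ref) else i + 1
        return (True, first, None, stop_reached)
    first = i + 1
    stop_offset = (len(skip) + 1 - i) if stop_reached else None
    if i >= len(skip) and stop_reached:
        stop_offset = 1
    return (False, first, stop_offset, stop_reached)
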