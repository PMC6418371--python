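"""Core screen: does an SNV create a novel essential splice-site dinucleotide?

An SNV can only create a dinucleotide it participates in, so exactly two
placements are evaluated on the transcribed strand: (variant base, next base
downstream in transcription order) and (previous base, variant base). A
placement is a candidate when the alternate pair reads GT (donor) or AG
(acceptor) on the transcribed strand *and* the reference pair at the identical
placement does not already read that dinucleotide — novelty is absolute.

Each candidate is reported with its sequence context aligned to the splice-site
consensus (the novel GT occupying intron positions +1/+2 for a donor, the novel
AG occupying intron positions -2/-1 for an acceptor), a weighted consensus
similarity in [0,1], and the signed distance to the nearest canonical site of
the same type (negative = the canonical site lies upstream, in transcription
order, of the candidate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

from intervaltree import IntervalTree

from .errors import ConfigurationError, ContextWindowError
from .variant_filtering import (
    FilterConfig,
    FrequencySource,
    annotate_maf,
    filter_by_maf,
)
from .variant_io import (
    CandidateReportRow,
    GeneModel,
    GenomeSequence,
    VariantRecord,
    VcfReadStats,
    read_vcf,
    reverse_complement,
)

log = logging.getLogger(__name__)

DONOR = "donor"
ACCEPTOR = "acceptor"
FIRST = "variant_is_first_base"
SECOND = "variant_is_second_base"

_ESSENTIAL = {DONOR: "GT", ACCEPTOR: "AG"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class ConsensusModel:
    """Splice-site consensus strings with per-position weights.

    Defaults follow the classical mammalian consensus: donor MAG|GTRAGT over
    positions -3..+6 of the exon|intron junction, acceptor (Y)12 NYAG|G over
    positions -16..+1. The essential dinucleotide positions (GT at +1/+2,
    AG at -2/-1) carry weight 0.25 each; the remaining 0.5 is spread uniformly
    over the extended positions. Weights may be overridden but must sum to 1
    with the essential positions carrying the largest weights.
    """

    donor: str = "MAGGTRAGT"
    donor_dinuc_index: int = 3  # 0-based index of the G of GT
    acceptor: str = "YYYYYYYYYYYYNYAGG"
    acceptor_dinuc_index: int = 14  # 0-based index of the A of AG
    donor_weights: Optional[list[float]] = None
    acceptor_weights: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if self.donor_weights is None:
            self.donor_weights = self._default_weights(len(self.donor), self.donor_dinuc_index)
        if self.acceptor_weights is None:
            self.acceptor_weights = self._default_weights(
                len(self.acceptor), self.acceptor_dinuc_index
            )
        for site_type in (DONOR, ACCEPTOR):
            consensus, dinuc, weights = self.for_site(site_type)
            if len(weights) != len(consensus):
                raise ConfigurationError(f"{site_type}: weight/consensus length mismatch")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ConfigurationError(f"{site_type}: weights must sum to 1")
            essential = {weights[dinuc], weights[dinuc + 1]}
            others = [w for i, w in enumerate(weights) if i not in (dinuc, dinuc + 1)]
            if others and min(essential) < max(others):
                raise ConfigurationError(
                    f"{site_type}: essential positions must carry the largest weights"
                )
            if consensus[dinuc:dinuc + 2] != _ESSENTIAL[site_type]:
                raise ConfigurationError(
                    f"{site_type}: consensus lacks {_ESSENTIAL[site_type]} at the "
                    "essential positions"
                )

    @staticmethod
    def _default_weights(length: int, dinuc_index: int) -> list[float]:
        rest = (length - 2)
        weights = [0.5 / rest] * length
        weights[dinuc_index] = 0.25
        weights[dinuc_index + 1] = 0.25
        return weights

    def for_site(self, site_type: str) -> tuple[str, int, list[float]]:
        if site_type == DONOR:
            return self.donor, self.donor_dinuc_index, self.donor_weights
        if site_type == ACCEPTOR:
            return self.acceptor, self.acceptor_dinuc_index, self.acceptor_weights
        raise ConfigurationError(f"unknown site type {site_type!r}")

    def window_shape(self, site_type: str) -> tuple[int, int]:
        """(bases before, bases after) the essential dinucleotide, in
        transcription order, for a consensus-aligned context window."""
        consensus, dinuc, _ = self.for_site(site_type)
        return dinuc, len(consensus) - dinuc - 2


def consensus_similarity(context: str, site_type: str, model: ConsensusModel) -> float:
    """Weighted fraction of positions matching the consensus IUPAC classes.

    1.0 iff every position matches; positions holding N in the context never
    match a non-N consensus class.
    """
    consensus, _, weights = model.for_site(site_type)
    if len(context) != len(consensus):
        raise ConfigurationError(
            f"context length {len(context)} != consensus length {len(consensus)} "
            f"for {site_type}"
        )
    score = 0.0
    for base, cons, w in zip(context.upper(), consensus, weights):
        if base in IUPAC[cons]:
            score += w
    return score


@dataclass
class SpliceSiteCandidate:
    """One putative novel donor/acceptor created by an SNV."""

    variant: VariantRecord
    gene_id: str
    transcript_id: str
    strand: str
    site_type: str
    register: str
    dinucleotide_span: tuple[int, int]  # genomic, 1-based closed
    alt_context: str
    ref_dinucleotide: str  # transcribed-strand reference pair at the placement
    canonical_context: str = ""
    distance_to_canonical: Optional[int] = None
    consensus_score: float = 0.0

    def __post_init__(self) -> None:
        target = _ESSENTIAL[self.site_type]
        if self.ref_dinucleotide == target:
            raise ValueError("candidate is not novel: reference pair already matches")
        lo, hi = self.dinucleotide_span
        if not lo <= self.variant.pos <= hi:
            raise ValueError("variant base outside dinucleotide span")


def transcribed_strand_window(
    genome: GenomeSequence,
    chrom: str,
    pos: int,
    flank: int,
    strand: str,
    alt: Optional[str] = None,
) -> str:
    """2*flank+1 window centred on 1-based ``pos``, read on the transcribed strand.

    ``alt`` (a plus-strand base, as in a VCF) replaces the centre base before
    any reverse complementing. Out-of-bounds windows raise.
    """
    if flank < 1:
        raise ConfigurationError("flank must be >= 1")
    seq = genome.fetch(chrom, pos - 1 - flank, pos + flank)
    if alt is not None:
        seq = seq[:flank] + alt.upper() + seq[flank + 1:]
    return seq if strand == "+" else reverse_complement(seq)


def _transcribed_context(
    genome: GenomeSequence,
    chrom: str,
    strand: str,
    first_base_pos: int,
    before: int,
    after: int,
    subst: Optional[tuple[int, str]] = None,
) -> str:
    """Window with `before` bases 5' and `after` bases 3' (transcription order)
    of a dinucleotide whose transcription-first base sits at genomic
    ``first_base_pos`` (1-based). ``subst`` substitutes a plus-strand base."""
    if strand == "+":
        lo, hi = first_base_pos - before, first_base_pos + 1 + after
    else:
        lo, hi = first_base_pos - 1 - after, first_base_pos + before
    seq = genome.fetch(chrom, lo - 1, hi)
    if subst is not None and lo <= subst[0] <= hi:
        i = subst[0] - lo
        seq = seq[:i] + subst[1] + seq[i + 1:]
    return seq if strand == "+" else reverse_complement(seq)


def _strand_base(genome: GenomeSequence, chrom: str, pos: int, strand: str) -> str:
    base = genome.base(chrom, pos)
    return base if strand == "+" else reverse_complement(base)


def enumerate_placements(
    genome: GenomeSequence,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    strand: str,
) -> list[tuple[str, str, tuple[int, int], int]]:
    """Sequence-level creation test for one SNV on one strand.

    Returns (site_type, register, genomic span, transcription-first base
    position) for every placement where the alternate pair reads GT or AG on
    the transcribed strand and the reference pair does not. Placements
    touching N or running off the chromosome yield nothing.
    """
    out = []
    ref_here = genome.base(chrom, pos)
    if ref_here != ref.upper():
        log.warning(
            "reference mismatch at %s:%d (VCF %s, genome %s); variant skipped",
            chrom, pos, ref, ref_here,
        )
        return out
    alt_t = alt.upper() if strand == "+" else reverse_complement(alt.upper())
    downstream = pos + 1 if strand == "+" else pos - 1
    upstream = pos - 1 if strand == "+" else pos + 1

    for register, partner_pos in ((FIRST, downstream), (SECOND, upstream)):
        if not 1 <= partner_pos <= genome.length(chrom):
            continue
        partner = _strand_base(genome, chrom, partner_pos, strand)
        ref_t = _strand_base(genome, chrom, pos, strand)
        if register == FIRST:
            alt_pair, ref_pair = alt_t + partner, ref_t + partner
            first_pos = pos
        else:
            alt_pair, ref_pair = partner + alt_t, partner + ref_t
            first_pos = partner_pos
        if "N" in alt_pair or "N" in ref_pair:
            log.info("N base in dinucleotide at %s:%d; placement skipped", chrom, pos)
            continue
        for site_type, target in _ESSENTIAL.items():
            if alt_pair == target and ref_pair != target:
                span = (min(pos, partner_pos), max(pos, partner_pos))
                out.append((site_type, register, span, first_pos))
    return out


def enumerate_creations(
    variant: VariantRecord,
    genome: GenomeSequence,
    model: GeneModel,
    margin: int = 100,
    consensus: Optional[ConsensusModel] = None,
) -> list[SpliceSiteCandidate]:
    """Candidates (unscored) this variant creates in one transcript's frame.

    Variants outside the transcript span by more than ``margin`` bp are not
    evaluated against that transcript. At most two candidates are possible
    (one per register).
    """
    if variant.chrom != model.chrom:
        return []
    lo, hi = model.span
    if not lo - margin <= variant.pos <= hi + margin:
        return []
    consensus = consensus or ConsensusModel()
    candidates = []
    placements = enumerate_placements(
        genome, variant.chrom, variant.pos, variant.ref_allele, variant.alt_allele,
        model.strand,
    )
    for site_type, register, span, first_pos in placements:
        before, after = consensus.window_shape(site_type)
        try:
            alt_context = _transcribed_context(
                genome, variant.chrom, model.strand, first_pos, before, after,
                subst=(variant.pos, variant.alt_allele),
            )
            ref_pair = _transcribed_context(
                genome, variant.chrom, model.strand, first_pos, 0, 0
            )
        except ContextWindowError as exc:
            log.warning("context window unavailable for %s:%d (%s)", variant.chrom,
                        variant.pos, exc)
            continue
        candidates.append(
            SpliceSiteCandidate(
                variant=variant,
                gene_id=model.gene_id,
                transcript_id=model.transcript_id,
                strand=model.strand,
                site_type=site_type,
                register=register,
                dinucleotide_span=span,
                alt_context=alt_context,
                ref_dinucleotide=ref_pair,
            )
        )
    return candidates


def _tcoord(pos: int, strand: str) -> int:
    """Coordinate increasing in transcription order."""
    return pos if strand == "+" else -pos


def canonical_sites(model: GeneModel) -> dict[str, list[int]]:
    """Transcription-first genomic positions of each canonical essential
    dinucleotide: donors (intron +1) after exons 1..n-1, acceptors (intron -2)
    before exons 2..n."""
    order = model.exons_in_transcription_order()
    donors, acceptors = [], []
    for (s1, e1), (s2, e2) in zip(order, order[1:]):
        if model.strand == "+":
            donors.append(e1 + 1)
            acceptors.append(s2 - 2)
        else:
            donors.append(s1 - 1)
            acceptors.append(e2 + 2)
    return {DONOR: donors, ACCEPTOR: acceptors}


def nearest_canonical_site(
    candidate: SpliceSiteCandidate,
    model: GeneModel,
    genome: GenomeSequence,
    consensus: Optional[ConsensusModel] = None,
) -> tuple[Optional[tuple[int, int]], Optional[int], Optional[str]]:
    """Nearest canonical site of the candidate's type: (genomic span of its
    essential dinucleotide, signed distance, reference consensus-window
    context). Distance is in transcription order relative to the candidate
    (negative = the canonical site is upstream); ties on |distance| resolve to
    the upstream site. Single-exon models have no canonical sites: null triple.
    """
    if model.n_exons < 2:
        return (None, None, None)
    consensus = consensus or ConsensusModel()
    sites = canonical_sites(model)[candidate.site_type]
    cand_t = _tcoord(
        candidate.dinucleotide_span[0] if model.strand == "+" else candidate.dinucleotide_span[1],
        model.strand,
    )
    best = min(sites, key=lambda p: (abs(_tcoord(p, model.strand) - cand_t),
                                     0 if _tcoord(p, model.strand) < cand_t else 1))
    distance = _tcoord(best, model.strand) - cand_t
    before, after = consensus.window_shape(candidate.site_type)
    try:
        context = _transcribed_context(genome, model.chrom, model.strand, best, before, after)
    except ContextWindowError:
        context = ""
    second = best + 1 if model.strand == "+" else best - 1
    span = (min(best, second), max(best, second))
    return (span, distance, context)


@dataclass
class PipelineConfig:
    """Everything run_paness needs beyond its input files."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    frequency: Optional[FrequencySource] = None
    consensus: ConsensusModel = field(default_factory=ConsensusModel)
    margin: int = 100
    genome_wide: bool = False
    sample_ids: Optional[list[str]] = None


def _row_from_candidate(c: SpliceSiteCandidate) -> CandidateReportRow:
    return CandidateReportRow(
        chrom=c.variant.chrom,
        pos=c.variant.pos,
        ref=c.variant.ref_allele,
        alt=c.variant.alt_allele,
        maf=c.variant.maf,
        gene_id=c.gene_id,
        transcript_id=c.transcript_id,
        site_type=c.site_type,
        strand=c.strand,
        register=c.register,
        span_start=c.dinucleotide_span[0],
        span_end=c.dinucleotide_span[1],
        alt_context=c.alt_context,
        canonical_context=c.canonical_context,
        consensus_score=c.consensus_score,
        dist_to_canonical=c.distance_to_canonical,
    )


def run_paness(
    vcf_source: Union[str, TextIO],
    genome: GenomeSequence,
    gene_models: list[GeneModel],
    config: Optional[PipelineConfig] = None,
) -> tuple[list[CandidateReportRow], dict]:
    """Whole-pipeline composition: read, annotate, gate on MAF, enumerate
    creations per overlapping transcript, attach canonical comparison and
    consensus score. Returns (sorted rows, run summary).

    In genome-wide mode transcript context is ignored: both strands are
    evaluated for every variant and rows carry empty gene fields. Per-record
    problems are aggregated in the summary; the run never aborts on one bad
    record.
    """
    config = config or PipelineConfig()
    stats = VcfReadStats()
    variants = read_vcf(vcf_source, sample_ids=config.sample_ids, stats=stats)

    errors: list[str] = []
    if config.frequency is not None:
        annotated = []
        for v in variants:
            try:
                annotated.append(annotate_maf(v, config.frequency))
            except Exception as exc:
                errors.append(str(exc))
                annotated.append(v)
        variants = annotated
    low_maf = filter_by_maf(variants, config.filters)

    trees: dict[str, IntervalTree] = {}
    by_id: dict[str, GeneModel] = {}
    for m in gene_models:
        lo, hi = m.span
        trees.setdefault(m.chrom, IntervalTree()).addi(
            max(1, lo - config.margin), hi + config.margin + 1, m
        )
        by_id[m.transcript_id] = m

    rows: list[CandidateReportRow] = []
    for v in low_maf:
        try:
            if config.genome_wide:
                for strand in "+-":
                    for site_type, register, span, first_pos in enumerate_placements(
                        genome, v.chrom, v.pos, v.ref_allele, v.alt_allele, strand
                    ):
                        before, after = config.consensus.window_shape(site_type)
                        try:
                            ctx = _transcribed_context(
                                genome, v.chrom, strand, first_pos, before, after,
                                subst=(v.pos, v.alt_allele),
                            )
                        except ContextWindowError:
                            continue
                        cand = SpliceSiteCandidate(
                            variant=v, gene_id="", transcript_id="", strand=strand,
                            site_type=site_type, register=register,
                            dinucleotide_span=span, alt_context=ctx,
                            ref_dinucleotide=_transcribed_context(
                                genome, v.chrom, strand, first_pos, 0, 0),
                        )
                        cand.consensus_score = consensus_similarity(
                            ctx, site_type, config.consensus)
                        rows.append(_row_from_candidate(cand))
            else:
                tree = trees.get(v.chrom)
                if tree is None:
                    continue
                for iv in sorted(tree[v.pos], key=lambda i: i.data.transcript_id):
                    model = iv.data
                    for cand in enumerate_creations(
                        v, genome, model, margin=config.margin, consensus=config.consensus
                    ):
                        span, dist, ctx = nearest_canonical_site(
                            cand, model, genome, config.consensus)
                        cand.canonical_context = ctx or ""
                        cand.distance_to_canonical = dist
                        cand.consensus_score = consensus_similarity(
                            cand.alt_context, cand.site_type, config.consensus)
                        rows.append(_row_from_candidate(cand))
        except Exception as exc:  # pragma: no cover - defensive aggregation
            errors.append(f"{v.chrom}:{v.pos} {v.ref_allele}>{v.alt_allele}: {exc}")

    rows.sort(key=lambda r: r.sort_key)
    summary = {
        "input_records": stats.input_records,
        "non_snv_dropped": stats.dropped_non_snv,
        "snvs": stats.snv_records,
        "low_maf_kept": len(low_maf),
        "candidates": len(rows),
        "candidate_variants": len({(r.chrom, r.pos, r.ref, r.alt) for r in rows}),
        "genes_affected": len({r.gene_id for r in rows if r.gene_id}),
        "errors": errors,
    }
    return rows, summary
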