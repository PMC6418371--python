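"""Readers, writers and domain types for the formats the pipeline touches.

VCF and GTF are consumed in their native 1-based closed coordinates (via pysam
and gffutils respectively); every internal sequence computation uses 0-based
half-open coordinates, converted at this boundary. The candidate report is a
fixed-column TSV defined here; the minimal transcript TSV dialect (one line per
transcript) exists so fixtures and small hand-written models need no GTF.

Minimal transcript TSV dialect, whitespace-separated::

    gene_id  transcript_id  chrom  strand  exon1start-exon1end,...  [CDS:start-end]

with all coordinates 1-based closed, exons sorted by start, e.g.::

    gene1  tx1  chr1  +  101-200,301-400  CDS:121-380
"""

from __future__ import annotations

import enum
import io
import logging
import os
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ContextWindowError, GeneModelError, VcfParseError

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class VariantRecord:
    """One normalized single-nucleotide variant.

    ``pos`` is the 1-based genomic position of the variant base. Multi-allelic
    VCF records are split upstream, so each record carries exactly one alt
    allele; ``sample_genotypes`` is relative to that allele.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    sample_genotypes: dict[str, Genotype] = field(default_factory=dict)
    info: dict[str, str] = field(default_factory=dict)
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if len(allele) != 1 or allele not in BASES:
                raise ValueError(f"{name} allele must be one of A/C/G/T, got {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def with_maf(self, maf: Optional[float]) -> "VariantRecord":
        return replace(self, maf=maf)


class GenomeSequence:
    """Uppercase per-chromosome nucleotide strings with bounds-checked access.

    ``fetch`` uses 0-based half-open coordinates; out-of-bounds queries raise
    rather than silently clipping.
    """

    def __init__(self, chroms: dict[str, str]):
        self._chroms = {name: seq.upper() for name, seq in chroms.items()}

    @classmethod
    def from_fasta(cls, source: Union[str, Path, TextIO]) -> "GenomeSequence":
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                records = list(SeqIO.parse(fh, "fasta"))
        else:
            records = list(SeqIO.parse(source, "fasta"))
        return cls({rec.id: str(rec.seq) for rec in records})

    def to_fasta(self, dest: Union[str, Path, TextIO]) -> None:
        records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in self._chroms.items()]
        if isinstance(dest, (str, Path)):
            with open(dest, "w") as fh:
                SeqIO.write(records, fh, "fasta")
        else:
            SeqIO.write(records, dest, "fasta")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    def length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def sequence(self, chrom: str) -> str:
        return self._chroms[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom[start:end)``, 0-based half-open, bounds-checked."""
        if chrom not in self._chroms:
            raise ContextWindowError(f"unknown chromosome {chrom!r}")
        seq = self._chroms[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ContextWindowError(
                f"window [{start},{end}) outside bounds of {chrom} (length {len(seq)})"
            )
        return seq[start:end]

    def base(self, chrom: str, pos: int) -> str:
        """Single reference base at 1-based position ``pos``."""
        return self.fetch(chrom, pos - 1, pos)

    def _overwrite(self, chrom: str, start: int, segment: str) -> None:
        # fixture-generator hook: splice `segment` into chrom at 0-based `start`
        seq = self._chroms[chrom]
        if start < 0 or start + len(segment) > len(seq):
            raise ContextWindowError("overwrite outside chromosome bounds")
        self._chroms[chrom] = seq[:start] + segment.upper() + seq[start + len(segment):]


@dataclass
class GeneModel:
    """One transcript: strand, ordered exons, optional CDS span.

    ``exons`` are 1-based closed genomic intervals sorted ascending by start;
    exon *numbering* is strand-aware (exon 1 is 5'-most in transcription
    order). This type is the source of gene orientation and of canonical
    splice junctions for the scan.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def validate(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise GeneModelError(f"{self.transcript_id}: no exons")
        exons = sorted(self.exons)
        if exons != self.exons:
            raise GeneModelError(f"{self.transcript_id}: exons not sorted by start")
        for start, end in exons:
            if start > end or start < 1:
                raise GeneModelError(f"{self.transcript_id}: bad exon interval ({start},{end})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1 + 1:  # overlap or zero-length intron
                raise GeneModelError(
                    f"{self.transcript_id}: exons ({s1},{e1}) and ({s2},{e2}) overlap or abut"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise GeneModelError(f"{self.transcript_id}: partial CDS bounds")
        if self.cds_start is not None:
            if not (self.span[0] <= self.cds_start <= self.cds_end <= self.span[1]):
                raise GeneModelError(f"{self.transcript_id}: CDS outside transcript span")
            for bound in (self.cds_start, self.cds_end):
                if not any(s <= bound <= e for s, e in exons):
                    raise GeneModelError(f"{self.transcript_id}: CDS bound {bound} not exonic")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def exons_in_transcription_order(self) -> list[tuple[int, int]]:
        """Exon intervals with exon 1 first (reversed genomic order on minus)."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def exon(self, number: int) -> tuple[int, int]:
        """1-based strand-aware exon lookup."""
        order = self.exons_in_transcription_order()
        if not 1 <= number <= len(order):
            raise GeneModelError(f"{self.transcript_id}: no exon {number}")
        return order[number - 1]


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

@dataclass
class VcfReadStats:
    input_records: int = 0
    snv_records: int = 0
    dropped_non_snv: int = 0


def _genotype_for_allele(gt: tuple, allele_index: int) -> Genotype:
    if gt is None or any(a is None for a in gt):
        return Genotype.MISSING
    hits = sum(1 for a in gt if a == allele_index)
    if hits == len(gt) and hits > 0:
        return Genotype.HOM_ALT
    if hits >= 1:
        return Genotype.HET
    return Genotype.HOM_REF  # zero copies of this alt allele


def _info_to_str(value, allele_index: int, n_alts: int) -> str:
    """Flatten a pysam INFO value; Number=A tuples are allele-matched."""
    if isinstance(value, tuple):
        if len(value) == n_alts:
            value = value[allele_index]
        else:
            return ",".join("" if v is None else str(v) for v in value)
    if value is None:
        return ""
    if value is True:
        return "1"
    return str(value)


def read_vcf(
    source: Union[str, Path, TextIO],
    sample_ids: Optional[Sequence[str]] = None,
    stats: Optional[VcfReadStats] = None,
) -> list[VariantRecord]:
    """Read a VCF 4.x file into normalized :class:`VariantRecord` objects.

    Multi-allelic records are split, one record per alt allele. Non-SNV
    alleles (indels, MNVs, symbolic, breakends) are dropped; the drop count is
    logged and recorded in ``stats`` when given. Alleles are uppercased.
    """
    if isinstance(source, (str, Path)):
        return _read_vcf_path(os.fspath(source), sample_ids, stats)
    # pysam needs a real path; spool file-like / text input to a temp file
    text = source.read()
    with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as tmp:
        tmp.write(text)
        path = tmp.name
    try:
        return _read_vcf_path(path, sample_ids, stats)
    finally:
        os.unlink(path)


def _read_vcf_path(path, sample_ids, stats) -> list[VariantRecord]:
    if stats is None:
        stats = VcfReadStats()
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"malformed VCF header in {path}: {exc}") from exc
    header_samples = list(vf.header.samples)
    if sample_ids is not None:
        missing = set(sample_ids) - set(header_samples)
        if missing:
            raise VcfParseError(f"samples absent from VCF header: {sorted(missing)}")
        samples = list(sample_ids)
    else:
        samples = header_samples

    records: list[VariantRecord] = []
    record_no = 0
    iterator = iter(vf)
    while True:
        try:
            rec = next(iterator)
        except StopIteration:
            break
        except (ValueError, OSError) as exc:
            raise VcfParseError(
                f"malformed VCF record #{record_no + 1} in {path}: {exc}"
            ) from exc
        record_no += 1
        stats.input_records += 1
        ref = (rec.ref or "").upper()
        alts = rec.alts or ()
        n_alts = len(alts)
        for i, alt in enumerate(alts):
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES or ref == alt:
                stats.dropped_non_snv += 1
                continue
            genotypes = {}
            for s in samples:
                try:
                    gt = rec.samples[s].get("GT")
                except KeyError:
                    gt = None
                genotypes[s] = _genotype_for_allele(gt, i + 1)
            info = {k: _info_to_str(v, i, n_alts) for k, v in rec.info.items()}
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    sample_genotypes=genotypes,
                    info=info,
                )
            )
            stats.snv_records += 1
    if stats.dropped_non_snv:
        log.info("read_vcf: dropped %d non-SNV allele(s)", stats.dropped_non_snv)
    return records


def write_vcf_text(records: Iterable[VariantRecord], sample_order: Sequence[str]) -> str:
    """Serialize SNV records back to minimal VCF 4.2 text (round-trip support)."""
    gt_map = {
        Genotype.HOM_REF: "0/0",
        Genotype.HET: "0/1",
        Genotype.HOM_ALT: "1/1",
        Genotype.MISSING: "./.",
    }
    records = list(records)
    chroms = sorted({r.chrom for r in records})
    lines = ["##fileformat=VCFv4.2"]
    for c in chroms:
        length = max(r.pos for r in records if r.chrom == c) + 1000
        lines.append(f"##contig=<ID={c},length={length}>")
    lines.append('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT", *sample_order]
    lines.append("\t".join(header))
    for r in sorted(records, key=lambda v: (v.chrom, v.pos, v.ref_allele, v.alt_allele)):
        info = ";".join(f"{k}={v}" for k, v in r.info.items() if v != "") or "."
        gts = [gt_map[r.sample_genotypes.get(s, Genotype.MISSING)] for s in sample_order]
        lines.append(
            "\t".join([r.chrom, str(r.pos), ".", r.ref_allele, r.alt_allele, ".", ".", info, "GT", *gts])
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Gene-model reading
# ---------------------------------------------------------------------------

def read_gene_models(source: Union[str, Path, TextIO]) -> list[GeneModel]:
    """Read transcript models from GTF or from the minimal TSV dialect.

    The format is sniffed from the first data line (9 tab-separated columns
    with an attribute field containing ``transcript_id`` means GTF). Models
    that violate :class:`GeneModel` invariants are rejected individually with
    a warning; an input yielding no parseable transcript raises.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    first = next((ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")), "")
    if first.count("\t") >= 8:
        models = _models_from_gtf(text)
    else:
        models = _models_from_tsv(text)
    kept = []
    for m in models:
        try:
            m.validate()
        except GeneModelError as exc:
            log.warning("rejecting model %s: %s", m.transcript_id, exc)
            continue
        kept.append(m)
    if not kept:
        raise GeneModelError("no valid transcript model in input")
    return kept


def _models_from_gtf(text: str) -> list[GeneModel]:
    try:
        db = gffutils.create_db(
            text,
            ":memory:",
            from_string=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises a mix of types on bad input
        raise GeneModelError(f"cannot parse GTF: {exc}") from exc

    exons: dict[str, dict] = {}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            try:
                tid = feat.attributes["transcript_id"][0]
            except KeyError:
                log.warning("GTF %s feature without transcript_id skipped", ftype)
                continue
            gid = feat.attributes.get("gene_id", [tid])[0]
            entry = exons.setdefault(
                tid, {"gene": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": [], "cds": []}
            )
            entry["exons" if ftype == "exon" else "cds"].append((feat.start, feat.end))

    models = []
    for tid, entry in exons.items():
        cds = sorted(entry["cds"])
        models.append(
            GeneModel(
                gene_id=entry["gene"],
                transcript_id=tid,
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=sorted(entry["exons"]),
                cds_start=cds[0][0] if cds else None,
                cds_end=cds[-1][1] if cds else None,
            )
        )
    return models


def _models_from_tsv(text: str) -> list[GeneModel]:
    models = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) not in (5, 6):
            raise GeneModelError(f"transcript TSV line {lineno}: expected 5 or 6 fields")
        gene_id, tid, chrom, strand, exon_field = fields[:5]
        try:
            exons = [
                (int(a), int(b))
                for a, b in (part.split("-") for part in exon_field.split(","))
            ]
        except ValueError as exc:
            raise GeneModelError(f"transcript TSV line {lineno}: bad exon list") from exc
        cds_start = cds_end = None
        if len(fields) == 6:
            if not fields[5].startswith("CDS:"):
                raise GeneModelError(f"transcript TSV line {lineno}: 6th field must be CDS:start-end")
            a, b = fields[5][4:].split("-")
            cds_start, cds_end = int(a), int(b)
        models.append(
            GeneModel(gene_id, tid, chrom, strand, sorted(exons), cds_start, cds_end)
        )
    return models


def write_gene_models_tsv(models: Iterable[GeneModel]) -> str:
    """Serialize models to the minimal TSV dialect."""
    lines = []
    for m in models:
        exon_field = ",".join(f"{s}-{e}" for s, e in m.exons)
        parts = [m.gene_id, m.transcript_id, m.chrom, m.strand, exon_field]
        if m.is_coding:
            parts.append(f"CDS:{m.cds_start}-{m.cds_end}")
        lines.append("\t".join(parts))
    return "\n".join(lines) + "\n"


def write_gene_models_gtf(models: Iterable[GeneModel], source: str = "paness") -> str:
    """Serialize models to GTF2.2 exon/CDS lines (validated by read round-trip)."""
    lines = []
    for m in models:
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
        for s, e in m.exons:
            lines.append("\t".join([m.chrom, source, "exon", str(s), str(e), ".", m.strand, ".", attrs]))
        if m.is_coding:
            for s, e in m.exons:
                cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                if cs <= ce:
                    lines.append(
                        "\t".join([m.chrom, source, "CDS", str(cs), str(ce), ".", m.strand, "0", attrs])
                    )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Candidate report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "maf", "gene_id", "transcript_id", "site_type",
    "strand", "register", "span_start", "span_end", "alt_context",
    "canonical_context", "consensus_score", "dist_to_canonical",
]


@dataclass(frozen=True)
class CandidateReportRow:
    """One candidate splice-site creation: a (variant, transcript, placement) triple."""

    chrom: str
    pos: int
    ref: str
    alt: str
    maf: Optional[float]
    gene_id: str
    transcript_id: str
    site_type: str  # donor | acceptor
    strand: str
    register: str  # variant_is_first_base | variant_is_second_base
    span_start: int
    span_end: int
    alt_context: str
    canonical_context: str
    consensus_score: float
    dist_to_canonical: Optional[int]

    @property
    def sort_key(self):
        return (self.chrom, self.pos, self.transcript_id, self.site_type, self.register)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_candidates(rows: Iterable[CandidateReportRow], dest: Union[str, Path, TextIO]) -> None:
    """Write the candidate report TSV with its fixed header and deterministic sort."""
    out = io.StringIO()
    out.write("\t".join(REPORT_COLUMNS) + "\n")
    for row in sorted(rows, key=lambda r: r.sort_key):
        values = [getattr(row, c) for c in REPORT_COLUMNS]
        out.write("\t".join(_fmt(v) for v in values) + "\n")
    text = out.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


def read_candidates(source: Union[str, Path, TextIO]) -> list[CandidateReportRow]:
    """Read a candidate report TSV back (round-trip inverse of write_candidates)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = text.splitlines()
    if not lines or lines[0].split("\t") != REPORT_COLUMNS:
        raise VcfParseError("candidate report header mismatch")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        rows.append(
            CandidateReportRow(
                chrom=f[0], pos=int(f[1]), ref=f[2], alt=f[3],
                maf=float(f[4]) if f[4] else None,
                gene_id=f[5], transcript_id=f[6], site_type=f[7], strand=f[8],
                register=f[9], span_start=int(f[10]), span_end=int(f[11]),
                alt_context=f[12], canonical_context=f[13],
                consensus_score=float(f[14]),
                dist_to_canonical=int(f[15]) if f[15] else None,
            )
        )
    return rows
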