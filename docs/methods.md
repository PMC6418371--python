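# Methods

## Model and scope

`paness` detects *creation* of essential splice-site dinucleotides by
single-nucleotide variants. The underlying observation is combinatorial: an
SNV can only create a dinucleotide it participates in, so for each variant
exactly two placements need checking on the transcribed strand — (variant
base, next base downstream in transcription order) and (previous base,
variant base). A placement is a candidate when the alternate pair reads `GT`
(donor) or `AG` (acceptor) on that strand **and** the reference pair at the
identical placement does not already read that dinucleotide. Novelty is
judged only at the identical placement, not against nearby GT/AG occurrences:
"creation" is read as a ref→alt change of that specific pair. Destruction or
weakening of existing sites is out of scope, as are extended-site-only
changes, branch points, splice enhancers, and learned splice-strength models.

Indels and MNVs are excluded at the I/O boundary (the method is defined over
single-nucleotide changes); multi-allelic records are split into one record
per alternate allele with allele-matched INFO values and per-allele genotype
classification. Any placement touching an `N` yields no candidate: undefined
sequence cannot create a defined motif.

A variant is evaluated against every transcript whose span (± a margin,
default 100 bp) contains it, independently per transcript; duplicate rows
across overlapping transcripts are expected and keyed by `transcript_id`.
Candidates that coincide with a canonical junction are retained (distance 0),
not suppressed — a variant at an exon-final base is exactly the kind of case
the screen exists for. A transcript-free *genome-wide* mode evaluates both
strands with empty gene fields, for inputs without usable gene models.

## Coordinates

VCF and GTF are consumed in their native 1-based closed convention (via pysam
and gffutils); all internal sequence arithmetic is 0-based half-open,
converted once at the I/O boundary. Sequence windows that would leave the
chromosome raise, and are reported per record rather than clipped. Exon
numbering is strand-aware: exon 1 is the 5'-most exon in transcription order.

## Consensus comparison

Defaults follow the classical mammalian splice consensus:

| site | consensus (IUPAC) | positions | essential |
|---|---|---|---|
| donor | `MAG\|GTRAGT` | −3..+6 | GT at +1,+2 |
| acceptor | `YYYYYYYYYYYYNYAG\|G` | −16..+1 | AG at −2,−1 |

The acceptor string defines 16 intronic positions (a 12-base polypyrimidine
stretch, N, Y, then AG) plus the first exonic base; window lengths are always
derived from the consensus string lengths (9 and 17 nt), so overriding the
consensus in configuration changes the windows consistently.

The score is a weighted fraction of positions whose base falls in the IUPAC
class at that position. The essential dinucleotide positions carry weight
0.25 each; the remaining 0.5 is uniform over the extended positions.
Consequences: the score is 1.0 iff every position matches; a candidate always
matches its two essential positions by construction, so scores start at 0.5
and the extended context differentiates candidates. The weighting is a
documented default, overridable (weights must sum to 1 with the essential
positions largest); it is a similarity, not a biophysical strength — this
package deliberately does not model splice-site strength.

Each candidate's `alt_context` is the consensus-aligned window with the
alternate allele substituted (the novel GT at donor +1/+2, the novel AG at
acceptor −2/−1); `canonical_context` is the reference sequence of the nearest
canonical site of the same type in the same window shape. Distance is signed
in transcription order relative to the candidate (negative = the canonical
site lies upstream); ties on |distance| resolve to the upstream site, for
determinism.

## Filtering

The frequency gate keeps variants with MAF ≤ 0.001 (comparator configurable;
`≤` is the default so a variant exactly at the threshold passes). A variant
absent from the frequency source has MAF `None` — never 0 — and passes the
gate by default, on the reasoning that an allele never observed in a large
reference population is rarer than any practical threshold; such variants are
counted separately in the log. Frequencies come either from an INFO field of
an annotated VCF or from an external TSV table (both supported because
annotation workflows differ in where they put the number).

The standard screen (effect classes, conservation/pathogenicity score
thresholds) is deliberately liberal: an absent annotation never excludes a
variant. Scores are consumed as pre-computed columns; nothing is recomputed.

Trio filtering classifies each variant's genotype pattern: autosomal
recessive requires a homozygous-alternate proband with two heterozygous
parents; the dominant de novo model requires a carrier proband with two
homozygous-reference parents. Sample roles are assigned explicitly in
configuration rather than parsed from pedigree files. A missing genotype
fails the pattern by default (`strict=True` raises instead). X-linked and
compound-heterozygous models are not implemented.

## Exon-skip consequence

The skip event is taken as given; the module computes only its effect. The
coding portion of the skipped exon determines the frame: length mod 3 = 0 is
frame-preserving (reported as an HGVS deletion, or delins when the junction
codon changes), otherwise a frameshift. Reference and skipped coding
sequences are translated with the standard genetic code and diffed; the first
differing residue anchors the HGVS description. fsTer numbering counts the
first altered residue as position 1, so `p.(Leu396ProfsTer23)` places the new
stop at position 23 of the shifted frame; a frameshift whose first shifted
codon is already a stop is reported as a nonsense change `p.(XposTer)`; a
shifted frame that never reaches a stop is reported `fsTer?` and flagged.
Skipping a wholly non-coding exon is "no protein change" (`p.(=)`), and
skipping the exon containing the start codon is rejected. The NMD flag is
the 50-nt heuristic: a premature stop at least 50 nt upstream of the last
exon–exon junction of the skipped transcript marks a likely NMD substrate.

## Synthetic fixtures

The generators emulate exactly what the screen needs and nothing more:
uniform-composition genomes at a requested GC fraction; transcripts with 2–8
exons, canonical `GT...AG` introns written at every junction, and valid CDS
(ATG start, in-frame stop, no internal stop); planted SNVs verified at plant
time against a brute-force oracle (a naive full-string scan kept separate
from the production placement logic); and trio genotypes assigned per planted
inheritance label. Allele frequencies straddle the 0.001 gate, including
absent-from-reference variants. All outputs are byte-identical for a fixed
seed, which is recorded as a comment/header in every emitted file.

What the fixtures do **not** emulate: real splice-site strength
distributions, linkage, mutation-rate heterogeneity, sequencing error,
overlapping genes, or alternative isoforms of one gene. Passing the
planted-truth tests therefore demonstrates the correctness of the placement
logic, the gates and the bookkeeping — not the clinical yield of the screen
on real exomes.

The worked-example fixture (`synthetic_worked_example`) is a labelled
synthetic stand-in for a published case: a 14-exon transcript engineered so
that a 103-bp exon 11 spans c.1185..c.1287, the exon-final base is the third
base of a GAG glutamate codon (residue 429) followed by the canonical intron
GT, the exon 10|11 junction splits a leucine codon at residue 395, and the
downstream sequence places the shifted-frame stop at offset 23. The pipeline
computes candidate detection, the frameshift and the NMD flag from this
sequence; the fixture encodes the published exon arithmetic as input, not the
answers.

## Problem sizes and numerical choices

The acceptance script and tests use: a 10 kb genome for the exhaustive
oracle sweep (all 30,000 SNVs × both strands), a 100 kb genome with 20
transcripts and 200+200+10 planted variants for recovery and trio checks, and
a 400 kb genome with 150 transcripts for the 100-transcript consequence-oracle
comparison. These sizes give exact, exhaustive coverage of the combinatorics
the method rests on while keeping the full suite under half a minute; larger
genomes add volume, not new cases, because every dinucleotide neighbourhood
class is already enumerated.

Other choices: report rows are sorted by (chrom, pos, transcript_id,
site_type, register) so runs are byte-reproducible; the transcript-overlap
margin defaults to 100 bp (near-gene sites are part of the method's point;
the bound is configurable); reference-mismatching variants (VCF REF ≠ genome
base) are skipped with a warning rather than trusted.

## Known limitations

* Creation detection only; no site-destruction or strength-change analysis.
* The consensus similarity is positional and unweighted by information
  content; it ranks context quality but is not calibrated to splicing
  efficiency.
* Single-exon-skip consequences only; intron retention, partial-exon usage
  via the novel site, and multi-exon skips are not modelled.
* GTF and the minimal TSV dialect are the only model inputs (no GFF3); VCF
  is the only variant input (no BCF/CRAM).
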