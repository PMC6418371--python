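# paness

Screen single-nucleotide variants for the **creation of novel essential
splice-site dinucleotides** — GT (donor) or AG (acceptor) on the transcribed
strand — in existing VCF data, with population-frequency and trio-inheritance
filtering and prediction of the exon-skip protein consequence.

## The problem

Standard variant annotation looks at canonical splice junctions. A synonymous
or intronic SNV can nevertheless *create* a cryptic splice site: if the
alternate allele turns a dinucleotide it participates in into GT or AG on the
transcribed strand, the spliceosome may use the new site, skipping an exon or
truncating a transcript. Such variants pass effect-class filters as
"synonymous, not potentially pathogenic" and are invisible unless the
sequence around each variant is examined directly.

`paness` makes that examination systematic. For each low-frequency SNV
(MAF ≤ 0.001 by default) it evaluates exactly the two dinucleotide placements
containing the variant base, in both registers, on the strand of each
overlapping transcript:

* **creation test** — the alternate pair reads `GT` or `AG` and the reference
  pair at the identical placement does not (novelty is absolute);
* **consensus comparison** — the candidate's context is aligned to the
  classical splice consensus (donor `MAG|GTRAGT`, positions −3..+6; acceptor
  `(Y)₁₂NYAG|G`, positions −16..+1) and scored as a weighted fraction of
  matching IUPAC classes, with the essential GT/AG positions weighted 0.25
  each;
* **canonical context** — the nearest canonical site of the same type is
  reported with its sequence and signed distance in transcription order.

Candidates can then be filtered by trio genotypes (autosomal recessive:
proband 1/1, both parents 0/1), and the downstream consequence of skipping an
exon is computed by reading-frame arithmetic: an exon whose coding length is
not a multiple of 3 produces a frameshift, reported in HGVS notation such as
`p.(Leu396ProfsTer23)` (frameshift starting at Leu396, replaced by Pro, stop
at position 23 of the new frame), with a 50-nt-rule flag for likely
nonsense-mediated decay.

## Worked example

Everything is testable offline: the `make-fixtures` subcommand writes a
seeded synthetic genome, transcript models (GTF and a minimal TSV dialect),
a trio VCF with planted splice-creating variants, and a ground-truth table.

```bash
paness make-fixtures --seed 7 --length 60000 --transcripts 10 \
    --creations 40 --nulls 40 --common 5 --recessive 5 --out fixtures
paness scan --vcf fixtures/trio.vcf --fasta fixtures/genome.fa \
    --genes fixtures/models.gtf --out scan
```

prints

```
INFO:paness.cli:scan: 85 input record(s), 85 SNV(s), 60 low-MAF, 42 candidate row(s) in 10 gene(s)
```

85 variants were read; 60 pass the MAF ≤ 0.001 gate (25 planted common and
high-frequency-null variants are removed); the 40 planted creations yield 42
candidate rows (a variant can create sites in both registers). The report
`scan/candidates.tsv` begins:

```
chrom  pos   ref alt maf        gene_id transcript_id site_type strand register                span_start span_end alt_context        canonical_context  consensus_score dist_to_canonical
chr1   817   T   G   0.000487   gene1   tx1           acceptor  +      variant_is_second_base  816        817      CCGTGTTAGCGCCTAGG  GGCGTCTCTCAACAAGT  0.833           33
```

The variant at chr1:817 creates an AG pair (it is the second base of the new
dinucleotide); the 17-nt context is aligned so the novel AG occupies acceptor
positions −2/−1, scores 0.833 against the consensus, and lies 33 bp
downstream of the nearest canonical acceptor.

Trio filtering and consequence prediction:

```bash
paness trio --vcf fixtures/trio.vcf --fasta fixtures/genome.fa \
    --genes fixtures/models.gtf \
    --roles proband=proband,mother=mother,father=father --out trio
# -> trio: 5 candidate row(s) consistent with autosomal_recessive

paness consequence --fasta fixtures/genome.fa --genes fixtures/models.gtf \
    --transcript tx1 --exon 2 --out cons
# -> p.(Asn18SerfsTer10)
```

Exactly the 5 planted recessive-pattern variants survive the trio filter, and
skipping the 197-bp exon 2 of `tx1` (197 mod 3 ≠ 0) frameshifts at residue 18
with a premature stop 10 codons into the new frame.

The same operations are available as library functions
(`run_paness`, `classify_inheritance`, `predict_exon_skip`, ...); see the
docstrings and `docs/methods.md`.

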