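# Methods

`scanlong` re-implements the computational side of a barcoded
full-length single-cell RNA-seq protocol on a long-read platform: pooled
cells carry 24-nt barcodes in the RT primer, cDNAs are flanked on both
ends by a 25-nt ISPCR anchor (`AAGCAGTGGTATCAACGCAGAGTAC`), and single
reads span entire transcripts. This note records the models, rules and
numerical choices the package commits to, and what its synthetic data
can and cannot show.

## Amplicon model and simulator

The simulator emits reads of the amplicon

```
anchor + ATGGG + transcript + polyA(25) + rc(barcode) + rc(anchor)
```

from either strand with equal probability. With probability
`truncation_prob` a read loses its TSO end together with a uniform
fraction of the transcript 5′ end — emulating incomplete reverse
transcription, the dominant incompleteness mode of polyT-primed
chemistry. Errors are i.i.d. per base (`p_sub`, `p_ins`, `p_del`; at
most one insertion after a base); error-free bases get Q20 and
error-carrying bases Q7, so qscore filters are exercisable. Everything
derives from a `numpy` `Generator`; identical inputs and seed give
byte-identical outputs. Barcodes, cell expression vectors and the
genome are drawn from separately keyed streams of the same seed so a
single seed never replays the barcode bases inside the genome.

Toy references place multi-exon genes on alternating strands of one
chromosome. Genes with ≥3 exons get a second transcript skipping exon
2; genes with ≥5 exons additionally get a third skipping the
penultimate exon, so a gene owns two skip junctions in *different*
transcripts — the precondition for a novel *combination* of annotated
junctions. Strain SNPs are placed only at exonic positions at a target
density per exonic kb (default 5/kb, chosen so a typical full-length
read covers several informative sites). The 3′-terminal transcript base
is pinned to a non-A so the synthetic polyA/transcript boundary is
unambiguous and adapter trimming can be verified base-exact.

What the simulator does **not** model: homopolymer-biased or
signal-level Nanopore errors, PCR duplicates and chimera formation
rates, 3′ coverage decay, gene-dense overlapping loci, and realistic
expression dispersion. Passing tests therefore demonstrate the
correctness of the *rules* (scoring, thresholds, classification,
averaging), not field performance on real flow-cell data.

## Demultiplexing

Each barcode is scored against the first and last
`min(150, read length)` bases, both strands, with a semi-global
alignment (barcode global, free end gaps in the window) under
match +2 / mismatch −2 / gap open −3 / gap extend −1, via
`Bio.Align.PairwiseAligner`. An exact hit scores 48; each substitution
costs 4, so the assignment cutoff of 31 tolerates about four
substitutions on the 24-mer. The published protocol's demultiplexer
does not document its matrix; this scheme was chosen to preserve the
cutoff's semantics and both matrix and cutoff are configurable. Ties at
the maximum score are left unassigned (conservative; avoids cell
cross-talk). Reads shorter than the window use the whole read as both
windows. Read filters (mean qscore ≥ 7, length ≥ 100) and cell filters
(≥100,000 full-length reads, base mapping ratio ≥ 0.85, ≥3,000 detected
genes) are all strict less-than exclusions: the boundary value passes.
The qscore is the Phred of the mean per-base error probability, the
long-read convention.

Full-length identification requires the anchor (≤5 edits, edlib) near
both read ends with opposite orientations; the RT end is the one with a
≥15-base polyT/polyA run within barcode distance, the other end is the
TSO (the `ATGGG` tail is corroborating, not required). Reads with
internal anchor hits are reported chimeric and excluded, not split.
Orientation flips the read so the TSO end is 5′; anchors, `ATGGG`,
barcode and the maximal polyA run abutting it are trimmed; the
transcribed strand of the original read is recorded.

## Quantification

Reads are assigned to transcripts by junction compatibility with a
±5 bp tolerance per edge (absorbing splice-edge wobble; configurable).
Because the chemistry anchors every cDNA at the polyA end, the read's
junction chain must match the transcript chain at its **mRNA 3′
terminus**: a 5′-truncated read may lose junctions only from the 5′
side, and a mono-exon read must lie in a transcript's 3′-terminal exon.
This is stricter than containment-anywhere and prevents mono-exon
fragments of novel isoforms from being silently absorbed by their host
gene's annotated transcripts. Ambiguous reads split their unit weight
equally among candidates — a deliberate, transparent replacement for
EM-based quantification, exact on full-length reads. Expression is
reported as reads per 10,000 assigned reads per gene (RPG10k) and
transcript (RPT10k); per cell the RPG10k row sums to 10,000 by
construction. "Detected gene" means raw count > 0 (no expression floor
is prescribed for detection).

Region labels use the precedence exon > intron > intergenic over a
read's blocks, one label per read (primary alignments only). lncRNA
quantification re-applies the same assignment rules to intergenic reads
against a secondary annotation, normalized within the lncRNA
compartment. Saturation curves subsample assigned reads without
replacement at fixed depths (default 10 draws) and report mean detected
genes and isoforms.

## Novel-isoform discovery

Per cell: reads sharing a (chrom, strand, junction chain) cluster after
snapping each edge to the nearest annotated splice site within ±5 bp;
residual unannotated edges unify to the cluster median; mono-exon reads
cluster by ≥50% reciprocal overlap. Clusters whose splice sites and
exonic regions are all annotated need ≥2 reads, clusters touching novel
exonic space need ≥5 (boundary counts pass). Identical chains collapse
with pooled supports; a chain that is a 5′-truncated terminal run of a
longer chain merges into it. Models merge across cells by chain
identity (mono-exon: reciprocal overlap); terminal ends are medians.

Classification against the annotation:

- **known** — chain equals an annotated chain, or is a contiguous
  subchain with the model's terminal exons inside the matching
  transcript exons (a 5′ fragment is degradation, not discovery);
  mono-exon models matching an annotated mono-exon transcript by
  reciprocal overlap are also known.
- **IR** — a complete annotated intron of the host gene, with at least
  a base of each flanking exon, inside one model exon.
- **CJ** — every junction annotated in the host gene, but the
  combination matches no single transcript.
- **CS** — every donor and acceptor site annotated, but at least one
  pairing is novel.
- **ME** — mono-exon model inside one annotated exon of its host.
- **MIR** — mono-exon model spanning annotated exons plus their
  intervening intron(s).
- **intergenic** — no gene overlap at all.
- **discarded** — any unannotated splice site after snapping (raw
  long-read splice errors would otherwise dominate), and mono-exon
  models that overlap a gene without fitting ME or MIR.

Multi-exon precedence is IR > CJ > CS: retention is the most specific
structural event. The host gene is the same-strand gene with the
largest exonic base overlap (union over transcripts; ties break by gene
id). The test suite checks this decision tree against an independent
brute-force transcription of the definitions on 1,000 randomized toy
annotations.

Expression filters are applied per cell on RPT10k computed jointly over
known + novel transcripts: values below 0.1 are zeroed; a novel
transcript must account for ≥5% of its host gene's transcript
expression (the 5% share is evaluated per cell, the same scope as the
RPT10k floor); transcripts detected in ≥3 cells are retained.

## Allele-specific expression

The alternate strain genome substitutes the ALT allele at every SNP
(lengths preserved, coordinates comparable). Reads are genotyped at
covered SNPs by comparing the read base to both alleles; a third base
counts for neither. Correspondence between read and genome is colinear
within each alignment block (exact for simulator truth alignments and
for SAM blocks without internal indels); no base-quality weighting.
Assignment follows two rules after excluding reads covering <60% of the
host gene's shortest annotated spliced transcript (per-gene minimum;
coverage capped at 1): a single informative SNP decides the strain;
otherwise a strain needs at least twice the other's SNP count (and at
least one SNP). Per-cell × gene maternal/paternal counts are averaged
over the two reference mappings — counts first, fractions recomputed
from the averaged counts — cancelling reference bias. Assignment error
on pure-strain cells is wrongly-assigned / all-assigned informative
reads per strain.

## Problem sizes and numerics

The packaged scenarios run at desk scale, chosen to keep every stage's
behaviour measurable with tight statistics: demultiplexing on 48-cell,
10,000-read libraries (error-free and at 5% substitutions + 2%/2%
indels); quantification and lncRNA recovery on ~1,500–2,000 read
libraries over 6–8 genes; isoform rediscovery with ~15–20 supporting
reads per planted model in 4 cells; allelic recovery with ≥5,000
informative reads across maternal fractions {0, 0.25, 0.5, 0.75, 1}.
Monte-Carlo recoveries are asserted within 3 binomial standard
deviations. Floating-point identities (RPG10k row sums) are held to
1e-6. All tie-breaks (assignment ties, host-gene ties, cluster
ordering) are deterministic and documented above.

## Known limitations

- No EM or rescue step for multi-mapping reads; equal splitting biases
  shared-terminal-exon isoform estimates toward uniformity.
- The 3′-anchored compatibility rule assumes polyT-primed libraries; it
  is wrong for random-primed or 5′-capture chemistries.
- Chimeric reads are discarded, never split into constituent cDNAs.
- SNP genotyping ignores base qualities and indel-adjacent wobble.
- The barcode score scale is this package's own; cutoffs from other
  demultiplexers do not transfer without re-calibration.
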