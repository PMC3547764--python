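# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)`. GFF3 input
and output (1-based inclusive) are converted at the I/O boundary only.
Gene models carry the exon chain and strand; introns are derived as the
gaps between consecutive exons. The region partition (exonic / intronic /
intergenic) is strandless because the library model is non-strand-specific;
where genes overlap, a base that is exonic in any gene is labelled exonic
(assignment priority exon > intron > intergenic).

## Coverage and expression

Coverage counts every aligned base of every uniquely mapped read.
Uniqueness is read from the NH tag when present, otherwise from mapping
quality (≥ 1 by default); multi-mapped reads contribute nothing.

RPKM = C·10⁹/(N·L). Each mate counts as one read in both C and N — the
unit is reads, not fragments. A read is assigned to a gene when ≥ 50% of
its aligned bases fall in that gene's exons; among several qualifying
genes the largest overlap wins and exact ties assign the read to no gene.
This majority rule is deterministic and symmetric where genes overlap.

The transcriptional-activity cutoff takes the nearest-rank 5th percentile
of all gene RPKMs; genes strictly below it are inactive, so a fully tied
library keeps every gene active ("lowest 5%" read literally as a strict
filter). Quartile bins for active genes use nearest-rank 25th/75th
percentiles the same way: with 100 distinct active values, exactly 25 fall
in each outer bin. An alternative reading of the activity rule — a
confidence interval per gene rather than a library-wide percentile — is a
different procedure; this package implements the percentile reading.

## UTR calling

From each annotated gene end the caller walks outward base by base while
depth > 0. The UTR ends at the last covered base before the first
zero-depth break; a single zero-depth base is a break by default
(`break_run` raises the required run length — coverage dropouts in real
libraries may warrant 2–5, but 1 is the literal reading of a
zero-count break). A walk entering another gene's span before any break
marks that end `neighbor-overlap-excluded`; reaching the chromosome end
without a break marks it `no-break-discarded`. 5'/3' assignment follows
the gene's strand.

uORF rule set: every ATG in any frame inside the called 5'-UTR that
reaches an in-frame stop ending at or before the CDS start is a candidate;
candidates longer than 150 nt or starting more than 500 nt before the main
ATG are removed. Length includes the stop codon; distance is measured ATG
first base to main-ATG first base (neither convention is forced by the
rule set, so both are fixed here and in the tests). uORFs are required to
terminate at or before the main ATG; allowing overlap into the CDS is a
plausible alternative that would only add candidates. Nested or
overlapping uORFs in different frames are all reported.

uATG rule set: distance < 150 nt, distance divisible by 3 (in frame), and
no in-frame stop codon between the uATG and the main start. The screen
runs over the called UTR sequence only, so output is invariant to sequence
upstream of the screen window.

## Novel transcripts

TARs are maximal runs of intergenic bases at depth ≥ 2 and length strictly
greater than 35. A single below-threshold base splits a run (`max_gap`
can bridge dropouts; default 0). The search space is the intergenic
partition minus the called UTR intervals, so continuous UTR coverage
flanking a gene is not reported as an independent unit.

TARs become nodes of a graph with an edge wherever ≥ 3 read pairs have one
mate overlapping each TAR (≥ 1 base; same-TAR pairs make no self-edge;
mates must share a chromosome within the 10 kb insert bound). Connected
components are TUs. TU length is the summed member-TAR length, not the
genomic span, because the average-expression filter (≥ 2 reads per base)
is only meaningful over expressed bases; the span is reported alongside.
TUs shorter than 150 bases or below the depth filter are discarded.
ORFs in TU sequences are maximal ATG-to-stop spans in all six frames
(first ATG per stop), reported at ≥ 33 aa (~100 nt) by default.

New-exon candidates are TAR-like runs (depth ≥ 2, length > 35) strictly
inside an annotated intron whose two edges are each joined to a flanking
exon by a called junction. The dual-junction requirement is what separates
a new internal exon from partial retained-intron coverage; runs without
it are left to the retained-intron evidence stream. The thresholds are
configuration keys.

## Junction discovery

Donor sites are GT on the forward strand (AC read on the forward strand
for reverse-strand introns), acceptors AG (CT). Sites are enumerated
inside annotated introns (plus configurable slop) and must be touched by
unique-read coverage within one base of the dinucleotide — spliced-read
coverage ends at the exon boundary, one base short of the intronic
dinucleotide itself, so the support window includes the adjacent exonic
base.

All same-strand donor→acceptor pairs within 4 bases to 10 kb (the
paired-insert mapping bound) become candidates. The junction sequence is
the upstream exon flank plus the downstream exon flank, 70 bases each by
default (read length 75 minus the 5-base minimum overhang, so a
full-length read can overhang by exactly the minimum on one side).
Reverse-strand junction sequences are stored in forward-genome
orientation; reads are scanned in both orientations, which is equivalent
to building them in transcription order.

Unmapped reads are rescued by trimming one base at a time from the 3' end
and re-searching the genome (exact substring, both strands) until the
first hit, stopping below 40 retained bases. Exact search is sufficient
at synthetic scale; for real data, externally computed trimmed alignments
can stand in.

The aligner places each rescued read (and its reverse complement) on the
candidate set with ≤ 2 mismatches and ≥ 5 matched bases on each side of
the junction midpoint, using a pigeonhole seed index (a read with ≤ k
mismatches must contain an exact segment of length ⌊R/(k+1)⌋), which is
exactly equivalent to a brute-force Hamming scan and is verified against
one in the tests. A read whose best score ties across two or more
candidates is dropped as ambiguous. A junction is called from ≥ 2
unambiguous trans-reads with distinct start offsets ("different match
positions" = distinct offsets on the junction sequence).

## Alternative-splicing classification

Retained introns are called from coverage: every intron base at depth ≥ 2
and an intron mean depth of at least 0.25 × the mean depth of the two
flanking exons, with no called new-exon candidate occupying the intron.
The two numeric thresholds are this package's own calibration — an
intron retained in a minor isoform at ~25%+ of gene expression passes,
sporadic intronic noise does not — and both are configuration keys.

Junction-based typing is strand-aware (the donor is the 5' intron edge in
transcription order). Per gene:

* a junction matching an annotated intron is constitutive — no event, but
  it participates in alternative-site grouping;
* **SE**: a junction spanning ≥ 1 entire annotated internal exon (its
  inclusion is evidenced by the annotated flanking introns);
* **MXE**: two SE calls whose skipped exons are disjoint, whose introns
  overlap, and where neither junction spans the other's exon, merge into
  one event;
* **A5SS / A3SS**: junction groups sharing an acceptor (resp. donor) with
  ≥ 2 distinct donors (resp. acceptors); a group with d distinct
  alternative sites yields d − 1 events;
* **AFE / ALE**: within such a group, an alternative outer site lying
  beyond the outermost annotated exon reclassifies that variant as an
  alternative first (resp. last) exon.

Precedence prevents double counting of one signal: junctions bounding a
called new-exon candidate are excluded first, SE junctions do not also
enter alt-site groups, and MXE pairing consumes its two SE calls. The
operational definitions of MXE/AFE/ALE are junction-anchored
reconstructions of the standard typology; the summary reports
CE = SE + AFE + ALE + MXE, the ratio CE/(RI + CE), and the mean lengths of
retained versus non-retained annotated introns.

## Synthetic data

The generator emulates a deeply sequenced, non-strand-specific 75-bp
paired-end mRNA library from a compact gene-dense fungal genome. Defaults:
one 140 kb chromosome; 62 genes (4 single-exon, 4 constitutive multi-exon,
5 uORF hosts, 5 uATG hosts, 2 new-exon hosts, and 10 RI + 10 SE + 10 A5SS
+ 10 A3SS + 2 MXE event genes); introns Normal(99, 15) clipped at 60 bases
with retained introns drawn at mean 89; UTR lengths lognormal with medians
102 (5') and 85.5 (3'), clipped to [20, 300]; 5 single-block and 3
two-block intergenic transcripts plus one 140-bp unit the TU filters must
reject; alternative splice sites offset by 12 bases; new exons 120 bp
(deliberately longer than a read, so reads can map inside them).

Splice dinucleotides, start/stop codons, uORFs/uATGs and alternative sites
are planted on the coding strand (genes land on either strand). 5'-UTRs
of uORF/uATG host genes are scrubbed of spurious ATGs so their truth
tables are exact; other UTRs keep whatever upstream features arise by
chance, and recovery there is checked as a superset. Planted spacers use
C/G/T codons only, which can contain neither ATG nor a stop codon.

Fragments per isoform are a deterministic lattice (2 × read-length
fragments every 25 bases, plus junction-anchored and junction-straddling
fragments that guarantee coverage to every block edge, at least two
distinct-offset spanning reads in both orientations per junction, and at
least three linking pairs per two-block unit) topped up with random
fragments (Normal(180, 20) length) at ~4× extra depth. Mates are the
fragment's two 75-base ends; alternating fragments flip mate orientation,
emulating the non-strand-specific protocol. Reads crossing a splice
junction cannot map contiguously and are emitted into the unmapped set;
every other read is written to a true-placement SAM at MAPQ 60. The error
model is substitution-only (default rate 0) because the junction aligner
is mismatch-only; errors never move a read's true placement.

What the simulation does not model — and what passing tests therefore do
not show about real data: mapping ambiguity and multi-mapped reads,
indels, coverage dips from GC or positional bias, PCR duplicates,
antisense transcription, overlapping genes, and transcript ends blurred by
incomplete poly(A) selection. Real libraries need the `break_run`,
`max_gap` and depth thresholds reconsidered against their noise floor.
Alternative first/last exons place their defining splice sites outside
annotated introns, where the default site search does not look, so AFE/ALE
are exercised at the classifier level with junction fixtures rather than
end-to-end.

## Numerical and degenerate-input choices

Percentiles are nearest-rank (no interpolation); boundary ties survive
strict filters. CE/(RI+CE) is None when no RI or CE event exists.
Zero-length UTRs are `defined` with length 0. Empty expression input is an
error; a genome with no genes is a valid input whose whole length is
intergenic. Intron candidates require ≥ 4 bases (room for GT…AG).
Transcripts shorter than one read emit no reads. Problem sizes throughout
the test suite and acceptance script (tens of genes, ~140 kb genomes,
~10⁴ read pairs) are chosen so each property is measured on hundreds of
independent features while a full run stays in the tens of seconds.
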