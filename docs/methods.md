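# Methods

sdrkit re-implements, as a tested library, the bespoke computational steps
used to characterise a long-read plant genome assembly with separated
haplotypes and its sex-determining region (SDR): self-alignment multiplicity
QC, Y/X SDR haplotyping from marker hits, variant-allele-fraction (VAF)
profile clustering across a sample panel, and read-depth-anomaly repeat
discovery. Upstream steps (basecalling, assembly, polishing, read mapping,
variant calling, multiple alignment, ML trees) are out of scope: their
outputs — FASTA contigs, tabular alignment hits, multi-sample VCF, per-base
depth tracks — are this package's inputs.

## Coordinate and format conventions

All internal coordinates are 1-based inclusive, the convention of tabular
alignment hits and VCF; BED output (and bedgraph input) is the only 0-based
half-open surface. Alignment hits use the 12- or 13-column tabular dialect
(`qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore [gaps]`); minus strand is encoded by descending subject
coordinates and normalised on parse. The optional 13th column carries total
gapped columns; when absent, gap rates fall back to gap opens as a lower
bound, with a logged warning — the standard 12-column dialect simply does
not carry the quantity that gaps/kb needs.

## Self-coverage multiplicity and allele divergence

An assembly that retains both parental haplotypes aligns against itself
twice over its duplicated fraction. Hits are filtered with strict
thresholds — alignment length > 300 bp, identity > 75%, bitscore > 1000 —
and the multiplicity of a base is the number of filtered hits whose query
interval covers it, computed with a difference-array sweep (exact;
cross-checked against per-base counting in tests). The trivial diagonal
self-hit is included, so unique sequence has multiplicity 1 and duplicated
sequence 2; multiplicities ≥ 5 are pooled. Coverage is counted on query
coordinates only, because an all-vs-all self-alignment emits both reciprocal
directions; the partner's coverage arrives with the reciprocal record.
An uncovered fraction (f0) is reported even though it is 0 for any input
containing the diagonal hits, so the six fractions always partition 1.

Allele divergence (heterozygosity) is summarised over off-diagonal filtered
hits: mismatches/kb and gaps/kb are totals over summed alignment columns,
identity is the length-weighted mean. A diagonal hit is one with identical
query/subject ids and identical intervals on the plus strand; off-diagonal
intra-contig hits (internal repeats) do count, and a flag restricts the
summary to inter-contig records. Both reciprocal directions of a pair are
counted — each is a distinct record, and the ratio estimators are unaffected.
Whether the original analysis symmetrised coverage or restricted divergence
to 2x regions is not documented anywhere we could rely on; these defaults
are ours and are stated rather than asserted as the original choice.

## SDR localisation and Y/X haplotyping

Marker sequences (the ~120 kb SDR reference interval, the ARR17 gene and its
partial repeats, the HEMA fragment, MSL, the conserved LRR/MET1/CLC/TCP
genes, the ~5 kb Populus-specific repeat PSR) are aligned to the assembly;
fragmented hits of one marker on one contig and strand are chained when
their contig-coordinate gap is ≤ 20 kb (default). The chain gap tolerates
the long variable intergenic stretches inside the SDR. A contig is called
SDR-bearing when its best SDR cluster covers ≥ 50% of the SDR query; a
contig with two qualifying clusters is reported twice and flagged as a
possible chimera rather than merged.

The haplotype rule is the biological one: the Y haplotype carries partial
repeats of the sex-switch gene ARR17 (whose small RNAs silence ARR17 in
males), X haplotypes carry none. A located SDR is classified Y iff at least
one ARR17-repeat cluster overlaps the SDR interval extended by a 50 kb flank;
X otherwise; contigs without an SDR call are unclassified. Enlarging the
flank is monotone (can only turn X into Y). Inverted-repeat arms are
identified exactly as in the original procedure: an opposite-strand pair of
repeat clusters within 10 kb whose spacer contains a HEMA-fragment cluster.
For this step clusters must be chained with a small gap (200 bp in the CLI)
so individual repeat copies stay separate. MSL completeness is called from
merged query coverage: complete ≥ 0.9, partial otherwise, absent with no
filtered hits. The chaining gap, query-fraction, flank, span and
completeness thresholds are not documented in the original analysis; the
defaults here are exposed as configuration.

The packaged reference intervals are Chr19:15,907,431–15,910,397 (ARR17),
Chr18:16,290,253–16,308,089 (ARR17 partial-repeat locus) and
Chr18:16,200,000–16,320,000 (SDR) on the P. trichocarpa "Stettler 14"
assembly (where the SDR is assembled on chromosome 18).

## VAF-profile clustering

From a joint multi-sample VCF carrying per-sample DP/RO/AO (as produced by a
haplotype-based caller run at ploidy 4 with minimum coverage 5 and minimum
VAF 0.1), the VAF matrix holds AO/DP per (site, alt allele, sample); entries
with depth below 5 reads, or missing calls, are masked. Multi-allelic sites
expand to one row per alt — collapsing them is a defensible alternative, but
row-per-alt keeps every allele's signal and is the documented choice here.

Cross-sample distances are raw Euclidean with pairwise deletion: a site
enters a pair's sum only when unmasked in both samples. Distances are not
normalised by the shared-site count by default (an optional flag rescales by
sqrt(n_total/n_shared) for very unequal panels); with masking the matrix is
symmetric and nonnegative but not necessarily Euclidean. Clustering is
Ward's minimum-variance method on squared distances (ward.D2: the
Lance–Williams recurrence on d², heights reported as sqrt of merge cost —
scipy's "ward" linkage computes exactly this). Merge order on exact ties may
differ between implementations; partitions on generic data do not. The MDS
is classical (Torgerson) scaling — double-centre the squared distances,
eigendecompose, scale eigenvectors by sqrt of positive eigenvalues — since
the original analysis named only "MDS" and the R ecosystem default for
distance input is cmdscale-style classical scaling. Negative eigenvalues
(possible under masking) are dropped with a warning and coordinates
zero-padded if fewer than k positive eigenvalues exist.

## Depth-anomaly repeat discovery

The background of a depth track is its median depth — robust to the
high-coverage loci themselves, which is the point of using it; the original
analysis names no explicit enrichment statistic, so thresholding against the
median is this package's stand-in. Non-overlapping 100 bp windows with mean
depth ≥ 10× background are flagged; flagged runs separated by ≤ 500 bp merge;
merged loci shorter than 1 kb are dropped. Each locus is then re-tiled and
windows below 3× background labelled low, which splits a locus into
uniformly-high versus mosaic parts — a rule-based analogue of the two-part
structure visible in real coverage profiles; the published split point of
such a locus was likely chosen by inspection, so boundaries here agree only
at window resolution. Copy counting merges overlapping subject intervals of
filtered hits (≥ 1 bp overlap) per subject sequence and counts merged
intervals; it is invariant under hit order and hit splitting.

The ORF scanner reports, in each of six frames, the ORF from the
most-upstream ATG to the next in-frame stop (one ORF per stop per frame),
with codons containing N matching nothing, filtered to ≥ 100 residues by
default. Unlike TransDecoder it does not report 5′-partial ORFs (no ATG, no
report), so counts can differ from that tool on truncated sequences.
Proximity annotation is strand-aware: a locus is "upstream of ARR17" when it
lies 5′ of the gene start on the gene's strand with an intervening gap of
15–40 kb, and "adjacent to repeats" at a gap ≤ 10 kb.

## Synthetic data: what it emulates and what it does not

The generators produce inputs with the statistical structure each stage
assumes, plus ground truth, so the pipeline is testable without any
downloads. All randomness flows through one seeded generator per call; a
fixed seed gives byte-identical outputs.

* **Diploid assembly**: equal-length contigs; a `dup_fraction` of them
  (default 0.45) receive a second-haplotype partner carrying binomial
  substitutions (default 130/kb) and Poisson indel events with geometric
  lengths (mean 3 bp; default 31 gap columns/kb) — the heterozygosity regime
  of an intersectional poplar hybrid, where those rates imply ~83–84% allele
  identity. The self-alignment table is generated from the planted truth,
  not by running an aligner, so the coverage module is tested as interval
  arithmetic rather than via alignment heuristics (a naive exact-match
  verifier exists for ≤ 10 kb toys only).
* **SDR contigs**: ordered LRR–MET1–CLC–TCP blocks inside an SDR span; Y
  contigs add ARR17 partial repeats (two as an inverted pair flanking a HEMA
  block), a PSR copy, and fragmentary MSL homology. Marker sizes are scaled
  down (30 kb SDR block) to keep tests fast.
* **VAF panels**: per group, a profile of states from {0, ¼, ½, ¾, 1}
  (ploidy-4 calling); relative to the first group each other group redraws a
  site's state with probability `group_divergence/0.4` (0.4 being the
  expected |Δstate| of a redraw, so `group_divergence` is the expected
  |Δstate| between group profiles). Per sample/site: depth ~
  Poisson(mean 30), forced below 5 with probability 0.05 (dropout), AO ~
  Binomial(depth, state). The binomial/Poisson model is a minimal stand-in:
  no mapping bias, no base-quality structure, no linkage between sites.
* **Depth tracks**: constant background plus clipped Gaussian noise, with
  planted loci at background×fold (noise scaled by sqrt(fold) inside).

Passing the recovery tests therefore shows the interval arithmetic,
estimators and clustering recover planted structure under idealised noise;
it does not validate alignment sensitivity, caller artefacts, or repeat
families with internal structure — those enter through the real upstream
tools, not this package.

## Problem sizes and numerical choices

Recovery tests and the acceptance script use desk-scale problems chosen as
the smallest sizes at which the estimators' sampling noise is well inside
the stated tolerances: 300–400 kb genomes over 10–20 contigs (10 seeds) for
divergence and duplicated-fraction recovery; 100 SDR contigs (50 Y + 50 X)
for classification; 20 panels of 3×5 samples × 200 sites for clustering;
120 kb depth tracks for locus detection. Multiplicity fractions must
partition 1 to 1e−9; Ward heights are nondecreasing; classical MDS
reconstructs a full-rank Euclidean distance matrix to 1e−8; linkage
tie-breaks follow scipy's nearest-neighbour chain. Degenerate inputs raise:
zero-background tracks, pairs of samples with no shared unmasked sites
(policy flag switches to NaN propagation), DP=0 with AO>0, overlapping
bedgraph lines, negative depths.

## Known limitations

* Divergence statistics assume the aligner emitted both reciprocal
  directions of every allelic pair; one-directional tables bias nothing in
  the ratios but halve `total_allelic_aln_length`.
* The Y/X rule depends on repeat marker sensitivity upstream; a Y contig
  whose repeats were missed by the aligner is indistinguishable from X.
* Classical MDS under heavy masking can drop substantial negative eigenvalue
  mass; the captured-mass fraction is reported so users can judge.
* The ORF scanner is deliberately simpler than TransDecoder (no 5′-partial
  ORFs, no coding-potential score).
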