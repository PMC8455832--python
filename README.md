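# sdrkit

Diagnostics and analyses for long-read plant genome assemblies with
**separated haplotypes**, centred on the poplar **sex-determining region
(SDR)**. Built for genomicists who assemble heterozygous (often hybrid)
dioecious trees and need to answer, from standard intermediate files:

1. **Is my assembly haplotype-separated, and how diverged are the alleles?**
   Self-alignment hits (tabular, 12/13-column) are filtered (length > 300 bp,
   identity > 75%, bitscore > 1000) and turned into a *multiplicity profile*:
   the fraction of bases covered exactly 0,1,2,3,4,≥5 times, counting the
   trivial diagonal self-hit. A merged-haplotype genome is mostly 1×; a
   separated one mostly 2×. Heterozygosity is summarised over off-diagonal
   hits as mismatches/kb, gaps/kb and length-weighted identity.
2. **Which contigs carry the SDR, and is each haplotype Y or X?** Marker
   hits are chained into clusters; a contig is SDR-bearing when a cluster
   covers ≥ 50% of the SDR query. The class is **Y** iff ARR17
   partial-repeat clusters lie in the flanked SDR window, **X** otherwise —
   the partial repeats (two arranged as an inverted repeat flanking a HEMA
   gene fragment, found via that fragment) silence the sex switch *ARR17* in
   males. MSL completeness is called from query coverage.
3. **Do sample VAF profiles group by species/haplotype origin?** From a
   joint multi-sample VCF (ploidy-4 calling, per-sample DP/RO/AO), VAF =
   AO/DP per alt per sample, masking entries with DP < 5; cross-sample
   Euclidean distances use pairwise deletion; clustering is Ward.D2
   (Lance–Williams on d², heights on the distance scale) and the embedding
   is classical (Torgerson) MDS.
4. **Where are high-copy repeats?** Depth-track windows ≥ 10× the median
   background are merged into loci, segmented into uniformly-high vs mosaic
   parts, copy-counted across assemblies by merged alignment hits, scanned
   in six frames for ORFs ≥ 100 aa, and annotated for the diagnostic
   15–40 kb-upstream-of-*ARR17* placement.

A first-class synthetic-data module generates all inputs with planted ground
truth (duplicated-haplotype assemblies, Y/X SDR contigs, group-structured
VAF panels, depth tracks), so the whole pipeline runs and is tested without
any sequencing data.

## Worked example

```bash
python examples/self_coverage_qc.py
```

simulates a 300 kb assembly in which 45% of the haploid genome is present as
two haplotype copies diverging at 130 substitutions/kb and 31 gap
columns/kb, then runs the QC on its self-alignment table:

```
assembly: 14 contigs, 420066 bp
  fraction covered 0x: 0.000
  fraction covered 1x: 0.429
  fraction covered 2x: 0.571
  fraction covered 3x: 0.000
  ...
  mismatches/kb: 126.6
  gaps/kb:       30.8
  mean identity: 84.3%
```

The 2× fraction is the duplicated share of *emitted* bases
(2·0.45/1.45 ≈ 0.57 for a planted duplicated fraction of 0.45 of the
haploid genome), and the per-kb rates recover the planted heterozygosity.
`examples/sdr_haplotyping.py`, `examples/vaf_clustering.py` and
`examples/repeat_discovery.py` demonstrate the other three capabilities the
same way; each prints what it computed and what the numbers mean.

The same stages are available as a thin CLI:

```bash
sdrkit simulate --out fixture/ --seed 1
sdrkit selfcov  --alignments fixture/self_hits.tsv --fasta fixture/assembly.fa --out qc/
sdrkit sdr      --assembly fixture/sdr_contig_Y.fa --marker-hits fixture/marker_hits_Y.tsv \
                --marker-fasta fixture/markers.fa --out sdr/
sdrkit vafclust --vcf fixture/panel.vcf -k 3 --out clust/
sdrkit repeats  --depth fixture/depth.bedgraph --out repeats/
sdrkit all      --out run/ --seed 1
```

## Layout

```
src/sdrkit/
  io_formats.py     FASTA / tabular hits / VCF / bedgraph / BED / newick
  synthetic.py      generators with planted ground truth
  self_coverage.py  multiplicity profile + allele divergence
  sdr.py            marker chaining, SDR location, Y/X call, inverted repeats, MSL
  vaf.py            VAF matrix, masked distances, ward.D2, classical MDS
  repeats.py        depth-anomaly loci, segmentation, copy counts, ORFs
  cli.py            sdrkit {simulate,selfcov,sdr,vafclust,repeats,all}
docs/methods.md     models, parameters, numerical choices, limitations
examples/           one narrative script per capability
```
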