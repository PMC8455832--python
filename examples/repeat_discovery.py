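"""High-copy repeat discovery from a read-depth track, with ORF scanning.

Simulates a 120 kb region at 30x background with a 9.3 kb locus at 100-fold
coverage whose left half is mosaic (short low-coverage dips), detects and
segments the locus, counts planted repeat copies from alignment hits, and
scans a constructed repeat sequence for ORFs of >= 100 residues.
"""

import numpy as np

import sdrkit
from sdrkit.io_formats import AlignmentRecord, GenomicInterval, SequenceRecord
from sdrkit import synthetic as syn

# mosaic left half: three 200 bp dips; uniformly high right half
high_runs = [
    (80_033, 81_000, 100.0), (81_201, 82_500, 100.0),
    (82_701, 84_217, 100.0), (84_418, 89_302, 100.0),
]
track, _ = syn.gen_depth_track(120_001, 30.0, high_runs, noise_sd=3.0, seed=4)

(locus,) = sdrkit.detect_high_coverage_loci(track)
segments = sdrkit.segment_locus(track, locus)
print(f"locus {locus.interval.start}-{locus.interval.end} "
      f"({locus.interval.length / 1000:.1f} kb), mean fold {locus.mean_fold:.0f}")
for seg, label in segments:
    print(f"  {label:<5} {seg.start}-{seg.end} ({seg.length} bp)")

# copy counting: 40 planted copies of the locus in a mock assembly
hits = [
    AlignmentRecord(
        query_id="locus", subject_id="asm", pident=92.0, aln_len=1500,
        mismatches=120, gap_opens=5, q_start=1, q_end=1500,
        s_start=s, s_end=s + 1499, evalue=0.0, bitscore=2500.0, gaps=30,
    )
    for s in range(10_000, 10_000 + 40 * 4000, 4000)
]
print(f"copies in assembly: {sdrkit.count_copies(hits)}")

# ORF scan on a constructed repeat sequence with one planted transposase-size ORF
from Bio.Seq import Seq
spacer = "TTAA" * 60
orf = "ATG" + "GCT" * 314 + "TAA"  # 315 aa
seq = spacer + str(Seq(orf).reverse_complement()) + spacer
for o in sdrkit.find_orfs(SequenceRecord(id="repeat", seq=seq), min_aa=100):
    print(f"ORF: {o.start}-{o.end} strand {o.strand}, {o.aa_length} aa")

gene = GenomicInterval("asm", 200_000, 203_000, strand="+")
locus_iv = sdrkit.repeats.RepeatLocus(
    interval=GenomicInterval("asm", 170_000, 180_000), mean_fold=50.0)
(ann,) = sdrkit.annotate_proximity([locus_iv], arr17_gene=gene)
print(f"upstream of ARR17 (15-40 kb window): {ann['upstream_of_ARR17']} "
      f"(gap {ann['gap_to_ARR17']} bp)")
print(
    "\nThe detector recovers the planted locus at window resolution; the "
    "segmentation separates the uniformly high half from the mosaic half."
)
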