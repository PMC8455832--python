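"""High-copy repeat discovery from read-depth anomalies, with ORF scanning.

A repeat family collapsed in the reference but abundant in the sequenced
genomes shows up as a locus whose mapped read depth is many-fold above
background (up to ~100x for the Populus-specific repeat at the SDR border).
This module tiles a depth track into fixed windows, flags windows whose mean
depth exceeds ``fold_threshold`` times the background (median depth of the
track), merges flagged runs into loci, sub-segments each locus into
uniformly-high versus mosaic parts, counts repeat copies in assemblies by
merging alignment hits, scans all six reading frames for ORFs of a minimum
protein length, and annotates each locus's position relative to ARR17
features (the 15-40 kb upstream-of-ARR17 placement is the diagnostic one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .io_formats import AlignmentRecord, DepthTrack, GenomicInterval, SequenceRecord
from .self_coverage import FilterParams, filter_alignments

__all__ = [
    "RepeatScanParams",
    "RepeatLocus",
    "OrfRecord",
    "detect_high_coverage_loci",
    "segment_locus",
    "count_copies",
    "find_orfs",
    "annotate_proximity",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class RepeatScanParams:
    """Windowing and thresholding parameters for depth-anomaly detection.

    ``background`` defaults to the median depth of the analysed track (robust
    to the loci themselves). A window is flagged when its mean depth is at
    least ``fold_threshold`` times background; inside a locus, windows below
    ``low_fold`` times background are labelled low.
    """

    window: int = 100
    fold_threshold: float = 10.0
    merge_gap: int = 500
    min_locus_len: int = 1000
    low_fold: float = 3.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not self.fold_threshold > self.low_fold >= 1:
            raise ValueError("need fold_threshold > low_fold >= 1")


@dataclass
class RepeatLocus:
    """A detected high-coverage locus with its segmentation and copy counts."""

    interval: GenomicInterval
    mean_fold: float
    segments: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    copy_counts: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame from ATG through the next in-frame stop.

    Coordinates are 1-based inclusive on the forward strand and span ATG
    through the stop codon; ``aa_length`` excludes the stop.
    """

    seq_id: str
    strand: str
    frame: int
    start: int
    end: int
    aa_length: int

    def __post_init__(self) -> None:
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")


def _window_means(depths: np.ndarray, window: int) -> np.ndarray:
    n_win = len(depths) // window
    if n_win == 0:
        raise ValueError(f"track shorter than one {window} bp window")
    trimmed = depths[: n_win * window]
    return trimmed.reshape(n_win, window).mean(axis=1)


def detect_high_coverage_loci(
    track: DepthTrack,
    params: RepeatScanParams | None = None,
    background: float | None = None,
) -> list[RepeatLocus]:
    """Detect loci whose depth is >= ``fold_threshold`` x background.

    Non-overlapping ``window``-bp windows are tiled from base 1; flagged runs
    separated by gaps of at most ``merge_gap`` bp are merged, and merged loci
    shorter than ``min_locus_len`` are dropped. ``mean_fold`` is the locus
    mean depth over background.
    """
    params = params or RepeatScanParams()
    bg = float(np.median(track.depths)) if background is None else float(background)
    if bg <= 0:
        raise ValueError("background depth is zero; cannot compute folds")
    means = _window_means(track.depths, params.window)
    flagged = means >= params.fold_threshold * bg
    loci: list[RepeatLocus] = []
    runs: list[tuple[int, int]] = []  # window index ranges, inclusive
    start = None
    for i, f in enumerate(flagged):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flagged) - 1))
    # merge runs whose gap (in bp) is <= merge_gap
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and (s - merged[-1][1] - 1) * params.window <= params.merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    for s, e in merged:
        start_bp = s * params.window + 1
        end_bp = (e + 1) * params.window
        if end_bp - start_bp + 1 < params.min_locus_len:
            continue
        mean_depth = float(track.depths[start_bp - 1:end_bp].mean())
        loci.append(
            RepeatLocus(
                interval=GenomicInterval(track.seq_id, start_bp, end_bp),
                mean_fold=mean_depth / bg,
            )
        )
    return loci


def segment_locus(
    track: DepthTrack,
    locus: RepeatLocus,
    params: RepeatScanParams | None = None,
    background: float | None = None,
) -> list[tuple[GenomicInterval, str]]:
    """Split a locus into high and low segments at window resolution.

    Windows (re-tiled from the locus start) with mean depth below
    ``low_fold`` x background are low, others high; adjacent same-label
    windows merge. The segments partition the locus exactly (a ragged final
    window joins the last segment).
    """
    params = params or RepeatScanParams()
    bg = float(np.median(track.depths)) if background is None else float(background)
    iv = locus.interval
    sub = track.depths[iv.start - 1: iv.end]
    n_win = len(sub) // params.window
    labels = []
    for i in range(n_win):
        w = sub[i * params.window: (i + 1) * params.window]
        labels.append("low" if w.mean() < params.low_fold * bg else "high")
    tail = len(sub) - n_win * params.window
    if tail:
        lbl = "low" if sub[n_win * params.window:].mean() < params.low_fold * bg else "high"
        labels.append(lbl)
    segments: list[tuple[GenomicInterval, str]] = []
    seg_start = iv.start
    for i, lbl in enumerate(labels):
        end = min(iv.start + (i + 1) * params.window - 1, iv.end)
        if segments and segments[-1][1] == lbl:
            segments[-1] = (
                GenomicInterval(iv.seq_id, segments[-1][0].start, end), lbl)
        else:
            segments.append((GenomicInterval(iv.seq_id, seg_start, end), lbl))
        seg_start = end + 1
    locus.segments = segments
    return segments


def count_copies(
    hits: Iterable[AlignmentRecord],
    filter_params: FilterParams | None = None,
) -> int:
    """Count repeat copies in an assembly from locus-query alignment hits.

    Hits are filtered with the same thresholds as self-alignment QC, their
    subject intervals merged per subject sequence (any >= 1 bp overlap
    merges), and the merged intervals counted over all subjects. The count is
    invariant under hit order and under splitting a hit into overlapping
    sub-hits.
    """
    kept = filter_alignments(hits, filter_params or FilterParams())
    by_subject: dict[str, list[tuple[int, int]]] = {}
    for r in kept:
        by_subject.setdefault(r.subject_id, []).append((r.s_start, r.s_end))
    total = 0
    for ivs in by_subject.values():
        ivs.sort()
        cur_end = -1
        for s, e in ivs:
            if s > cur_end:
                total += 1
                cur_end = e
            else:
                cur_end = max(cur_end, e)
    return total


def _scan_frame(seq: str, offset: int) -> list[tuple[int, int]]:
    """ATG..stop spans (0-based nt, inclusive of stop) in one forward frame.

    One ORF per stop: the most-upstream ATG since the previous in-frame stop.
    Codons containing N never match ATG or a stop.
    """
    orfs = []
    atg_pos = None
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if "N" in codon:
            continue
        if codon in _STOPS:
            if atg_pos is not None:
                orfs.append((atg_pos, i + 2))
            atg_pos = None
        elif codon == "ATG" and atg_pos is None:
            atg_pos = i
    return orfs


def find_orfs(record: SequenceRecord, min_aa: int = 100) -> list[OrfRecord]:
    """Six-frame ORF scan reporting proteins of at least ``min_aa`` residues.

    An ORF runs from the most-upstream ATG to the next in-frame stop (one ORF
    per stop per frame); ORFs without a stop codon are not reported.
    Reverse-strand ORFs are reported in forward coordinates with strand '-'.
    """
    out: list[OrfRecord] = []
    n = len(record.seq)
    for strand, seq in (("+", record.seq), ("-", str(Seq(record.seq).reverse_complement()))):
        for frame in range(3):
            for s0, e0 in _scan_frame(seq, frame):
                aa = (e0 - s0 + 1) // 3 - 1
                if aa < min_aa:
                    continue
                if strand == "+":
                    start, end = s0 + 1, e0 + 1
                else:
                    start, end = n - e0, n - s0
                out.append(
                    OrfRecord(
                        seq_id=record.id, strand=strand, frame=frame,
                        start=start, end=end, aa_length=aa,
                    )
                )
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def annotate_proximity(
    loci: Sequence[RepeatLocus],
    arr17_gene: GenomicInterval | None = None,
    repeat_clusters: Sequence[GenomicInterval] = (),
    upstream_window: tuple[int, int] = (15_000, 40_000),
    adjacent_gap: int = 10_000,
) -> list[dict]:
    """Annotate each locus's placement relative to ARR17 features.

    ``upstream_of_ARR17`` is set when the locus lies 5' of the gene start on
    the gene's strand with a gap inside ``upstream_window`` (inclusive);
    ``adjacent_to_repeats`` when the gap to any ARR17 partial-repeat cluster
    is at most ``adjacent_gap``. Gaps are between closest interval ends; an
    overlapping feature has gap 0 and is never "upstream".
    """
    lo, hi = upstream_window
    annotations = []
    for locus in loci:
        iv = locus.interval
        entry = {
            "locus": iv,
            "upstream_of_ARR17": False,
            "gap_to_ARR17": None,
            "adjacent_to_repeats": False,
        }
        if arr17_gene is not None and arr17_gene.seq_id == iv.seq_id:
            if iv.overlaps(arr17_gene):
                gap = 0
                upstream = False
            elif iv.end < arr17_gene.start:
                gap = arr17_gene.start - iv.end - 1
                upstream = arr17_gene.strand != "-"
            else:
                gap = iv.start - arr17_gene.end - 1
                upstream = arr17_gene.strand == "-"
            entry["gap_to_ARR17"] = gap
            entry["upstream_of_ARR17"] = upstream and lo <= gap <= hi
        for feat in repeat_clusters:
            if feat.seq_id != iv.seq_id:
                continue
            if iv.overlaps(feat):
                gap = 0
            elif iv.end < feat.start:
                gap = feat.start - iv.end - 1
            else:
                gap = iv.start - feat.end - 1
            if gap <= adjacent_gap:
                entry["adjacent_to_repeats"] = True
                break
        annotations.append(entry)
    return annotations
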