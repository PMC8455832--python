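"""Synthetic inputs with the statistical structure each analysis stage assumes.

The generators emulate, at desk scale, the data situations the pipeline is
built for:

* a long-read diploid assembly in which a controllable fraction of the genome
  is represented by two separately assembled haplotypes whose alleles diverge
  at given per-kb substitution and gap rates (defaults 130 substitutions/kb
  and 31 gap columns/kb, the heterozygosity regime of an intersectional
  poplar hybrid);
* sex-determining-region (SDR) contigs carrying the conserved marker gene
  order LRR-MET1-CLC-TCP, where the Y haplotype additionally carries partial
  ARR17 repeats — two of them as an inverted pair flanking a HEMA gene
  fragment — and copies of the ~5 kb Populus-specific repeat (PSR);
* multi-sample VCFs whose variant-allele-fraction (VAF) profiles are
  group-structured with ploidy-4 states {0, 1/4, 1/2, 3/4, 1}, binomial read
  sampling at Poisson depth, and sub-5x dropout;
* per-base depth tracks with planted high-fold repeat loci (up to 100x
  background).

Alignment hit tables are generated from the planted truth rather than by
running an aligner, so downstream modules are tested as interval arithmetic,
not alignment heuristics. All randomness flows through one
numpy.random.Generator seeded from the params, so a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import AlignmentRecord, DepthTrack, GenomicInterval, SequenceRecord

__all__ = [
    "DiploidSimParams",
    "VafSimParams",
    "SimTruth",
    "gen_diploid_assembly",
    "gen_self_alignment_table",
    "gen_sdr_contigs",
    "gen_vaf_vcf",
    "gen_depth_track",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# ploidy-4 VAF states: 0..4 alt alleles out of 4
_VAF_STATES = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
# E|u - v| for two independent uniform draws from the five states;
# used to convert a target expected |delta state| into a redraw probability
_MEAN_ABS_STATE_DIFF = 0.4


@dataclass(frozen=True)
class DiploidSimParams:
    """Parameters of the duplicated-haplotype assembly simulator.

    ``dup_fraction`` is the fraction of the (haploid) genome present as two
    haplotype copies; ``mismatch_rate``/``indel_rate`` are substitutions and
    gap columns per kb between alleles; indel event lengths are geometric
    with mean ``indel_len_mean``.
    """

    genome_size: int = 2_000_000
    n_contigs: int = 20
    dup_fraction: float = 0.45
    mismatch_rate: float = 130.0
    indel_rate: float = 31.0
    indel_len_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dup_fraction <= 1.0:
            raise ValueError("dup_fraction must be in [0,1]")
        if self.mismatch_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.genome_size < self.n_contigs:
            raise ValueError(
                f"genome_size {self.genome_size} too small for "
                f"{self.n_contigs} contigs"
            )


@dataclass(frozen=True)
class VafSimParams:
    """Parameters of the group-structured VAF panel simulator."""

    n_groups: int = 3
    samples_per_group: int = 5
    n_sites: int = 200
    group_divergence: float = 0.25
    mean_depth: float = 30.0
    dropout_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_groups, self.samples_per_group, self.n_sites) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0,1]")
        if self.group_divergence < 0:
            raise ValueError("group_divergence must be >= 0")


@dataclass
class AllelicPair:
    """One planted haplotype pair with its realized edit statistics."""

    id_a: str
    id_b: str
    len_a: int
    len_b: int
    mismatches: int
    gap_columns: int
    aln_columns: int

    @property
    def pident(self) -> float:
        matches = self.aln_columns - self.mismatches - self.gap_columns
        return 100.0 * matches / self.aln_columns


@dataclass
class SimTruth:
    """Ground truth emitted alongside each synthetic dataset."""

    contig_lengths: dict[str, int] = field(default_factory=dict)
    allelic_pairs: list[AllelicPair] = field(default_factory=list)
    marker_intervals: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    marker_lengths: dict[str, int] = field(default_factory=dict)
    sample_labels: list[int] = field(default_factory=list)
    repeat_loci: list[tuple[int, int, float]] = field(default_factory=list)
    haplotype: str | None = None


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _mutate(
    rng: np.random.Generator,
    seq: np.ndarray,
    mismatch_rate: float,
    indel_rate: float,
    indel_len_mean: float,
) -> tuple[np.ndarray, int, int, int]:
    """Derive an allelic copy; returns (seq, mismatches, gap_columns, aln_columns).

    Indels are applied first (event count Poisson, lengths geometric), then
    substitutions at distinct positions of the derived sequence, so every
    planted edit is exactly one mismatch or gap column in the implied
    alignment.
    """
    n = len(seq)
    n_events = rng.poisson(n * indel_rate / 1000.0 / indel_len_mean)
    gap_columns = 0
    insertions = 0
    if n_events > 0:
        positions = np.sort(rng.choice(n, size=min(n_events, n), replace=False))
        lengths = rng.geometric(1.0 / indel_len_mean, size=len(positions))
        is_ins = rng.random(len(positions)) < 0.5
        pieces = []
        cursor = 0
        for pos, ln, ins in zip(positions, lengths, is_ins):
            if pos < cursor:
                continue  # event swallowed by a previous deletion
            if ins:
                pieces.append(seq[cursor:pos])
                pieces.append(_random_seq(rng, int(ln)))
                cursor = pos
                insertions += int(ln)
                gap_columns += int(ln)
            else:
                ln = int(min(ln, n - pos))
                pieces.append(seq[cursor:pos])
                cursor = pos + ln
                gap_columns += ln
        pieces.append(seq[cursor:])
        out = np.concatenate(pieces)
    else:
        out = seq.copy()
    m = len(out)
    n_sub = rng.binomial(m, min(mismatch_rate / 1000.0, 1.0)) if m else 0
    if n_sub:
        pos = rng.choice(m, size=n_sub, replace=False)
        shift = rng.integers(1, 4, size=n_sub)
        idx = np.searchsorted(_BASES, out[pos])
        out[pos] = _BASES[(idx + shift) % 4]
    aln_columns = n + insertions
    return out, int(n_sub), int(gap_columns), int(aln_columns)


def gen_diploid_assembly(
    params: DiploidSimParams,
) -> tuple[list[SequenceRecord], SimTruth]:
    """Simulate an assembly in which part of the genome keeps both haplotypes.

    The haploid genome is split into ``n_contigs`` equal contigs;
    ``round(dup_fraction * n_contigs)`` of them receive a second-haplotype
    partner contig carrying substitutions and indels at the planted per-kb
    rates. Total emitted length is therefore ~ genome_size * (1 + dup_fraction).
    """
    rng = np.random.default_rng(params.seed)
    contig_len = params.genome_size // params.n_contigs
    n_dup = round(params.dup_fraction * params.n_contigs)
    records: list[SequenceRecord] = []
    truth = SimTruth()
    for i in range(params.n_contigs):
        name = f"ctg{i:04d}"
        seq = _random_seq(rng, contig_len)
        records.append(SequenceRecord(id=name, seq=_to_str(seq)))
        truth.contig_lengths[name] = contig_len
        if i < n_dup:
            alt_name = f"ctg{i:04d}_hap2"
            alt, mm, gaps, cols = _mutate(
                rng, seq, params.mismatch_rate, params.indel_rate,
                params.indel_len_mean,
            )
            records.append(SequenceRecord(id=alt_name, seq=_to_str(alt)))
            truth.contig_lengths[alt_name] = len(alt)
            truth.allelic_pairs.append(
                AllelicPair(
                    id_a=name, id_b=alt_name, len_a=contig_len, len_b=len(alt),
                    mismatches=mm, gap_columns=gaps, aln_columns=cols,
                )
            )
    return records, truth


def _pair_record(
    pair: AllelicPair, forward: bool
) -> AlignmentRecord:
    qid, sid = (pair.id_a, pair.id_b) if forward else (pair.id_b, pair.id_a)
    qlen, slen = (pair.len_a, pair.len_b) if forward else (pair.len_b, pair.len_a)
    return AlignmentRecord(
        query_id=qid, subject_id=sid, pident=round(pair.pident, 3),
        aln_len=pair.aln_columns, mismatches=pair.mismatches,
        gap_opens=max(1, pair.gap_columns // 3) if pair.gap_columns else 0,
        q_start=1, q_end=qlen, s_start=1, s_end=slen,
        evalue=0.0, bitscore=2.0 * pair.aln_columns, strand="+",
        gaps=pair.gap_columns,
    )


def gen_self_alignment_table(truth: SimTruth) -> list[AlignmentRecord]:
    """Emit the hit table an all-vs-all self-alignment of the simulated
    assembly would produce: the trivial full-length diagonal self-hit for
    every contig plus both reciprocal directions of each allelic pair."""
    records: list[AlignmentRecord] = []
    for name, length in truth.contig_lengths.items():
        records.append(
            AlignmentRecord(
                query_id=name, subject_id=name, pident=100.0, aln_len=length,
                mismatches=0, gap_opens=0, q_start=1, q_end=length,
                s_start=1, s_end=length, evalue=0.0, bitscore=2.0 * length,
                strand="+", gaps=0,
            )
        )
    for pair in truth.allelic_pairs:
        records.append(_pair_record(pair, forward=True))
        records.append(_pair_record(pair, forward=False))
    return records


def naive_allelic_check(a: str, b: str, max_len: int = 10_000) -> bool:
    """Exact-match verifier for edit-free toy pairs (<= 10 kb only)."""
    if max(len(a), len(b)) > max_len:
        raise ValueError("naive verifier is restricted to sequences <= 10 kb")
    return a == b


# ---------------------------------------------------------------------------
# SDR contigs

_MARKER_LENGTHS = {
    "SDR": 30_000,
    "ARR17": 3_000,
    "ARR17_repeat": 1_200,
    "HEMA": 800,
    "MSL": 2_500,
    "TCP": 2_000,
    "CLC": 2_000,
    "MET1": 2_000,
    "LRR": 2_000,
    "PSR": 5_000,
}


def _marker_hit(
    marker: str, contig: str, start: int, strand: str,
    q_start: int | None = None, q_end: int | None = None,
    s_end: int | None = None, pident: float = 98.0,
) -> AlignmentRecord:
    qlen = _MARKER_LENGTHS[marker]
    q_start = q_start or 1
    q_end = q_end or qlen
    if s_end is None:
        s_end = start + (q_end - q_start)
    # query and subject spans may differ (indel-containing alignment);
    # alignment columns are at least the longer span
    span = max(q_end - q_start + 1, s_end - start + 1)
    return AlignmentRecord(
        query_id=marker, subject_id=contig, pident=pident, aln_len=span,
        mismatches=int(span * (100 - pident) / 100), gap_opens=0,
        q_start=q_start, q_end=q_end, s_start=start, s_end=s_end,
        evalue=0.0, bitscore=2.0 * span, strand=strand, gaps=0,
    )


def gen_sdr_contigs(
    haplotype: str, seed: int = 0, contig_id: str | None = None
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[AlignmentRecord], SimTruth]:
    """Simulate one SDR-bearing contig with its marker hits.

    The contig carries the ordered marker blocks LRR-MET1-CLC-TCP inside an
    SDR span; for ``haplotype == "Y"`` it additionally carries ARR17 partial
    repeats (two of them as an inverted pair with a HEMA fragment between the
    arms), PSR copies, and only fragmentary MSL homology. The SDR marker hit
    is emitted fragmented into three chained chunks to exercise hit chaining.

    Returns (contig records, marker records, marker-hit alignment records,
    truth with all planted intervals).
    """
    if haplotype not in ("Y", "X"):
        raise ValueError("haplotype must be 'Y' or 'X'")
    rng = np.random.default_rng(seed)
    name = contig_id or f"tig_{haplotype}_{seed:05d}"
    truth = SimTruth(haplotype=haplotype)
    truth.marker_lengths = dict(_MARKER_LENGTHS)
    placed: list[tuple[str, int, int, str]] = []  # (marker, start, end, strand)

    prefix = int(rng.integers(5_000, 15_000))
    sdr_start = prefix + 1
    cursor = sdr_start
    # conserved gene order shared by Y and X haplotypes
    for marker in ("LRR", "MET1", "CLC", "TCP"):
        cursor += int(rng.integers(500, 2_000))
        ln = _MARKER_LENGTHS[marker]
        placed.append((marker, cursor, cursor + ln - 1, "+"))
        cursor += ln
    if haplotype == "Y":
        # inverted ARR17 partial-repeat pair flanking a HEMA fragment
        cursor += int(rng.integers(1_000, 3_000))
        ln_r = _MARKER_LENGTHS["ARR17_repeat"]
        left = cursor
        placed.append(("ARR17_repeat", left, left + ln_r - 1, "+"))
        cursor = left + ln_r + int(rng.integers(200, 600))
        ln_h = _MARKER_LENGTHS["HEMA"]
        placed.append(("HEMA", cursor, cursor + ln_h - 1, "+"))
        cursor += ln_h + int(rng.integers(200, 600))
        placed.append(("ARR17_repeat", cursor, cursor + ln_r - 1, "-"))
        cursor += ln_r
        # extra (non-inverted) partial repeats and a PSR copy
        for _ in range(int(rng.integers(1, 4))):
            cursor += int(rng.integers(500, 2_000))
            placed.append(("ARR17_repeat", cursor, cursor + ln_r - 1, "+"))
            cursor += ln_r
        cursor += int(rng.integers(500, 2_000))
        ln_p = _MARKER_LENGTHS["PSR"]
        placed.append(("PSR", cursor, cursor + ln_p - 1, "+"))
        cursor += ln_p
    sdr_end = cursor + int(rng.integers(500, 2_000))
    contig_len = sdr_end + int(rng.integers(5_000, 15_000))
    contig_seq = _to_str(_random_seq(rng, contig_len))

    hits: list[AlignmentRecord] = []
    # fragmented SDR hit: three chunks covering ~80% of the SDR query
    sdr_len = _MARKER_LENGTHS["SDR"]
    span = sdr_end - sdr_start + 1
    bounds = [0.0, 0.3, 0.62, 1.0]
    for lo, hi in zip(bounds, bounds[1:]):
        s0 = sdr_start + int(lo * span)
        s1 = sdr_start + int(hi * span) - int(rng.integers(50, 200))
        q0 = 1 + int(lo * (sdr_len - 1))
        q1 = 1 + int(hi * (sdr_len - 1)) - int(rng.integers(20, 80))
        hits.append(_marker_hit("SDR", name, s0, "+", q_start=q0, q_end=q1, s_end=s1))
    for marker, start, end, strand in placed:
        hits.append(_marker_hit(marker, name, start, strand))
        truth.marker_intervals.setdefault(name, []).append(
            GenomicInterval(seq_id=name, start=start, end=end, strand=strand)
        )
    truth.marker_intervals.setdefault(name, []).append(
        GenomicInterval(seq_id=name, start=sdr_start, end=sdr_end, strand="+")
    )
    if haplotype == "Y":
        # fragmentary MSL homology only: one short high-identity hit
        msl_len = _MARKER_LENGTHS["MSL"]
        frag = int(0.3 * msl_len)
        pos = sdr_start + int(rng.integers(0, span - frag))
        hits.append(_marker_hit("MSL", name, pos, "+", q_start=1, q_end=frag))
    truth.contig_lengths[name] = contig_len

    contigs = [SequenceRecord(id=name, seq=contig_seq)]
    markers = [
        SequenceRecord(id=m, seq=_to_str(_random_seq(rng, ln)))
        for m, ln in _MARKER_LENGTHS.items()
    ]
    return contigs, markers, hits, truth


# ---------------------------------------------------------------------------
# VAF panels


def gen_vaf_vcf(params: VafSimParams, path: str | None = None):
    """Simulate a group-structured multi-sample VCF of ploidy-4 VAF profiles.

    Each group has a profile of VAF states drawn from {0, 1/4, 1/2, 3/4, 1};
    relative to the first group's profile, each other group redraws a site's
    state with probability ``group_divergence / 0.4`` (0.4 is the expected
    |state difference| of an independent redraw, so the expected |delta|
    between group profiles equals ``group_divergence``). Per sample and site,
    depth ~ Poisson(mean_depth), forced below 5 with probability
    ``dropout_prob``, and alt observations ~ Binomial(depth, state).

    Returns (vcf text, sample ids, group labels); writes the text to ``path``
    when given.
    """
    rng = np.random.default_rng(params.seed)
    base = rng.choice(_VAF_STATES, size=params.n_sites)
    redraw_p = min(params.group_divergence / _MEAN_ABS_STATE_DIFF, 1.0)
    profiles = [base]
    for _ in range(1, params.n_groups):
        prof = base.copy()
        redraw = rng.random(params.n_sites) < redraw_p
        prof[redraw] = rng.choice(_VAF_STATES, size=int(redraw.sum()))
        profiles.append(prof)

    sample_ids = [
        f"g{g}_s{s}"
        for g in range(params.n_groups)
        for s in range(params.samples_per_group)
    ]
    labels = [g for g in range(params.n_groups) for _ in range(params.samples_per_group)]

    lines = [
        "##fileformat=VCFv4.2",
        '##contig=<ID=regionA,length=%d>' % (params.n_sites + 1),
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference observations">',
        '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate observations">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    for j in range(params.n_sites):
        calls = []
        for g in range(params.n_groups):
            state = profiles[g][j]
            for _ in range(params.samples_per_group):
                depth = int(rng.poisson(params.mean_depth))
                if rng.random() < params.dropout_prob:
                    depth = int(rng.integers(0, 5))
                ao = int(rng.binomial(depth, state)) if depth else 0
                calls.append(f"./.:{depth}:{depth - ao}:{ao}")
        lines.append(
            f"regionA\t{j + 1}\t.\tA\tC\t.\t.\t.\tGT:DP:RO:AO\t" + "\t".join(calls)
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text, sample_ids, labels


# ---------------------------------------------------------------------------
# Depth tracks


def gen_depth_track(
    length: int,
    background: float,
    loci: Sequence[tuple[int, int, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    seq_id: str = "region",
) -> tuple[DepthTrack, SimTruth]:
    """Simulate a per-base depth track with planted high-fold loci.

    Depth is ``background`` plus clipped Gaussian noise outside the planted
    loci and ``background * fold`` inside. Loci are (start, end, fold),
    1-based inclusive, and may not overlap.
    """
    loci = sorted(loci)
    prev_end = 0
    for start, end, fold in loci:
        if not 1 <= start <= end <= length:
            raise ValueError(f"locus ({start},{end}) outside [1,{length}]")
        if start <= prev_end:
            raise ValueError("planted loci overlap")
        prev_end = end
    rng = np.random.default_rng(seed)
    depths = np.full(length, float(background))
    if noise_sd > 0:
        depths += rng.normal(0.0, noise_sd, size=length)
    for start, end, fold in loci:
        depths[start - 1:end] = background * fold
        if noise_sd > 0:
            depths[start - 1:end] += rng.normal(
                0.0, noise_sd * np.sqrt(fold), size=end - start + 1
            )
    np.clip(depths, 0.0, None, out=depths)
    truth = SimTruth(repeat_loci=[(s, e, f) for s, e, f in loci])
    return DepthTrack(seq_id=seq_id, depths=depths), truth
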