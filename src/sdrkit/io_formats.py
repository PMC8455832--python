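"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 1-based inclusive, matching the conventions of
tabular alignment hits and VCF. BED (and bedgraph on input) is the only
0-based half-open surface. Minus strand in alignment hits is encoded, as the
tabular dialect does, by subject coordinates printed in descending order; on
parse the subject interval is normalised to ascending order and the strand
recorded explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

_IUPAC_STRICT = set("ACGTN")

__all__ = [
    "SequenceRecord",
    "AlignmentRecord",
    "VcfSite",
    "GenomicInterval",
    "DepthTrack",
    "read_fasta",
    "write_fasta",
    "parse_alignment_table",
    "write_alignment_table",
    "parse_sample_vcf",
    "read_depth_track",
    "write_bed",
    "read_bed",
    "write_newick",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (assembly contig or marker reference)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a non-empty token, got {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise local-alignment hit (tabular blastn-style dialect).

    Coordinates are 1-based inclusive. ``s_start <= s_end`` always holds after
    parsing; a hit whose subject coordinates were printed in descending order
    carries ``strand == "-"``. ``gaps`` is the total number of gapped columns;
    -1 means the 12-column dialect was read and only ``gap_opens`` is known.
    """

    query_id: str
    subject_id: str
    pident: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    strand: str = "+"
    gaps: int = -1

    def __post_init__(self) -> None:
        if self.q_start < 1 or self.q_end < self.q_start:
            raise ValueError(
                f"bad query interval [{self.q_start},{self.q_end}] for "
                f"{self.query_id} vs {self.subject_id}"
            )
        if self.s_start < 1 or self.s_end < self.s_start:
            raise ValueError(
                f"bad subject interval [{self.s_start},{self.s_end}] for "
                f"{self.query_id} vs {self.subject_id}"
            )
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident {self.pident} outside [0,100]")
        if self.evalue < 0:
            raise ValueError(f"negative evalue {self.evalue}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def is_diagonal(self) -> bool:
        """True for the trivial full-identity self-hit of a sequence onto itself."""
        return (
            self.query_id == self.subject_id
            and self.strand == "+"
            and self.q_start == self.s_start
            and self.q_end == self.s_end
        )


@dataclass
class VcfSite:
    """One VCF record with per-sample depth and allele-observation counts.

    ``dp``/``ro`` are per-sample arrays; ``ao[i]`` is the list of alt-allele
    observation counts for sample i (one entry per alt). ``missing[i]`` is True
    when the sample has no call at this site.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    dp: list[int]
    ro: list[int]
    ao: list[list[int]]
    missing: list[bool]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for i, (m, a) in enumerate(zip(self.missing, self.ao)):
            if not m and len(a) != len(self.alts):
                raise ValueError(
                    f"sample {i} at {self.chrom}:{self.pos} has {len(a)} AO values "
                    f"for {len(self.alts)} alt alleles"
                )


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in "+-.":
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, seq_id: str, pos: int) -> bool:
        return seq_id == self.seq_id and self.start <= pos <= self.end


@dataclass
class DepthTrack:
    """Per-base read depth for one sequence, 1-based addressing.

    ``depths[i]`` is the depth at base i+1.
    """

    seq_id: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 1:
            raise ValueError("depths must be one-dimensional")
        if np.any(self.depths < 0):
            raise ValueError(f"negative depth in track for {self.seq_id}")

    @property
    def length(self) -> int:
        return int(self.depths.shape[0])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, permissive: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, uppercasing sequence.

    Characters outside {A,C,G,T,N} raise an error naming the offending
    position, unless ``permissive`` is set, in which case they are mapped to N
    with a logged warning.
    """
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = [i for i, c in enumerate(seq) if c not in _IUPAC_STRICT]
        if bad:
            if permissive:
                logger.warning(
                    "%s: %d non-ACGTN characters mapped to N (first at position %d)",
                    rec.id, len(bad), bad[0] + 1,
                )
                seq = "".join(c if c in _IUPAC_STRICT else "N" for c in seq)
            else:
                raise ValueError(
                    f"non-ACGTN character {seq[bad[0]]!r} in sequence {rec.id} "
                    f"at position {bad[0] + 1}"
                )
        seen[rec.id] = seen.get(rec.id, 0) + 1
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ValueError(f"duplicate sequence ids in {path}: {', '.join(dupes)}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 80) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Tabular alignment hits (qseqid sseqid pident length mismatch gapopen
# qstart qend sstart send evalue bitscore [gaps])


def parse_alignment_table(path: str | Path) -> list[AlignmentRecord]:
    """Parse a 12- or 13-column tabular local-alignment hit file.

    The 13th column, when present, is the total number of gapped columns.
    Subject coordinates printed in descending order encode the minus strand
    and are normalised to ascending order.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 13 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                aln_len = int(fields[3])
                mismatches = int(fields[4])
                gap_opens = int(fields[5])
                q_start, q_end = int(fields[6]), int(fields[7])
                s_start, s_end = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
                gaps = int(fields[12]) if len(fields) == 13 else -1
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            strand = "+"
            if s_start > s_end:
                strand = "-"
                s_start, s_end = s_end, s_start
            records.append(
                AlignmentRecord(
                    query_id=fields[0], subject_id=fields[1], pident=pident,
                    aln_len=aln_len, mismatches=mismatches, gap_opens=gap_opens,
                    q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
                    evalue=evalue, bitscore=bitscore, strand=strand, gaps=gaps,
                )
            )
    return records


def write_alignment_table(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Write records in the 13-column dialect (round-trips with the parser)."""
    with open(path, "w") as fh:
        for r in records:
            s1, s2 = (r.s_end, r.s_start) if r.strand == "-" else (r.s_start, r.s_end)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id, r.subject_id, f"{r.pident:.3f}", r.aln_len,
                        r.mismatches, r.gap_opens, r.q_start, r.q_end, s1, s2,
                        f"{r.evalue:.2g}", f"{r.bitscore:.1f}", r.gaps,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF


def parse_sample_vcf(
    path: str | Path,
    regions: Sequence[GenomicInterval] | None = None,
) -> tuple[list[str], list[VcfSite]]:
    """Read a multi-sample VCF with per-sample DP/RO/AO fields.

    Only sites overlapping ``regions`` are kept (all sites when None).
    Multi-allelic sites are kept intact; AO carries one count per alt.
    """
    import pysam

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from None
    for key in ("DP", "RO", "AO"):
        if key not in vcf.header.formats:
            raise ValueError(f"VCF {path} lacks required per-sample FORMAT key {key}")
    samples = list(vcf.header.samples)
    sites: list[VcfSite] = []
    for rec in vcf:
        if regions is not None and not any(
            iv.contains(rec.chrom, rec.pos) for iv in regions
        ):
            continue
        alts = tuple(rec.alts or ())
        dp, ro, ao, missing = [], [], [], []
        for s in samples:
            call = rec.samples[s]
            d = call.get("DP")
            r = call.get("RO")
            a = call.get("AO")
            if d is None or a is None or all(x is None for x in np.atleast_1d(a)):
                dp.append(0)
                ro.append(0)
                ao.append([])
                missing.append(True)
            else:
                dp.append(int(d))
                ro.append(int(r) if r is not None else 0)
                avals = [int(x) for x in (a if isinstance(a, tuple) else (a,))]
                ao.append(avals)
                missing.append(False)
        sites.append(
            VcfSite(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref or "N", alts=alts,
                dp=dp, ro=ro, ao=ao, missing=missing,
            )
        )
    return samples, sites


# ---------------------------------------------------------------------------
# Depth tracks, BED, newick


def read_depth_track(path: str | Path) -> DepthTrack:
    """Read a per-base depth track from bedgraph or 3-column depth TSV.

    Bedgraph lines are 0-based half-open ``seq start end depth``; depth TSV
    lines are 1-based ``seq pos depth`` (the samtools-depth convention). The
    two are distinguished by column count. Returns a dense 1-based array over
    [1, max covered position]; uncovered bases are 0.
    """
    seq_id = None
    entries: list[tuple[int, int, float]] = []  # 1-based inclusive
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) == 4:
                sid, start0, end0, depth = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                start, end = start0 + 1, int(end0)
            elif len(fields) == 3:
                sid, pos, depth = fields[0], int(fields[1]), float(fields[2])
                start = end = pos
            else:
                raise ValueError(f"{path}:{lineno}: expected 3 or 4 columns")
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth {depth}")
            if seq_id is None:
                seq_id = sid
            elif sid != seq_id:
                raise ValueError(
                    f"{path}:{lineno}: track mixes sequences {seq_id!r} and {sid!r}"
                )
            entries.append((start, end, depth))
    if seq_id is None:
        raise ValueError(f"empty depth track {path}")
    entries.sort()
    length = max(e for _, e, _ in entries)
    depths = np.zeros(length, dtype=float)
    prev_end = 0
    for start, end, depth in entries:
        if start <= prev_end:
            raise ValueError(
                f"overlapping depth entries in {path} near position {start}"
            )
        depths[start - 1:end] = depth
        prev_end = end
    return DepthTrack(seq_id=seq_id, depths=depths)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None) -> None:
    """Write intervals as BED (0-based half-open)."""
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.seq_id, str(iv.start - 1), str(iv.end)]
            if names is not None or scores is not None or iv.strand != ".":
                cols.append(names[i] if names is not None else ".")
                cols.append(str(scores[i]) if scores is not None else "0")
                cols.append(iv.strand if iv.strand != "." else ".")
            fh.write("\t".join(cols) + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 else "."
            intervals.append(
                GenomicInterval(seq_id=f[0], start=int(f[1]) + 1, end=int(f[2]),
                                strand=strand)
            )
    return intervals


def write_newick(newick: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip() + "\n")
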