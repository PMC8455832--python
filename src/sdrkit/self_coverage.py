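"""Haplotype-separation diagnostics from genome self-alignment hits.

A genome assembled with both parental haplotypes kept as separate contigs
aligns against itself twice over its duplicated fraction: every base is
covered once by the trivial diagonal self-hit and once by the hit onto its
allelic partner. The multiplicity profile (fraction of bases covered exactly
0, 1, 2, 3, 4 or >=5 times by filtered hits, diagonal included) therefore
separates haplotype-merged assemblies (mostly 1x) from haplotype-separated
ones (mostly 2x). Allele divergence (heterozygosity) is summarised from the
same hits as mismatches/kb, gaps/kb and length-weighted mean identity over
off-diagonal alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FilterParams",
    "MultiplicityProfile",
    "DivergenceSummary",
    "filter_alignments",
    "multiplicity_profile",
    "allelic_divergence",
    "genome_summary",
    "fold_coverage",
]


def fold_coverage(total_sequenced_bases: float, genome_size: float) -> float:
    """Sequencing fold coverage: total sequenced bases over genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return total_sequenced_bases / genome_size

_MULT_KEYS = ("f0", "f1", "f2", "f3", "f4", "f5plus")


@dataclass(frozen=True)
class FilterParams:
    """Hit-quality thresholds; a hit is kept only when STRICTLY above all three."""

    min_aln_length: int = 300
    min_identity: float = 75.0
    min_bitscore: float = 1000.0

    def __post_init__(self) -> None:
        if self.min_aln_length < 0 or self.min_identity < 0 or self.min_bitscore < 0:
            raise ValueError("filter thresholds must be >= 0")

    def keeps(self, rec: AlignmentRecord) -> bool:
        return (
            rec.aln_len > self.min_aln_length
            and rec.pident > self.min_identity
            and rec.bitscore > self.min_bitscore
        )


@dataclass
class MultiplicityProfile:
    """Fractions of bases covered exactly 0,1,2,3,4 and >=5 times.

    ``per_sequence`` maps sequence id -> (fractions dict, length); the
    genome-wide fractions are the length-weighted means.
    """

    fractions: dict[str, float]
    total_bases: int
    per_sequence: dict[str, tuple[dict[str, float], int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = sum(self.fractions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"multiplicity fractions sum to {s}, not 1")


@dataclass
class DivergenceSummary:
    """Allele-divergence statistics over off-diagonal filtered hits."""

    mismatches_per_kb: float
    gaps_per_kb: float
    mean_identity_percent: float
    total_allelic_aln_length: int
    defined: bool = True  # False when there were no off-diagonal hits


def filter_alignments(
    records: Iterable[AlignmentRecord], params: FilterParams | None = None
) -> list[AlignmentRecord]:
    """Keep hits with aln_len, identity and bitscore strictly above thresholds."""
    params = params or FilterParams()
    return [r for r in records if params.keeps(r)]


def multiplicity_profile(
    records: Sequence[AlignmentRecord],
    seq_lengths: Mapping[str, int],
) -> MultiplicityProfile:
    """Per-base coverage multiplicity over query coordinates of filtered hits.

    Each hit (including the trivial diagonal self-hit, which must be present
    in ``records`` for covered-once sequence to count as 1x) contributes +1
    over its query interval. Subject-side coverage is carried by the
    reciprocal record of an all-vs-all self-alignment.
    """
    counts: dict[str, np.ndarray] = {}
    for rec in records:
        if rec.query_id not in seq_lengths:
            raise KeyError(f"query {rec.query_id} missing from seq_lengths")
        length = seq_lengths[rec.query_id]
        if rec.q_end > length:
            raise ValueError(
                f"hit {rec.query_id}:[{rec.q_start},{rec.q_end}] exceeds "
                f"sequence length {length}"
            )
        diff = counts.setdefault(rec.query_id, np.zeros(length + 1, dtype=np.int64))
        diff[rec.q_start - 1] += 1
        diff[rec.q_end] -= 1

    per_sequence: dict[str, tuple[dict[str, float], int]] = {}
    pooled = np.zeros(6, dtype=np.int64)
    total = 0
    for seq_id, length in seq_lengths.items():
        if seq_id in counts:
            mult = np.cumsum(counts[seq_id][:-1])
            clipped = np.minimum(mult, 5)
            tab = np.bincount(clipped, minlength=6)
        else:
            tab = np.array([length, 0, 0, 0, 0, 0], dtype=np.int64)
        fr = {k: tab[i] / length for i, k in enumerate(_MULT_KEYS)}
        per_sequence[seq_id] = (fr, length)
        pooled += tab
        total += length
    if total == 0:
        raise ValueError("no sequences provided")
    fractions = {k: pooled[i] / total for i, k in enumerate(_MULT_KEYS)}
    return MultiplicityProfile(
        fractions=fractions, total_bases=total, per_sequence=per_sequence
    )


def allelic_divergence(
    records: Sequence[AlignmentRecord],
    inter_contig_only: bool = False,
) -> DivergenceSummary:
    """Divergence between alleles from off-diagonal filtered hits.

    Both reciprocal directions of a pair count (each is a distinct record);
    rates are per-kb of summed alignment length. When no record carries the
    total-gaps column, gap opens stand in as a lower bound (logged).
    """
    offdiag = [r for r in records if not r.is_diagonal]
    if inter_contig_only:
        offdiag = [r for r in offdiag if r.query_id != r.subject_id]
    if not offdiag:
        return DivergenceSummary(0.0, 0.0, 0.0, 0, defined=False)
    total_len = sum(r.aln_len for r in offdiag)
    total_mm = sum(r.mismatches for r in offdiag)
    if any(r.gaps < 0 for r in offdiag):
        logger.warning(
            "total-gaps column absent for some hits; gaps/kb uses gap opens "
            "as a lower bound"
        )
        total_gaps = sum(r.gaps if r.gaps >= 0 else r.gap_opens for r in offdiag)
    else:
        total_gaps = sum(r.gaps for r in offdiag)
    mean_ident = sum(r.pident * r.aln_len for r in offdiag) / total_len
    return DivergenceSummary(
        mismatches_per_kb=1000.0 * total_mm / total_len,
        gaps_per_kb=1000.0 * total_gaps / total_len,
        mean_identity_percent=mean_ident,
        total_allelic_aln_length=total_len,
    )


def genome_summary(
    profile: MultiplicityProfile, divergence: DivergenceSummary
) -> pd.DataFrame:
    """Tabular report: per-sequence and genome-wide multiplicity fractions
    plus the divergence summary, one row per sequence and a TOTAL row."""
    rows = []
    for seq_id, (fr, length) in sorted(profile.per_sequence.items()):
        rows.append({"sequence": seq_id, "length": length, **fr})
    rows.append(
        {"sequence": "TOTAL", "length": profile.total_bases, **profile.fractions}
    )
    df = pd.DataFrame(rows)
    df.attrs["mismatches_per_kb"] = divergence.mismatches_per_kb
    df.attrs["gaps_per_kb"] = divergence.gaps_per_kb
    df.attrs["mean_identity_percent"] = divergence.mean_identity_percent
    df.attrs["divergence_defined"] = divergence.defined
    return df
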