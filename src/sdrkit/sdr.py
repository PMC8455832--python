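"""Sex-determining-region (SDR) localisation and Y/X haplotype classification.

In poplars with an XY system, the Y SDR haplotype carries partial repeats of
the sex-switch gene ARR17 (two of them arranged as an inverted repeat whose
arms flank a fragment of the HEMA gene); X haplotypes carry none. Given
marker-to-assembly alignment hits, this module chains fragmented hits per
marker into clusters, locates SDR-bearing contigs, classifies each located
SDR haplotype as Y or X by the presence of ARR17 partial-repeat clusters,
identifies inverted-repeat arms via the intervening HEMA fragment, and calls
completeness of the male-specific MSL locus by query coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import AlignmentRecord, GenomicInterval

__all__ = [
    "MarkerCluster",
    "SdrCall",
    "InvertedRepeatCall",
    "MslCall",
    "RegionSpec",
    "DEFAULT_REGIONS",
    "cluster_marker_hits",
    "locate_sdr",
    "classify_haplotype",
    "find_inverted_repeat",
    "call_msl",
]

MARKER_NAMES = frozenset(
    {"SDR", "ARR17", "ARR17_repeat", "HEMA", "MSL", "TCP", "CLC", "MET1", "LRR", "PSR"}
)


@dataclass(frozen=True)
class RegionSpec:
    """Named reference intervals of the marker loci on the reference genome
    used for read mapping and marker extraction (1-based inclusive)."""

    arr17_gene: GenomicInterval
    arr17_repeat_locus: GenomicInterval
    sdr: GenomicInterval


#: Reference coordinates of the marker loci on the P. trichocarpa
#: "Stettler 14" assembly (SDR assembled on chromosome 18 there).
DEFAULT_REGIONS = RegionSpec(
    arr17_gene=GenomicInterval("Chr19", 15_907_431, 15_910_397),
    arr17_repeat_locus=GenomicInterval("Chr18", 16_290_253, 16_308_089),
    sdr=GenomicInterval("Chr18", 16_200_000, 16_320_000),
)


@dataclass
class MarkerCluster:
    """A chained group of alignment hits of one marker onto one contig."""

    marker_name: str
    contig_id: str
    interval: GenomicInterval
    strand: str
    covered_query_fraction: float
    n_hits: int
    best_identity: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.covered_query_fraction <= 1.0 + 1e-12:
            raise ValueError(
                f"covered_query_fraction {self.covered_query_fraction} outside [0,1]"
            )


@dataclass
class SdrCall:
    """SDR interval on a contig with its Y/X haplotype class and evidence."""

    contig_id: str
    sdr_interval: GenomicInterval | None
    strand: str
    haplotype_class: str  # Y | X | unclassified
    n_repeat_clusters: int = 0
    markers_present: list[str] = field(default_factory=list)
    flagged_multiple: bool = False


@dataclass
class InvertedRepeatCall:
    """An ARR17 partial-repeat inverted pair with the HEMA fragment between."""

    contig_id: str
    left_arm: GenomicInterval
    right_arm: GenomicInterval
    spacer: GenomicInterval
    hema_present: bool = True


@dataclass
class MslCall:
    """Completeness call for the MSL locus on one contig."""

    contig_id: str
    status: str  # complete | partial | absent
    covered_query_fraction: float
    best_identity: float


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def cluster_marker_hits(
    records: Iterable[AlignmentRecord],
    marker_lengths: dict[str, int],
    chain_gap: int = 20_000,
) -> list[MarkerCluster]:
    """Chain fragmented hits of each marker into clusters.

    Hits of the same marker on the same contig and strand whose
    contig-coordinate gap is at most ``chain_gap`` are merged; the cluster
    interval spans min..max of the merged hits and the covered query fraction
    is the merged query-side coverage divided by the marker length. Chaining
    is idempotent: clustering an already-chained hit set changes nothing.
    """
    groups: dict[tuple[str, str, str], list[AlignmentRecord]] = {}
    for rec in records:
        groups.setdefault((rec.query_id, rec.subject_id, rec.strand), []).append(rec)
    clusters: list[MarkerCluster] = []
    for (marker, contig, strand), hits in sorted(groups.items()):
        if marker not in marker_lengths:
            raise KeyError(f"marker {marker} missing from marker_lengths")
        hits.sort(key=lambda r: (r.s_start, r.s_end))
        chain: list[AlignmentRecord] = []
        chain_end = -1

        def _flush() -> None:
            if not chain:
                return
            qcov = _merged_length([(r.q_start, r.q_end) for r in chain])
            clusters.append(
                MarkerCluster(
                    marker_name=marker,
                    contig_id=contig,
                    interval=GenomicInterval(
                        seq_id=contig,
                        start=min(r.s_start for r in chain),
                        end=max(r.s_end for r in chain),
                        strand=strand,
                    ),
                    strand=strand,
                    covered_query_fraction=min(qcov / marker_lengths[marker], 1.0),
                    n_hits=len(chain),
                    best_identity=max(r.pident for r in chain),
                )
            )

        for rec in hits:
            if chain and rec.s_start - chain_end > chain_gap:
                _flush()
                chain = []
            chain.append(rec)
            chain_end = max(chain_end, rec.s_end)
        _flush()
    return clusters


def locate_sdr(
    clusters: Sequence[MarkerCluster],
    min_query_fraction: float = 0.5,
) -> list[tuple[str, GenomicInterval, str, bool]]:
    """Call SDR-bearing contigs from SDR marker clusters.

    Emits one call per contig whose best SDR cluster covers at least
    ``min_query_fraction`` of the SDR query; a contig with two qualifying
    clusters (possible chimera) yields two calls, both flagged.
    """
    by_contig: dict[str, list[MarkerCluster]] = {}
    for cl in clusters:
        if cl.marker_name == "SDR" and cl.covered_query_fraction >= min_query_fraction:
            by_contig.setdefault(cl.contig_id, []).append(cl)
    calls = []
    for contig, cls in sorted(by_contig.items()):
        flagged = len(cls) > 1
        for cl in sorted(cls, key=lambda c: c.interval.start):
            calls.append((contig, cl.interval, cl.strand, flagged))
    return calls


def classify_haplotype(
    sdr_calls: Sequence[tuple[str, GenomicInterval, str, bool]],
    clusters: Sequence[MarkerCluster],
    flank: int = 50_000,
    all_contigs: Sequence[str] | None = None,
) -> list[SdrCall]:
    """Classify each located SDR haplotype as Y or X.

    Y iff at least one ARR17 partial-repeat cluster overlaps the SDR interval
    extended by ``flank`` on both sides; X iff the SDR was located and no
    such cluster exists; contigs named in ``all_contigs`` without an SDR call
    are reported unclassified. Enlarging ``flank`` can only convert X to Y,
    never Y to X.
    """
    repeat_clusters = [c for c in clusters if c.marker_name == "ARR17_repeat"]
    marker_by_contig: dict[str, set[str]] = {}
    for c in clusters:
        marker_by_contig.setdefault(c.contig_id, set()).add(c.marker_name)
    out: list[SdrCall] = []
    called = set()
    for contig, interval, strand, flagged in sdr_calls:
        called.add(contig)
        lo = max(1, interval.start - flank)
        hi = interval.end + flank
        window = GenomicInterval(seq_id=contig, start=lo, end=hi)
        n_rep = sum(
            1 for c in repeat_clusters
            if c.contig_id == contig and c.interval.overlaps(window)
        )
        out.append(
            SdrCall(
                contig_id=contig,
                sdr_interval=interval,
                strand=strand,
                haplotype_class="Y" if n_rep >= 1 else "X",
                n_repeat_clusters=n_rep,
                markers_present=sorted(marker_by_contig.get(contig, ())),
                flagged_multiple=flagged,
            )
        )
    for contig in all_contigs or ():
        if contig not in called:
            out.append(
                SdrCall(
                    contig_id=contig, sdr_interval=None, strand=".",
                    haplotype_class="unclassified",
                    markers_present=sorted(marker_by_contig.get(contig, ())),
                )
            )
    return out


def find_inverted_repeat(
    clusters: Sequence[MarkerCluster],
    max_span: int = 10_000,
) -> list[InvertedRepeatCall]:
    """Identify ARR17 partial-repeat inverted pairs by the HEMA fragment
    between the arms: a call is emitted for each opposite-strand pair of
    repeat clusters on one contig within ``max_span`` whose gap contains a
    HEMA cluster.

    Clusters should be chained with a gap smaller than the repeat spacing
    (e.g. ``chain_gap=200``) so that individual repeat copies stay separate;
    the coarse chaining used for haplotype classification would fuse
    same-strand copies across the arm region.
    """
    repeats = [c for c in clusters if c.marker_name == "ARR17_repeat"]
    hemas = [c for c in clusters if c.marker_name == "HEMA"]
    calls: list[InvertedRepeatCall] = []
    for i, a in enumerate(repeats):
        for b in repeats[i + 1:]:
            if a.contig_id != b.contig_id or a.strand == b.strand:
                continue
            left, right = (a, b) if a.interval.start <= b.interval.start else (b, a)
            if left.interval.end >= right.interval.start:
                continue  # arms overlap: no spacer
            span = right.interval.end - left.interval.start + 1
            if span > max_span:
                continue
            spacer = GenomicInterval(
                seq_id=a.contig_id,
                start=left.interval.end + 1,
                end=right.interval.start - 1,
            )
            if any(
                h.contig_id == a.contig_id
                and h.interval.start >= spacer.start
                and h.interval.end <= spacer.end
                for h in hemas
            ):
                calls.append(
                    InvertedRepeatCall(
                        contig_id=a.contig_id,
                        left_arm=left.interval,
                        right_arm=right.interval,
                        spacer=spacer,
                    )
                )
    return calls


def call_msl(
    clusters: Sequence[MarkerCluster],
    contig_id: str,
    complete_fraction: float = 0.9,
) -> MslCall:
    """Call MSL completeness on a contig by merged query coverage of MSL hits:
    complete (>= ``complete_fraction``), partial (anything above zero) or
    absent (no filtered hits)."""
    msl = [
        c for c in clusters
        if c.marker_name == "MSL" and c.contig_id == contig_id
    ]
    if not msl:
        return MslCall(contig_id=contig_id, status="absent",
                       covered_query_fraction=0.0, best_identity=0.0)
    frac = max(c.covered_query_fraction for c in msl)
    status = "complete" if frac >= complete_fraction else "partial"
    return MslCall(
        contig_id=contig_id, status=status, covered_query_fraction=frac,
        best_identity=max(c.best_identity for c in msl),
    )
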