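"""Variant-allele-fraction (VAF) profile clustering across samples.

For a panel of samples jointly called against one reference (ploidy 4, so
VAFs concentrate near {0, 1/4, 1/2, 3/4, 1}), the VAF profile over a region
is a fingerprint of the sample's haplotype composition there. This module
builds the masked sample x site VAF matrix (entries with per-sample depth
below ``min_depth`` reads are excluded), computes cross-sample Euclidean
distances with pairwise deletion, clusters them with Ward's minimum-variance
method on squared distances (the ward.D2 convention: heights reported on the
distance scale), and embeds the distance matrix with classical (Torgerson)
multidimensional scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .io_formats import GenomicInterval, VcfSite

import logging

logger = logging.getLogger(__name__)

__all__ = [
    "VafParams",
    "VafMatrix",
    "DistanceMatrix",
    "LinkageTree",
    "MdsEmbedding",
    "build_vaf_matrix",
    "pairwise_distance",
    "ward_linkage",
    "mds_embed",
    "cut_tree",
    "export_newick",
]


@dataclass(frozen=True)
class VafParams:
    """Masking and region-restriction parameters for VAF extraction."""

    min_depth: int = 5
    regions: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class VafMatrix:
    """Masked sample x site VAF values; one row per (site, alt allele).

    ``values[i, j]`` is AO/DP for site-row i and sample j, valid only where
    ``mask[i, j]`` is True.
    """

    sample_ids: list[str]
    site_keys: list[tuple[str, int, str]]  # (chrom, pos, alt)
    values: np.ndarray  # (n_sites, n_samples) float
    mask: np.ndarray  # (n_sites, n_samples) bool; True = usable
    min_depth: int

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (len(self.site_keys), len(self.sample_ids)):
            raise ValueError("matrix shape inconsistent with labels")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative cross-sample distance matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    shared_site_counts: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class LinkageTree:
    """Agglomerative merge history in scipy linkage form.

    ``merges`` is the (n-1, 4) scipy linkage matrix: members merged, merge
    height on the distance scale, new cluster size. Heights are nondecreasing.
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


@dataclass
class MdsEmbedding:
    """Classical MDS coordinates with the eigenvalue spectrum."""

    sample_ids: list[str]
    coords: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # descending, full spectrum
    positive_mass_captured: float


def build_vaf_matrix(
    sites: Sequence[VcfSite],
    samples: Sequence[str],
    params: VafParams | None = None,
) -> VafMatrix:
    """VAF = AO/DP per alt allele per sample; entries with DP below
    ``min_depth`` or a missing call are masked. Multi-allelic sites expand to
    one row per alt allele. Sites are restricted to ``params.regions`` when
    any are given."""
    params = params or VafParams()
    keys: list[tuple[str, int, str]] = []
    rows_v: list[np.ndarray] = []
    rows_m: list[np.ndarray] = []
    n = len(samples)
    for site in sites:
        if params.regions and not any(
            iv.contains(site.chrom, site.pos) for iv in params.regions
        ):
            continue
        for ai, alt in enumerate(site.alts):
            vals = np.zeros(n)
            mask = np.zeros(n, dtype=bool)
            for si in range(n):
                if site.missing[si]:
                    continue
                dp = site.dp[si]
                ao = site.ao[si][ai]
                if dp == 0:
                    if ao > 0:
                        raise ValueError(
                            f"site {site.chrom}:{site.pos} sample {samples[si]}: "
                            f"AO={ao} with DP=0"
                        )
                    continue
                if dp < params.min_depth:
                    continue
                vals[si] = ao / dp
                mask[si] = True
            keys.append((site.chrom, site.pos, alt))
            rows_v.append(vals)
            rows_m.append(mask)
    values = np.array(rows_v) if rows_v else np.zeros((0, n))
    maskm = np.array(rows_m) if rows_m else np.zeros((0, n), dtype=bool)
    return VafMatrix(
        sample_ids=list(samples), site_keys=keys, values=values, mask=maskm,
        min_depth=params.min_depth,
    )


def pairwise_distance(
    matrix: VafMatrix,
    allow_empty_pairs: bool = False,
    rescale_by_shared: bool = False,
) -> DistanceMatrix:
    """Cross-sample Euclidean distances with pairwise deletion.

    D[i,j] = sqrt(sum over sites unmasked in BOTH samples of (v_i - v_j)^2).
    Distances are not normalised by the shared-site count by default (raw
    Euclidean distances); ``rescale_by_shared`` multiplies each pair by
    sqrt(n_sites / n_shared) to compensate unequal coverage. A pair with
    zero shared sites raises unless ``allow_empty_pairs``, in which case its
    distance is NaN.
    """
    v = matrix.values
    m = matrix.mask.astype(float)
    n_sites = v.shape[0]
    shared = (m.T @ m).astype(int)
    vm = np.where(matrix.mask, v, 0.0)
    # sum over shared sites of (vi - vj)^2, via masked expansions
    sq = vm**2
    cross = vm.T @ vm
    si = (sq.T @ m)  # sum_i vi^2 over sites where both i (row) and j unmasked
    d2 = si + si.T - 2 * cross
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)
    d = np.sqrt(d2)
    if rescale_by_shared and n_sites > 0:
        with np.errstate(divide="ignore"):
            scale = np.sqrt(np.where(shared > 0, n_sites / np.maximum(shared, 1), np.nan))
        np.fill_diagonal(scale, 1.0)
        d = d * scale
    empty = (shared == 0) & ~np.eye(len(matrix.sample_ids), dtype=bool)
    if empty.any():
        if not allow_empty_pairs:
            i, j = np.argwhere(empty)[0]
            raise ValueError(
                f"samples {matrix.sample_ids[i]} and {matrix.sample_ids[j]} "
                "share no usable sites"
            )
        d[empty] = np.nan
    d = (d + d.T) / 2  # enforce exact symmetry against float noise
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        sample_ids=list(matrix.sample_ids), values=d, shared_site_counts=shared
    )


def ward_linkage(dist: DistanceMatrix) -> LinkageTree:
    """Ward's minimum-variance clustering on squared distances (ward.D2).

    Agglomeration follows the Lance-Williams recurrence with Ward
    coefficients on d^2; the reported merge height is the square root of the
    minimal merge cost, i.e. heights are on the distance scale, matching the
    ward.D2 convention of R's hclust. Heights are nondecreasing.
    """
    if np.isnan(dist.values).any():
        raise ValueError("distance matrix contains NaN; cannot cluster")
    condensed = squareform(dist.values, checks=False)
    merges = sch.linkage(condensed, method="ward")
    return LinkageTree(merges=merges, labels=list(dist.sample_ids))


def mds_embed(dist: DistanceMatrix, k: int = 2) -> MdsEmbedding:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres the squared distances, B = -1/2 J D^2 J, eigendecomposes
    B, and scales the top eigenvectors by the square roots of their (positive)
    eigenvalues. Negative eigenvalues — which arise when masking makes the
    matrix non-Euclidean — are dropped with a logged warning; coordinates are
    zero-padded when fewer than ``k`` positive eigenvalues exist.
    """
    n = dist.n
    if n < 2:
        raise ValueError("MDS needs at least 2 samples")
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n-1={n - 1}")
    d2 = dist.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-9 * max(abs(eigval[0]), 1.0)
    if eigval[-1] < -tol:
        logger.warning(
            "distance matrix is non-Euclidean (most negative eigenvalue "
            "%.3g); negative components dropped", eigval[-1],
        )
    pos = eigval > tol
    n_pos = int(pos.sum())
    coords = np.zeros((n, k))
    use = min(k, n_pos)
    coords[:, :use] = eigvec[:, :use] * np.sqrt(eigval[:use])
    pos_mass = eigval[pos].sum()
    captured = eigval[:use][eigval[:use] > tol].sum() / pos_mass if pos_mass > 0 else 0.0
    return MdsEmbedding(
        sample_ids=list(dist.sample_ids), coords=coords,
        eigenvalues=eigval, positive_mass_captured=float(captured),
    )


def cut_tree(tree: LinkageTree, k: int) -> list[int]:
    """Labels of the k clusters present after n-k merges (0-based, ordered
    by first appearance along the leaf list)."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1,{n}]")
    raw = sch.cut_tree(tree.merges, n_clusters=k).ravel()
    # renumber clusters by first appearance for deterministic labels
    remap: dict[int, int] = {}
    labels = []
    for c in raw:
        if c not in remap:
            remap[c] = len(remap)
        labels.append(remap[c])
    return labels


def export_newick(tree: LinkageTree) -> str:
    """Newick string with branch lengths equal to merge-height differences."""
    n = tree.n_leaves
    if n == 1:
        return f"{tree.labels[0]}:0.0;"
    node_height: dict[int, float] = {i: 0.0 for i in range(n)}
    node_str: dict[int, str] = {i: tree.labels[i] for i in range(n)}
    for idx, (a, b, h, _size) in enumerate(tree.merges):
        a, b = int(a), int(b)
        new = n + idx
        sa = f"{node_str[a]}:{h - node_height[a]:.6g}"
        sb = f"{node_str[b]}:{h - node_height[b]:.6g}"
        node_str[new] = f"({sa},{sb})"
        node_height[new] = float(h)
    return node_str[2 * n - 2] + ";"
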