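"""Per-chromosome adjacency-constrained agglomerative segmentation.

Every CpG site starts as a singleton cluster; at each step the genomically
adjacent pair of clusters with the smallest dissimilarity (nLLR plus the
Cauchy distance penalty, see :mod:`methblocks.core_model`) is merged.  Only
adjacent same-chromosome clusters are candidates, so every cluster -- and
hence every segment obtained by cutting the resulting tree -- is a
contiguous genomic interval.  Chromosomes are segmented independently and
the per-chromosome results concatenated.

The merge history is a :class:`SegmentDendrogram`; cutting it at ``k``
clusters undoes the last ``k - 1`` merges.  The default resolution is
chosen per chromosome by minimizing a Schwarz-type BIC,
``-2 log L + k * n * log(N_obs)``, where each of the ``k`` segments carries
one free rate per sample and ``N_obs`` counts site/sample cells with
non-zero coverage.

The incremental agglomeration uses a priority queue with lazy invalidation
of stale candidate pairs; its merge sequence is contractually identical to
re-evaluating every adjacent pair from scratch at each step (enforced by an
oracle test).  Ties in merge cost are broken toward the leftmost pair.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.special import xlogy

from .core_model import MethylationCountSet, site_rate_mle

__all__ = [
    "Merge",
    "SegmentDendrogram",
    "Segment",
    "Segmentation",
    "build_dendrogram",
    "cut_dendrogram",
    "bic_score",
    "bic_path",
    "select_segmentation_bic",
    "segment_genome",
]


class Merge(NamedTuple):
    """One agglomeration step: clusters ``left`` and ``right`` fuse into
    ``new_id`` at dissimilarity ``cost`` (of which ``nllr`` is the
    likelihood part, the rest the distance penalty)."""

    left: int
    right: int
    cost: float
    nllr: float
    new_id: int


@dataclass
class SegmentDendrogram:
    """Merge tree of one chromosome.

    Leaves are cluster ids ``0 .. leaf_count-1`` in genomic order (local to
    the chromosome); merge ``j`` creates cluster id ``leaf_count + j``.
    ``intervals`` maps every cluster id to its inclusive local site-index
    range ``(lo, hi)``.  ``offset`` is the global row index of the
    chromosome's first site in the parent count set.
    """

    chrom: str
    leaf_count: int
    offset: int
    merges: list[Merge] = field(default_factory=list)
    intervals: dict[int, tuple[int, int]] = field(default_factory=dict)

    def cluster_members(self, cluster_id: int) -> np.ndarray:
        """Local site indices of a cluster, in genomic order."""
        lo, hi = self.intervals[cluster_id]
        return np.arange(lo, hi + 1)

    def clusters_at(self, k: int) -> list[int]:
        """Active cluster ids after applying the first ``leaf_count - k``
        merges, sorted by genomic position."""
        if not 1 <= k <= self.leaf_count:
            raise ValueError(f"k={k} out of range [1, {self.leaf_count}]")
        active = set(range(self.leaf_count))
        for mg in self.merges[: self.leaf_count - k]:
            active.discard(mg.left)
            active.discard(mg.right)
            active.add(mg.new_id)
        return sorted(active, key=lambda cid: self.intervals[cid][0])


@dataclass
class Segment:
    """A contiguous block of CpG sites with pooled per-sample rates."""

    chrom: str
    start_pos: int
    end_pos: int
    site_indices: np.ndarray  # global rows in the MethylationCountSet
    n_cpgs: int
    per_sample_rate: np.ndarray  # pooled MLE per sample, nan if no coverage
    mean_rate: float  # coverage-weighted mean methylation across samples
    coherent: bool | None = None
    coherence_pvalue: float | None = None


@dataclass
class Segmentation:
    """An ordered partition of all CpG sites into segments."""

    segments: list[Segment]
    k_per_chrom: dict[str, int]
    bic: float | None = None

    def breakpoints(self, data: MethylationCountSet) -> dict[str, np.ndarray]:
        """Internal segment boundaries per chromosome, as local site
        indices: boundary ``b`` separates sites ``b-1`` and ``b``."""
        slices = data.chrom_slices()
        out: dict[str, np.ndarray] = {ch: np.array([], dtype=int) for ch in slices}
        for ch, sl in slices.items():
            starts = [
                int(seg.site_indices[0]) - sl.start
                for seg in self.segments
                if seg.chrom == ch
            ]
            out[ch] = np.array(sorted(starts)[1:], dtype=int)
        return out


def _ll(c: np.ndarray, t: np.ndarray) -> float:
    # pooled-MLE binomial log-kernel over samples; 0*log 0 = 0, and
    # zero-coverage pools get a dummy rate so they contribute exactly 0
    total = c + t
    p = np.where(total > 0, c / np.where(total > 0, total, 1.0), 0.5)
    return float(np.sum(xlogy(c, p) + xlogy(t, 1.0 - p)))


def _penalty(gap: float, scale: float) -> float:
    x = gap / scale
    return math.log(math.pi * (1.0 + x * x))


def build_dendrogram(
    data: MethylationCountSet, chrom: str, scale: float = 100.0
) -> SegmentDendrogram:
    """Agglomerate one chromosome bottom-up into a full merge tree.

    Repeatedly merges the adjacent cluster pair with the smallest
    dissimilarity, recomputing the new cluster's dissimilarities to its (at
    most two) genomic neighbors from pooled raw counts, until one cluster
    remains.
    """
    slices = data.chrom_slices()
    if chrom not in slices:
        raise ValueError(f"chromosome {chrom!r} not present in data")
    sl = slices[chrom]
    C = data.meth_counts[sl].astype(float)
    T = data.unmeth_counts[sl].astype(float)
    pos = data.positions[sl]
    m = C.shape[0]

    dend = SegmentDendrogram(chrom=chrom, leaf_count=m, offset=sl.start)
    dend.intervals = {i: (i, i) for i in range(m)}
    if m == 1:
        return dend

    # per-cluster state, indexed by cluster id
    csum: dict[int, np.ndarray] = {i: C[i] for i in range(m)}
    tsum: dict[int, np.ndarray] = {i: T[i] for i in range(m)}
    tot = C + T
    p = np.where(tot > 0, C / np.where(tot > 0, tot, 1.0), 0.5)
    leaf_ll = (xlogy(C, p) + xlogy(T, 1.0 - p)).sum(axis=1)
    ll: dict[int, float] = {i: float(leaf_ll[i]) for i in range(m)}
    left_nb: dict[int, int | None] = {i: i - 1 if i > 0 else None for i in range(m)}
    right_nb: dict[int, int | None] = {i: i + 1 if i < m - 1 else None for i in range(m)}
    alive = set(range(m))

    # heap entries: (cost, start-of-left-cluster, left_id, right_id);
    # the start index breaks cost ties toward the leftmost pair
    heap: list[tuple[float, int, int, int]] = []

    def pair_cost(li: int, ri: int) -> tuple[float, float]:
        c = csum[li] + csum[ri]
        t = tsum[li] + tsum[ri]
        merged_ll = _ll(c, t)
        nllr_val = ll[li] + ll[ri] - merged_ll
        if nllr_val < 0.0:
            nllr_val = 0.0
        gap = float(pos[dend.intervals[ri][0]] - pos[dend.intervals[li][1]])
        return nllr_val + _penalty(gap, scale), nllr_val

    for i in range(m - 1):
        cost, _ = pair_cost(i, i + 1)
        heapq.heappush(heap, (cost, i, i, i + 1))

    next_id = m
    while len(alive) > 1:
        cost, _, li, ri = heapq.heappop(heap)
        if li not in alive or ri not in alive or right_nb[li] != ri:
            continue  # stale entry
        _, nllr_val = pair_cost(li, ri)
        new_id = next_id
        next_id += 1
        dend.merges.append(Merge(li, ri, cost, nllr_val, new_id))
        lo = dend.intervals[li][0]
        hi = dend.intervals[ri][1]
        dend.intervals[new_id] = (lo, hi)
        csum[new_id] = csum[li] + csum[ri]
        tsum[new_id] = tsum[li] + tsum[ri]
        ll[new_id] = ll[li] + ll[ri] - nllr_val
        ln, rn = left_nb[li], right_nb[ri]
        alive.discard(li)
        alive.discard(ri)
        alive.add(new_id)
        left_nb[new_id] = ln
        right_nb[new_id] = rn
        if ln is not None:
            right_nb[ln] = new_id
            c2, _ = pair_cost(ln, new_id)
            heapq.heappush(heap, (c2, dend.intervals[ln][0], ln, new_id))
        if rn is not None:
            left_nb[rn] = new_id
            c2, _ = pair_cost(new_id, rn)
            heapq.heappush(heap, (c2, lo, new_id, rn))
    return dend


def _make_segment(data: MethylationCountSet, global_idx: np.ndarray) -> Segment:
    c = data.meth_counts[global_idx].sum(axis=0)
    t = data.unmeth_counts[global_idx].sum(axis=0)
    rates = np.atleast_1d(site_rate_mle(c, t))
    total_reads = float(c.sum() + t.sum())
    mean_rate = float(c.sum()) / total_reads if total_reads > 0 else float("nan")
    return Segment(
        chrom=data.chroms[global_idx[0]],
        start_pos=int(data.positions[global_idx[0]]),
        end_pos=int(data.positions[global_idx[-1]]),
        site_indices=global_idx,
        n_cpgs=int(global_idx.size),
        per_sample_rate=rates,
        mean_rate=mean_rate,
    )


def cut_dendrogram(
    dend: SegmentDendrogram, k: int, data: MethylationCountSet
) -> list[Segment]:
    """Extract the ``k``-cluster partition of the chromosome as segments."""
    segments = []
    for cid in dend.clusters_at(k):
        lo, hi = dend.intervals[cid]
        gidx = np.arange(dend.offset + lo, dend.offset + hi + 1)
        segments.append(_make_segment(data, gidx))
    return segments


def _n_obs(data: MethylationCountSet, rows: np.ndarray, mode: str) -> float:
    depth = data.meth_counts[rows] + data.unmeth_counts[rows]
    if mode == "cells":
        return float((depth > 0).sum())
    if mode == "reads":
        return float(depth.sum())
    raise ValueError(f"unknown nobs_mode {mode!r}")


def bic_score(
    segments: list[Segment], data: MethylationCountSet, nobs_mode: str = "cells"
) -> float:
    """Schwarz criterion of a segmentation: ``-2 log L + k*n*log(N_obs)``.

    Each segment contributes one free rate per sample (``k * n`` parameters
    in total); ``N_obs`` defaults to the number of covered site/sample
    cells ("cells"), with total read count ("reads") as an alternative.
    """
    from .core_model import segment_log_likelihood

    k = len(segments)
    n = data.n_samples
    ll_total = sum(segment_log_likelihood(data, seg.site_indices) for seg in segments)
    rows = np.concatenate([seg.site_indices for seg in segments])
    nobs = max(_n_obs(data, rows, nobs_mode), 1.0)
    return -2.0 * ll_total + k * n * math.log(nobs)


def bic_path(
    dend: SegmentDendrogram, data: MethylationCountSet, nobs_mode: str = "cells"
) -> tuple[np.ndarray, np.ndarray]:
    """BIC at every cut ``k = 1 .. leaf_count`` along the merge path.

    Exploits that each merge lowers the total log-likelihood by exactly its
    nLLR, so the whole path costs one pass over the merges.
    """
    m = dend.leaf_count
    sl = slice(dend.offset, dend.offset + m)
    C = data.meth_counts[sl].astype(float)
    T = data.unmeth_counts[sl].astype(float)
    tot = C + T
    p = np.where(tot > 0, C / np.where(tot > 0, tot, 1.0), 0.5)
    ll_leaves = float((xlogy(C, p) + xlogy(T, 1.0 - p)).sum())
    nobs = max(_n_obs(data, np.arange(sl.start, sl.stop), nobs_mode), 1.0)
    log_nobs = math.log(nobs)
    n = data.n_samples

    ks = np.arange(1, m + 1)
    ll_at_k = np.empty(m)
    ll_at_k[m - 1] = ll_leaves  # k = m: no merges applied
    drop = 0.0
    for j, mg in enumerate(dend.merges):
        drop += mg.nllr
        ll_at_k[m - 2 - j] = ll_leaves - drop  # after j+1 merges: k = m-j-1
    bics = -2.0 * ll_at_k + ks * n * log_nobs
    return ks, bics


def select_segmentation_bic(
    dend: SegmentDendrogram, data: MethylationCountSet, nobs_mode: str = "cells"
) -> list[Segment]:
    """Cut the dendrogram at the BIC-minimizing resolution (ties -> smaller k)."""
    ks, bics = bic_path(dend, data, nobs_mode)
    best_k = int(ks[int(np.argmin(bics))])  # argmin returns first min: smallest k
    return cut_dendrogram(dend, best_k, data)


def segment_genome(
    data: MethylationCountSet,
    resolution: str | int = "bic",
    k: int | None = None,
    scale: float = 100.0,
    nobs_mode: str = "cells",
) -> Segmentation:
    """Segment every chromosome independently and concatenate the results.

    Parameters
    ----------
    resolution
        ``"bic"`` (default) selects the cut per chromosome by BIC; an
        integer (or ``resolution="k"`` with ``k=...``) cuts each chromosome
        at a fixed number of segments (clipped to the site count).
    scale
        Divisor of the genomic distance in the Cauchy penalty (bp).
    """
    if isinstance(resolution, (int, np.integer)):
        k = int(resolution)
        resolution = "k"
    if resolution == "k" and (k is None or k < 1):
        raise ValueError("fixed-k resolution requires k >= 1")
    if resolution not in ("bic", "k"):
        raise ValueError(f"unknown resolution {resolution!r}")

    segments: list[Segment] = []
    k_per_chrom: dict[str, int] = {}
    total_bic = 0.0
    for chrom in data.chrom_slices():
        dend = build_dendrogram(data, chrom, scale=scale)
        if resolution == "bic":
            segs = select_segmentation_bic(dend, data, nobs_mode)
        else:
            segs = cut_dendrogram(dend, min(k, dend.leaf_count), data)
        total_bic += bic_score(segs, data, nobs_mode)
        k_per_chrom[chrom] = len(segs)
        segments.extend(segs)
    return Segmentation(segments=segments, k_per_chrom=k_per_chrom, bic=total_bic)
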