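"""Binomial likelihood machinery for multi-sample methylation data.

A WGBS dataset is summarized by two count matrices over ``m`` CpG sites and
``n`` samples: methylated read counts ``C`` and unmethylated read counts
``T``.  The methylated count at site *i* in sample *j* is modelled as
``Binomial(t_ij + c_ij, p_ij)`` where ``p_ij`` is the methylation rate.  The
maximum-likelihood estimate of the rate is the site's beta-value
``c / (c + t)``; pooling a set of sites ``S`` gives the aggregated rate
``sum(c) / sum(c + t)`` per sample.

This module provides those MLEs, the pooled binomial log-likelihood of a
site set (with the binomial coefficient dropped -- it cancels in every
likelihood ratio used downstream), the negative log-likelihood ratio (nLLR)
merge cost between two site sets, and the heavy-tailed genomic distance
penalty (negative log density of a standard Cauchy at ``delta / scale``)
that, added to the nLLR, forms the clustering dissimilarity.

Conventions
-----------
* ``0 * log 0 := 0`` throughout; zero-coverage site/sample cells contribute
  nothing to any likelihood.
* Rates of zero-coverage pools are *undefined* and reported as ``nan``.
* Genomic positions are 1-based coordinates of the CpG cytosine; distances
  are plain coordinate differences in bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

__all__ = [
    "MethylationCountSet",
    "site_rate_mle",
    "pooled_rate_mle",
    "segment_log_likelihood",
    "nllr",
    "distance_penalty",
    "cluster_gap",
    "dissimilarity",
    "LOG_PI",
]

#: Minimum of the distance penalty, attained at delta = 0.
LOG_PI = float(np.log(np.pi))


@dataclass
class MethylationCountSet:
    """Paired methylated/unmethylated count matrices with genomic coordinates.

    Parameters
    ----------
    meth_counts
        Integer matrix ``(m, n)`` of methylated read counts ``C``.
    unmeth_counts
        Integer matrix ``(m, n)`` of unmethylated read counts ``T``.
    positions
        1-based genomic coordinate of each CpG cytosine, length ``m``;
        strictly increasing within each chromosome.
    chroms
        Chromosome label per site, length ``m``; sites must be grouped by
        chromosome in storage order.
    sample_ids
        Sample names, length ``n``.
    """

    meth_counts: np.ndarray
    unmeth_counts: np.ndarray
    positions: np.ndarray
    chroms: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.meth_counts = np.asarray(self.meth_counts)
        self.unmeth_counts = np.asarray(self.unmeth_counts)
        if self.meth_counts.ndim == 1:
            self.meth_counts = self.meth_counts[:, None]
        if self.unmeth_counts.ndim == 1:
            self.unmeth_counts = self.unmeth_counts[:, None]
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chroms = np.asarray(self.chroms, dtype=object)
        if self.meth_counts.shape != self.unmeth_counts.shape:
            raise ValueError("meth_counts and unmeth_counts must share shape")
        m, n = self.meth_counts.shape
        if m < 1 or n < 1:
            raise ValueError("need at least one site and one sample")
        if self.positions.shape != (m,) or self.chroms.shape != (m,):
            raise ValueError("positions/chroms must have one entry per site")
        if (self.meth_counts < 0).any() or (self.unmeth_counts < 0).any():
            raise ValueError("negative read counts")
        if not self.sample_ids:
            self.sample_ids = [f"sample_{j}" for j in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal number of samples")
        self._validate_site_order()

    def _validate_site_order(self) -> None:
        seen: set = set()
        prev_chrom = None
        for i, ch in enumerate(self.chroms):
            if ch != prev_chrom:
                if ch in seen:
                    raise ValueError(
                        f"sites of chromosome {ch!r} are not contiguous in storage order"
                    )
                seen.add(ch)
                prev_chrom = ch
            elif self.positions[i] <= self.positions[i - 1]:
                raise ValueError(
                    f"positions not strictly increasing on {ch!r} at row {i}"
                )

    @property
    def n_sites(self) -> int:
        return self.meth_counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.meth_counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """Read depth per site/sample cell, ``t + c``."""
        return self.meth_counts + self.unmeth_counts

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome, in storage order."""
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, self.n_sites + 1):
            if i == self.n_sites or self.chroms[i] != self.chroms[start]:
                out[self.chroms[start]] = slice(start, i)
                start = i
        return out


def site_rate_mle(meth, unmeth):
    """Per-site methylation rate MLE (the beta-value) ``c / (c + t)``.

    Accepts scalars or arrays.  Returns ``nan`` where coverage is zero
    (the undefined-rate signal).
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if (meth < 0).any() or (unmeth < 0).any():
        raise ValueError("counts must be non-negative")
    total = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(total > 0, meth / np.where(total > 0, total, 1.0), np.nan)
    if rate.ndim == 0:
        return float(rate)
    return rate


def _check_sites(data: MethylationCountSet, sites) -> np.ndarray:
    idx = np.atleast_1d(np.asarray(sites, dtype=np.intp))
    if idx.size == 0:
        raise ValueError("empty site set")
    if np.unique(idx).size != idx.size:
        raise ValueError("duplicate site indices in set")
    if idx.min() < 0 or idx.max() >= data.n_sites:
        raise ValueError("site index out of range")
    return idx


def _pooled_log_likelihood(c_tot: np.ndarray, t_tot: np.ndarray) -> float:
    # log-likelihood (binomial kernel only) at the pooled per-sample MLE;
    # xlogy enforces 0*log(0) = 0. Zero-coverage pools get a dummy rate 0.5
    # (their counts are 0, so they contribute exactly 0; nan would leak
    # through xlogy, which does not short-circuit 0*log(nan)).
    total = c_tot + t_tot
    p = np.where(total > 0, c_tot / np.where(total > 0, total, 1.0), 0.5)
    return float(np.sum(xlogy(c_tot, p) + xlogy(t_tot, 1.0 - p)))


def pooled_rate_mle(data: MethylationCountSet, sites, sample: int | None = None):
    """Aggregated methylation rate over a site set, per sample.

    Returns the ratio of summed methylated counts to summed total counts
    (``nan`` when the pool has zero coverage).  With ``sample=None`` the
    full length-``n`` vector is returned.
    """
    idx = _check_sites(data, sites)
    c = data.meth_counts[idx].sum(axis=0)
    t = data.unmeth_counts[idx].sum(axis=0)
    rates = site_rate_mle(c, t)
    if sample is None:
        return rates
    return float(np.atleast_1d(rates)[sample])


def segment_log_likelihood(data: MethylationCountSet, sites) -> float:
    """Binomial log-likelihood of a site set at its pooled per-sample MLEs.

    ``log L_S = sum_{i in S} sum_j [c_ij log p_Sj + t_ij log(1 - p_Sj)]``
    with the binomial coefficient omitted.  Always <= 0.
    """
    idx = _check_sites(data, sites)
    c = data.meth_counts[idx].sum(axis=0).astype(float)
    t = data.unmeth_counts[idx].sum(axis=0).astype(float)
    return _pooled_log_likelihood(c, t)


def nllr(data: MethylationCountSet, a, b) -> float:
    """Negative log-likelihood ratio merge cost between disjoint site sets.

    ``nLLR(A, B) = -log L_{A u B} + log L_A + log L_B``; non-negative
    because the pooled fit cannot beat the separate MLE fits.  Tiny negative
    floating-point residues are clamped to 0.
    """
    ia = _check_sites(data, a)
    ib = _check_sites(data, b)
    if np.intersect1d(ia, ib).size:
        raise ValueError("site sets overlap")
    la = segment_log_likelihood(data, ia)
    lb = segment_log_likelihood(data, ib)
    lab = segment_log_likelihood(data, np.concatenate([ia, ib]))
    value = la + lb - lab
    return value if value > 0.0 else 0.0


def distance_penalty(delta_bp: float, same_chrom: bool = True, scale: float = 100.0) -> float:
    """Heavy-tailed genomic distance penalty.

    Negative log density of a Student's t with one degree of freedom (a
    standard Cauchy) at ``delta_bp / scale``:
    ``log(pi * (1 + (delta/scale)^2))``.  Minimum ``log(pi)`` at distance 0,
    strictly increasing in distance, ``+inf`` across chromosomes.
    """
    if delta_bp < 0:
        raise ValueError("delta_bp must be non-negative")
    if not same_chrom:
        return math.inf
    x = delta_bp / scale
    return math.log(math.pi * (1.0 + x * x))


def cluster_gap(data: MethylationCountSet, a, b) -> int:
    """Shortest genomic distance (bp) between any site of ``a`` and of ``b``."""
    pa = data.positions[_check_sites(data, a)]
    pb = data.positions[_check_sites(data, b)]
    return int(np.abs(pa[:, None] - pb[None, :]).min())


def dissimilarity(data: MethylationCountSet, a, b, scale: float = 100.0) -> float:
    """Full merge dissimilarity: nLLR plus the genomic distance penalty.

    ``d(A, B) = nLLR(A, B) - log T(delta(A,B)/scale; 1)`` on a shared
    chromosome, ``+inf`` otherwise, where ``delta`` is the minimum pairwise
    coordinate difference.
    """
    ia = _check_sites(data, a)
    ib = _check_sites(data, b)
    ca = set(data.chroms[ia])
    cb = set(data.chroms[ib])
    if len(ca) != 1 or len(cb) != 1:
        raise ValueError("each cluster must lie on a single chromosome")
    if ca != cb:
        return math.inf
    return nllr(data, ia, ib) + distance_penalty(
        cluster_gap(data, ia, ib), same_chrom=True, scale=scale
    )
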