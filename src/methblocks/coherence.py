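"""Likelihood-ratio test for within-segment methylation coherence.

A segment is *coherently methylated* when a single methylation rate per
sample explains all its CpG sites.  For a segment with ``r`` sites the test
compares

* M0 (common): one pooled rate per sample over the whole segment, and
* M1 (separate): one rate per site per sample (the per-site beta-values),

both evaluated with the pooled binomial log-kernel.  The statistic
``2 * (log L(M1) - log L(M0))`` is referred to a chi-square distribution
with ``r - 1`` degrees of freedom by default; the statistically standard
nesting count for ``n`` samples, ``n_eff * (r - 1)`` with ``n_eff`` the
samples that have any coverage in the segment, is available as
``df_mode="per_sample"``.  Segments with ``p > alpha`` (default 0.05) are
flagged coherent; the pattern *across* samples is deliberately left
unconstrained.  No multiple-testing correction is applied to the flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy
from scipy.stats import chi2

from .core_model import MethylationCountSet, _check_sites, segment_log_likelihood
from .clustering import Segment, Segmentation

__all__ = ["CoherenceResult", "coherence_test", "annotate_segmentation"]


@dataclass
class CoherenceResult:
    lrt_statistic: float
    df: int
    p_value: float
    coherent: bool


def coherence_test(
    data: MethylationCountSet,
    sites,
    alpha: float = 0.05,
    df_mode: str = "paper",
) -> CoherenceResult:
    """Test whether all sites of a segment share one rate per sample.

    Zero-coverage cells drop out of both models identically.  ``df = 0``
    (single-site segments) yields statistic 0, p = 1, coherent.
    """
    idx = _check_sites(data, sites)
    c = data.meth_counts[idx].astype(float)
    t = data.unmeth_counts[idx].astype(float)
    r = idx.size

    if df_mode == "paper":
        df = r - 1
    elif df_mode == "per_sample":
        n_eff = int(((c + t).sum(axis=0) > 0).sum())
        df = n_eff * (r - 1)
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")

    if df == 0:
        return CoherenceResult(0.0, 0, 1.0, True)

    # M1: per-site per-sample MLEs (dummy rate for zero-coverage cells:
    # their counts are 0, so they contribute 0 to the log-likelihood)
    total = c + t
    p1 = np.where(total > 0, c / np.where(total > 0, total, 1.0), 0.5)
    ll_m1 = float((xlogy(c, p1) + xlogy(t, 1.0 - p1)).sum())
    # M0: pooled per-sample MLEs
    ll_m0 = segment_log_likelihood(data, idx)

    stat = 2.0 * (ll_m1 - ll_m0)
    if stat < 0.0:
        stat = 0.0
    p_value = float(chi2.sf(stat, df))
    return CoherenceResult(stat, df, p_value, p_value > alpha)


def annotate_segmentation(
    segmentation: Segmentation,
    data: MethylationCountSet,
    alpha: float = 0.05,
    df_mode: str = "paper",
) -> Segmentation:
    """Fill the coherence flag and p-value of every segment in place."""
    for seg in segmentation.segments:
        res = coherence_test(data, seg.site_indices, alpha=alpha, df_mode=df_mode)
        seg.coherent = res.coherent
        seg.coherence_pvalue = res.p_value
    return segmentation
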