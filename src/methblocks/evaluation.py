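"""Breakpoint recovery metrics, annotation enrichment, and entropy summaries.

Breakpoints are identified with the inter-CpG boundary they split: boundary
``b`` separates sites ``b-1`` and ``b`` (local chromosome indices).
Comparing a predicted segmentation to truth classifies boundaries as
*preserved* (matched one-to-one within a tolerance), *lost* (truth only)
or *gained* (prediction only); the candidate-negative universe for
specificity is every remaining inter-CpG boundary of the chromosome.

Enrichment of an annotation class among coherent segments uses a 2x2 table
(coherent / non-coherent x overlapping / non-overlapping) with a two-sided
Fisher exact test -- the sum of hypergeometric probabilities of all tables
with the observed margins that are no more likely than the observed one --
and Benjamini-Hochberg correction across classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .clustering import Segmentation, segment_genome
from .synthetic import NoisyDatasetCollection

__all__ = [
    "BreakpointComparison",
    "MetricEstimate",
    "EnrichmentResult",
    "compare_breakpoints",
    "breakpoint_metrics",
    "bootstrap_ci",
    "fisher_exact_two_sided",
    "enrichment_test",
    "beta_entropy",
    "raw_beta_values",
    "segment_rate_values",
    "run_noise_experiment",
    "summarize_noise_experiment",
]


@dataclass
class BreakpointComparison:
    preserved: int
    lost: int
    gained: int
    candidate_negatives: int


@dataclass
class MetricEstimate:
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    ci_low: dict | None = None
    ci_high: dict | None = None


@dataclass
class EnrichmentResult:
    annotation_class: str
    table: np.ndarray  # [[coherent&overlap, coherent&no], [non-coh&overlap, non-coh&no]]
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


def _check_sorted(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.size and (np.diff(arr) <= 0).any():
        raise ValueError(f"{name} breakpoints must be sorted and unique")
    return arr


def compare_breakpoints(
    truth_bps,
    predicted_bps,
    site_positions,
    tolerance_bp: int = 0,
) -> BreakpointComparison:
    """Classify boundaries as preserved / lost / gained.

    Breakpoints are boundary indices into ``site_positions`` (boundary
    ``b`` lies between sites ``b-1`` and ``b``).  Matching is greedy
    one-to-one; with the default ``tolerance_bp = 0`` only identical
    boundaries match, otherwise boundaries whose genomic gap midpoints lie
    within ``tolerance_bp`` may pair up.
    """
    truth = _check_sorted(np.asarray(truth_bps), "truth")
    pred = _check_sorted(np.asarray(predicted_bps), "predicted")
    positions = np.asarray(site_positions)
    n_boundaries = max(len(positions) - 1, 0)

    if tolerance_bp == 0:
        preserved = int(np.intersect1d(truth, pred).size)
    else:
        mid = lambda b: 0.5 * (positions[int(b) - 1] + positions[int(b)])
        t_pos = np.array([mid(b) for b in truth])
        p_pos = np.array([mid(b) for b in pred])
        used = np.zeros(len(pred), dtype=bool)
        preserved = 0
        for tp in t_pos:  # greedy in genomic order: nearest unused within tol
            cand = np.flatnonzero(~used)
            if cand.size == 0:
                break
            dist = np.abs(p_pos[cand] - tp)
            j = cand[int(np.argmin(dist))]
            if abs(p_pos[j] - tp) <= tolerance_bp:
                used[j] = True
                preserved += 1
    lost = len(truth) - preserved
    gained = len(pred) - preserved
    negatives = n_boundaries - (preserved + lost + gained)
    return BreakpointComparison(preserved, lost, gained, max(negatives, 0))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def breakpoint_metrics(cmp: BreakpointComparison) -> MetricEstimate:
    """Point estimates of sensitivity, specificity, precision and F1."""
    sens = _ratio(cmp.preserved, cmp.preserved + cmp.lost)
    prec = _ratio(cmp.preserved, cmp.preserved + cmp.gained)
    spec = _ratio(cmp.candidate_negatives, cmp.candidate_negatives + cmp.gained)
    if np.isnan(sens) or np.isnan(prec) or (sens + prec) == 0:
        f1 = 0.0 if (cmp.preserved == 0 and (cmp.lost or cmp.gained)) else float("nan")
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return MetricEstimate(sens, spec, prec, f1)


def bootstrap_ci(
    values,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of per-replicate values."""
    vals = np.asarray([v for v in values], dtype=float)
    if vals.size == 0:
        raise ValueError("bootstrap_ci needs at least one value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = np.nanmean(vals[idx], axis=1)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(means, lo)),
        float(np.quantile(means, 1.0 - lo)),
    )


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by hypergeometric enumeration.

    Sums the probabilities of every table with the observed margins whose
    probability does not exceed the observed table's (with a 1 + 1e-7
    relative slack against ties lost to rounding).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a = t[0, 0]
    row1, col1, n = t[0].sum(), t[:, 0].sum(), t.sum()
    if n == 0:
        return 1.0
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(min(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum(), 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _merged_intervals(intervals) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end > start:
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.array(starts), np.array(ends))
    return merged


def _overlap_bp(chrom: str, start0: int, end0: int, merged) -> int:
    if chrom not in merged:
        return 0
    starts, ends = merged[chrom]
    i = int(np.searchsorted(ends, start0, side="right"))
    j = int(np.searchsorted(starts, end0, side="left"))
    if i >= j:
        return 0
    return int(
        np.sum(np.minimum(ends[i:j], end0) - np.maximum(starts[i:j], start0))
    )


def enrichment_test(
    segmentation: Segmentation,
    annotations: dict[str, list],
    min_overlap_bp: int = 1,
    fdr_alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test each annotation class for enrichment among coherent segments.

    ``annotations`` maps class name -> iterable of (chrom, start, end)
    intervals in 0-based half-open BED convention.  Each segment is one
    trial; overlap means a shared span of at least ``min_overlap_bp``.
    p-values are BH-corrected across classes; significant means q < 0.05.
    """
    segs = segmentation.segments
    if any(s.coherent is None for s in segs):
        raise ValueError("segments lack coherence flags; run annotate_segmentation")
    coherent = np.array([bool(s.coherent) for s in segs])
    results: list[EnrichmentResult] = []
    for name in annotations:
        merged = _merged_intervals(annotations[name])
        overlaps = np.array([
            _overlap_bp(s.chrom, s.start_pos - 1, s.end_pos, merged) >= min_overlap_bp
            for s in segs
        ])
        table = np.array([
            [int((coherent & overlaps).sum()), int((coherent & ~overlaps).sum())],
            [int((~coherent & overlaps).sum()), int((~coherent & ~overlaps).sum())],
        ])
        a, b = table[0]
        c, d = table[1]
        if not merged or overlaps.all() or not overlaps.any():
            p = 1.0
            odds = float("nan")
        else:
            p = fisher_exact_two_sided(table)
            if min(a, b, c, d) == 0:  # Haldane correction for the sample OR
                odds = float((a + 0.5) * (d + 0.5)) / float((b + 0.5) * (c + 0.5))
            else:
                odds = float(a * d) / float(b * c)
        results.append(EnrichmentResult(name, table, odds, p))
    if results:
        qvals = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, qvals):
            r.q_value = float(q)
            r.significant = q < fdr_alpha
    return results


def beta_entropy(beta_values, n_bins: int = 20) -> float:
    """Shannon entropy (bits) of beta-values histogrammed over [0, 1]."""
    vals = np.asarray(beta_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite beta-values")
    counts, _ = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def raw_beta_values(data) -> np.ndarray:
    """Per-cell beta-values of covered site/sample cells, flattened."""
    depth = data.total_counts()
    mask = depth > 0
    return (data.meth_counts[mask] / depth[mask]).ravel()


def segment_rate_values(
    segmentation: Segmentation, coherent_only: bool = False
) -> np.ndarray:
    """Pooled per-sample segment rates, flattened over defined cells."""
    rows = [
        s.per_sample_rate
        for s in segmentation.segments
        if not coherent_only or s.coherent
    ]
    if not rows:
        return np.array([])
    vals = np.concatenate(rows)
    return vals[np.isfinite(vals)]


def run_noise_experiment(
    collection: NoisyDatasetCollection,
    scale: float = 100.0,
    tolerance_bp: int = 0,
    nobs_mode: str = "cells",
) -> pd.DataFrame:
    """Segment every replicate and compare its breakpoints to the truth.

    Returns one row per (eta, replicate) with breakpoint counts and the
    four point metrics -- the data behind a noise-robustness curve.
    """
    truth_bps = collection.truth.breakpoints
    slices = collection.baseline.chrom_slices()
    rows = []
    for (eta, k), data in sorted(collection.replicates.items()):
        seg = segment_genome(data, resolution="bic", scale=scale, nobs_mode=nobs_mode)
        pred = seg.breakpoints(data)
        tot = BreakpointComparison(0, 0, 0, 0)
        for chrom, sl in slices.items():
            cmp = compare_breakpoints(
                truth_bps.get(chrom, np.array([], dtype=int)),
                pred.get(chrom, np.array([], dtype=int)),
                data.positions[sl],
                tolerance_bp=tolerance_bp,
            )
            tot.preserved += cmp.preserved
            tot.lost += cmp.lost
            tot.gained += cmp.gained
            tot.candidate_negatives += cmp.candidate_negatives
        met = breakpoint_metrics(tot)
        rows.append({
            "eta": eta, "replicate": k,
            "preserved": tot.preserved, "lost": tot.lost, "gained": tot.gained,
            "sensitivity": met.sensitivity, "specificity": met.specificity,
            "precision": met.precision, "f1": met.f1,
        })
    return pd.DataFrame(rows)


def summarize_noise_experiment(
    df: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-amplitude means with bootstrap CIs over replicates."""
    metrics = ["sensitivity", "specificity", "precision", "f1"]
    out = []
    for eta, grp in df.groupby("eta", sort=True):
        row: dict = {"eta": eta, "n_replicates": len(grp)}
        total = grp[["preserved", "lost", "gained"]].sum(axis=1)
        row["gained_proportion"] = float((grp["gained"] / total).mean())
        for i, mname in enumerate(metrics):
            vals = grp[mname].to_numpy()
            row[mname] = float(np.nanmean(vals))
            lo, hi = bootstrap_ci(
                vals[np.isfinite(vals)] if np.isfinite(vals).any() else vals,
                n_boot=n_boot, level=level,
                seed=None if seed is None else seed + i,
            )
            row[f"{mname}_ci_low"] = lo
            row[f"{mname}_ci_high"] = hi
        out.append(row)
    return pd.DataFrame(out)
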