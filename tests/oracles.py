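"""Independent from-scratch oracles used to cross-check the implementation.

Everything here is deliberately naive: per-sample pure-Python loops with
``math.log`` for the likelihoods, scipy's Student-t density for the
distance penalty, and quadratic re-evaluation of every adjacent pair at
every agglomeration step.  None of it shares code with the package paths
it checks.
"""

import math

import numpy as np
from scipy.stats import t as student_t


def oracle_log_likelihood(data, sites) -> float:
    """Pooled-MLE binomial log-kernel, summed with plain Python loops."""
    total = 0.0
    for j in range(data.n_samples):
        c = sum(int(data.meth_counts[i, j]) for i in sites)
        t = sum(int(data.unmeth_counts[i, j]) for i in sites)
        if c + t == 0:
            continue
        p = c / (c + t)
        if c:
            total += c * math.log(p)
        if t:
            total += t * math.log(1.0 - p)
    return total


def oracle_nllr(data, a, b) -> float:
    v = (
        oracle_log_likelihood(data, a)
        + oracle_log_likelihood(data, b)
        - oracle_log_likelihood(data, list(a) + list(b))
    )
    return max(v, 0.0)


def oracle_penalty(delta_bp: float, scale: float = 100.0) -> float:
    return -math.log(student_t.pdf(delta_bp / scale, df=1))


def oracle_dissimilarity(data, a, b, scale: float = 100.0) -> float:
    ca = {data.chroms[i] for i in a}
    cb = {data.chroms[i] for i in b}
    if ca != cb:
        return math.inf
    delta = min(
        abs(int(data.positions[i]) - int(data.positions[j])) for i in a for j in b
    )
    return oracle_nllr(data, a, b) + oracle_penalty(delta, scale)


def oracle_agglomerate(data, chrom: str, scale: float = 100.0):
    """Quadratic greedy agglomeration re-evaluating every adjacent pair from
    raw counts at every step.  Returns [(left_interval, right_interval,
    cost), ...] with inclusive local-index intervals."""
    sl = data.chrom_slices()[chrom]
    clusters = [[i] for i in range(sl.stop - sl.start)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters) - 1):
            a = [sl.start + x for x in clusters[i]]
            b = [sl.start + x for x in clusters[i + 1]]
            cost = oracle_dissimilarity(data, a, b, scale)
            # strict < keeps the leftmost pair on ties
            if best is None or cost < best[0]:
                best = (cost, i)
        cost, i = best
        li = (clusters[i][0], clusters[i][-1])
        ri = (clusters[i + 1][0], clusters[i + 1][-1])
        merges.append((li, ri, cost))
        clusters[i : i + 2] = [clusters[i] + clusters[i + 1]]
    return merges


def oracle_bh(pvals):
    """Benjamini-Hochberg step-up adjusted p-values, textbook formula."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def oracle_fisher_two_sided(table) -> float:
    """Two-sided Fisher p by direct enumeration with factorials."""
    t = np.asarray(table, dtype=np.int64)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x):
        return math.exp(
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(n - r1 + 1) - math.lgamma(c1 - x + 1)
            - math.lgamma(n - r1 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1.0 + 1e-7):
            total += px
    return min(total, 1.0)
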