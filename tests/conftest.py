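import numpy as np
import pytest
from hypothesis import settings

import methblocks as mb

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def random_countset(rng, m=None, n=None, depth_high=20, p_zero=0.15, n_chroms=1):
    """Small random count set; some cells get zero coverage."""
    m = m if m is not None else int(rng.integers(1, 8))
    n = n if n is not None else int(rng.integers(1, 4))
    depth = rng.integers(0, depth_high, size=(m, n))
    depth[rng.random((m, n)) < p_zero] = 0
    meth = rng.binomial(depth, rng.random((m, n)))
    chrom_of = np.sort(rng.integers(0, n_chroms, size=m))
    chroms = np.array([f"chr{c + 1}" for c in chrom_of], dtype=object)
    positions = np.empty(m, dtype=np.int64)
    for c in np.unique(chrom_of):
        rows = np.flatnonzero(chrom_of == c)
        positions[rows] = np.cumsum(rng.integers(2, 500, size=rows.size))
    return mb.MethylationCountSet(meth, depth - meth, positions, chroms)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def desk_sim():
    """Desk-scale baseline: 2000 CpGs, 10 segments, 5 samples, depth 30,
    adjacent-segment rate differences >= 0.3."""
    data, truth = mb.simulate_baseline(
        n_sites=2000, n_samples=5, n_segments=10, depth_mean=30.0,
        seed=101, min_neighbor_rate_diff=0.3,
    )
    return data, truth


@pytest.fixture(scope="session")
def desk_segmentation(desk_sim):
    """BIC segmentation of the desk-scale baseline with coherence flags.

    Coherence uses the per-sample df convention (df = n_eff * (r - 1)):
    with the r - 1 default, a multi-sample LRT statistic of order n*(r-1)
    is referred to a chi-square with only r - 1 df, so no truly
    homogeneous multi-CpG segment at n = 5 samples would be flagged
    coherent and the fixture would be empty.
    """
    data, _ = desk_sim
    seg = mb.segment_genome(data, resolution="bic")
    mb.annotate_segmentation(seg, data, df_mode="per_sample")
    return seg
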