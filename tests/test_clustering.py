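import math

import numpy as np
import pytest

import methblocks as mb
from methblocks.clustering import bic_path

from conftest import random_countset
from oracles import oracle_agglomerate, oracle_log_likelihood


def make_set(meth, unmeth, positions, chroms=None):
    m = np.asarray(meth).shape[0]
    chroms = chroms if chroms is not None else ["chr1"] * m
    return mb.MethylationCountSet(meth, unmeth, positions, chroms)


class TestBuildDendrogram:
    def test_single_site_no_merges(self):
        data = make_set([[3]], [[7]], [10])
        dend = mb.build_dendrogram(data, "chr1")
        assert dend.leaf_count == 1 and dend.merges == []

    def test_two_sites_forced_merge(self):
        data = make_set([[3], [9]], [[7], [1]], [10, 60])
        dend = mb.build_dendrogram(data, "chr1")
        assert len(dend.merges) == 1
        assert dend.merges[0].cost == pytest.approx(
            mb.dissimilarity(data, [0], [1]), rel=1e-12
        )

    def test_missing_chromosome_errors(self):
        data = make_set([[1]], [[1]], [10])
        with pytest.raises(ValueError):
            mb.build_dendrogram(data, "chrX")

    def test_merge_sequence_matches_quadratic_oracle(self, rng):
        for _ in range(15):
            data = random_countset(rng, m=int(rng.integers(2, 25)), n=int(rng.integers(1, 4)))
            dend = mb.build_dendrogram(data, "chr1")
            expected = oracle_agglomerate(data, "chr1")
            assert len(dend.merges) == len(expected)
            for mg, (li, ri, cost) in zip(dend.merges, expected):
                assert dend.intervals[mg.left] == li
                assert dend.intervals[mg.right] == ri
                assert mg.cost == pytest.approx(cost, rel=1e-9, abs=1e-9)


class TestCutDendrogram:
    @pytest.fixture
    def dend_data(self, rng):
        data = random_countset(rng, m=12, n=2)
        return mb.build_dendrogram(data, "chr1"), data

    def test_root_cut_spans_chromosome(self, dend_data):
        dend, data = dend_data
        (seg,) = mb.cut_dendrogram(dend, 1, data)
        assert seg.n_cpgs == 12
        assert seg.start_pos == data.positions[0]
        assert seg.end_pos == data.positions[-1]

    def test_leaf_cut_is_singletons(self, dend_data):
        dend, data = dend_data
        segs = mb.cut_dendrogram(dend, 12, data)
        assert [s.n_cpgs for s in segs] == [1] * 12

    def test_out_of_range_k_errors(self, dend_data):
        dend, data = dend_data
        with pytest.raises(ValueError):
            mb.cut_dendrogram(dend, 0, data)
        with pytest.raises(ValueError):
            mb.cut_dendrogram(dend, 13, data)

    def test_cuts_are_nested_partitions(self, dend_data):
        dend, data = dend_data
        prev_bounds = None
        for k in range(12, 0, -1):
            segs = mb.cut_dendrogram(dend, k, data)
            assert len(segs) == k
            idx = np.concatenate([s.site_indices for s in segs])
            assert np.array_equal(np.sort(idx), np.arange(12))  # partition
            bounds = {int(s.site_indices[0]) for s in segs}
            if prev_bounds is not None:
                assert bounds < prev_bounds  # one merge removes one boundary
                assert len(prev_bounds - bounds) == 1
            prev_bounds = bounds


class TestBIC:
    def test_single_cell_anchor(self):
        data = make_set([[3]], [[7]], [10])
        segs = mb.cut_dendrogram(mb.build_dendrogram(data, "chr1"), 1, data)
        assert mb.bic_score(segs, data) == pytest.approx(12.21729, abs=1e-5)

    def test_matches_from_scratch_recomputation(self, rng):
        for _ in range(10):
            data = random_countset(rng, m=int(rng.integers(2, 10)), n=2)
            dend = mb.build_dendrogram(data, "chr1")
            for k in (1, data.n_sites):
                segs = mb.cut_dendrogram(dend, k, data)
                ll = sum(oracle_log_likelihood(data, list(s.site_indices)) for s in segs)
                nobs = int(((data.meth_counts + data.unmeth_counts) > 0).sum())
                expected = -2 * ll + k * data.n_samples * math.log(max(nobs, 1))
                assert mb.bic_score(segs, data) == pytest.approx(expected, rel=1e-9)

    def test_likelihood_nonincreasing_with_merges(self, rng):
        data = random_countset(rng, m=20, n=2)
        dend = mb.build_dendrogram(data, "chr1")
        lls = []
        for k in range(20, 0, -1):
            segs = mb.cut_dendrogram(dend, k, data)
            lls.append(sum(mb.segment_log_likelihood(data, s.site_indices) for s in segs))
        assert all(b <= a + 1e-9 for a, b in zip(lls, lls[1:]))

    def test_selection_equals_exhaustive_argmin(self, rng):
        data = random_countset(rng, m=10, n=2)
        dend = mb.build_dendrogram(data, "chr1")
        segs = mb.select_segmentation_bic(dend, data)
        scores = {
            k: mb.bic_score(mb.cut_dendrogram(dend, k, data), data)
            for k in range(1, 11)
        }
        best_k = min(scores, key=lambda k: (scores[k], k))
        assert len(segs) == best_k
        ks, bics = bic_path(dend, data)
        for k in range(1, 11):
            assert bics[k - 1] == pytest.approx(scores[k], rel=1e-9)

    def test_flat_rate_selects_one_segment(self):
        rng = np.random.default_rng(5)
        depth = rng.poisson(30, size=(60, 2))
        meth = rng.binomial(depth, 0.6)
        data = make_set(meth, depth - meth, np.arange(1, 61) * 50)
        dend = mb.build_dendrogram(data, "chr1")
        assert len(mb.select_segmentation_bic(dend, data)) == 1

    def test_sharp_change_recovers_boundary(self):
        rng = np.random.default_rng(7)
        depth = rng.poisson(30, size=(100, 1))
        rates = np.r_[np.full(50, 0.1), np.full(50, 0.9)][:, None]
        meth = rng.binomial(depth, rates)
        data = make_set(meth, depth - meth, np.arange(1, 101) * 50)
        dend = mb.build_dendrogram(data, "chr1")
        segs = mb.select_segmentation_bic(dend, data)
        # the true changepoint must be a selected boundary; with a single
        # sample the cells-based BIC penalty is mild, so a few extra
        # boundaries from sampling noise are tolerated
        assert 50 in {int(s.site_indices[0]) for s in segs}
        assert len(segs) <= 10


class TestSegmentGenome:
    def test_no_segment_spans_chromosomes(self, rng):
        data = random_countset(rng, m=30, n=2, n_chroms=3)
        seg = mb.segment_genome(data)
        for s in seg.segments:
            assert len(set(data.chroms[s.site_indices])) == 1
        idx = np.concatenate([s.site_indices for s in seg.segments])
        assert np.array_equal(np.sort(idx), np.arange(30))

    def test_fixed_k_resolution(self, rng):
        data = random_countset(rng, m=40, n=2)
        seg = mb.segment_genome(data, resolution="k", k=5)
        assert seg.k_per_chrom == {"chr1": 5}
        seg_many = mb.segment_genome(data, resolution="k", k=100)  # clipped
        assert seg_many.k_per_chrom == {"chr1": 40}

    def test_deterministic_and_sample_order_invariant(self, rng):
        data = random_countset(rng, m=25, n=3)
        a = mb.segment_genome(data)
        b = mb.segment_genome(data)
        perm = [2, 0, 1]
        data_p = mb.MethylationCountSet(
            data.meth_counts[:, perm], data.unmeth_counts[:, perm],
            data.positions, data.chroms,
            [data.sample_ids[j] for j in perm],
        )
        c = mb.segment_genome(data_p)
        for x in (b, c):
            assert [tuple(s.site_indices[[0, -1]]) for s in x.segments] == [
                tuple(s.site_indices[[0, -1]]) for s in a.segments
            ]
        assert a.bic == b.bic

    def test_zero_coverage_sites_are_retained(self):
        data = make_set(
            [[3], [0], [9]], [[7], [0], [1]], [10, 20, 30]
        )
        seg = mb.segment_genome(data, resolution="k", k=1)
        assert seg.segments[0].n_cpgs == 3
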