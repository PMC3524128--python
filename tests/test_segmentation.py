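import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microcna.segmentation import (
    NO_SPLIT,
    SegmentationParams,
    aberrant_segments,
    best_interval,
    best_split,
    segment_gene_profile,
)


def brute_force_best_split(values, min_probes):
    """Independent exhaustive scan of the Welch-style split statistic."""
    n = len(values)
    if n < 2 * min_probes:
        return NO_SPLIT
    best_i, best_s = -1, -1.0
    for i in range(min_probes, n - min_probes + 1):
        left, right = values[:i], values[i:]
        diff = abs(left.mean() - right.mean())
        se = np.sqrt(left.var() / len(left) + right.var() / len(right))
        if se == 0:
            s = np.inf if diff > 0 else 0.0
        else:
            s = diff / se
        if s > best_s:
            best_i, best_s = i, s
    return best_i, best_s


class TestBestSplit:
    def test_exact_step_found(self):
        values = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
        idx, stat = best_split(values, min_probes=2)
        assert idx == 5
        assert stat == np.inf

    def test_constant_vector_no_signal(self):
        idx, stat = best_split(np.zeros(20), min_probes=2)
        assert stat == 0.0

    def test_too_short_input_sentinel(self):
        assert best_split(np.array([1.0, 2.0, 3.0]), min_probes=2) == NO_SPLIT

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=30)
        idx, stat = best_split(values, min_probes=5)
        bidx, bstat = brute_force_best_split(values, 5)
        assert idx == bidx
        assert stat == pytest.approx(bstat, rel=1e-9)


class TestSegmentGeneProfile:
    def test_all_zeros_single_neutral_segment(self):
        positions = np.arange(0, 40_000, 200)
        segs = segment_gene_profile(np.zeros(200), positions)
        assert len(segs) == 1
        assert segs[0].call == "neutral"
        assert (segs[0].probe_index_start, segs[0].probe_index_end) == (0, 200)

    def test_noiseless_step_recovered_exactly(self):
        positions = np.arange(0, 40_000, 200)
        values = np.concatenate([np.zeros(100), np.full(100, 0.6)])
        segs = segment_gene_profile(values, positions)
        assert len(segs) == 2
        assert segs[0].probe_index_end == 100
        assert segs[1].call == "gain"
        assert segs[1].mean_log2 == pytest.approx(0.6)

    def test_noiseless_interior_implants_recovered_exactly(self):
        """Runs <= 50 probes with <= 2 true breakpoints, zero noise: exact recovery."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(20, 51))
            kind = rng.integers(3)
            values = np.zeros(n)
            if kind == 0:  # single step
                cut = int(rng.integers(6, n - 5))
                values[cut:] = 0.6
                expected = {0, cut, n}
            elif kind == 1:  # interior bump
                i = int(rng.integers(5, n - 11))
                j = int(rng.integers(i + 5, min(i + 30, n - 5) + 1))
                values[i:j] = -0.6
                expected = {0, i, j, n}
            else:  # constant
                expected = {0, n}
            segs = segment_gene_profile(values, np.arange(n) * 200)
            got = {s.probe_index_start for s in segs} | {n}
            assert got == expected, (kind, n, expected, got)

    def test_noisy_step_breakpoints_within_two_probes(self):
        """Step +0.6 over probes 80-119, noise sd 0.15: both breakpoints within
        +/-2 probes in at least 90% of 50 seeded replicates."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            values = rng.normal(0, 0.15, size=200)
            values[80:120] += 0.6
            segs = segment_gene_profile(values, np.arange(200) * 200)
            gains = [s for s in segs if s.call == "gain"]
            if len(gains) == 1 and abs(gains[0].probe_index_start - 80) <= 2 and abs(
                gains[0].probe_index_end - 120
            ) <= 2:
                hits += 1
        assert hits >= 45

    def test_short_run_single_segment(self):
        segs = segment_gene_profile(np.array([0.5, 0.6]), np.array([0, 200]))
        assert len(segs) == 1
        assert segs[0].call == "gain"

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=80), st.integers(0, 10))
    def test_segments_tile_probe_run(self, values, jitter):
        """Segments partition [0, n) without gaps or overlaps for any input."""
        values = np.asarray(values)
        positions = np.cumsum(np.full(len(values), 200)) + jitter
        segs = segment_gene_profile(values, positions)
        assert segs[0].probe_index_start == 0
        assert segs[-1].probe_index_end == len(values)
        for a, b in zip(segs, segs[1:]):
            assert a.probe_index_end == b.probe_index_start
        assert all(s.n_probes == s.probe_index_end - s.probe_index_start >= 1 for s in segs)

    def test_monotone_sensitivity_in_split_threshold(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 0.15, size=300)
        values[40:90] += 0.6
        values[200:210] -= 0.6
        positions = np.arange(300) * 200
        n_prev = None
        for thr in (12.0, 8.0, 6.0, 4.0):
            params = SegmentationParams(split_stat_threshold=thr, interval_stat_threshold=max(thr, 6.0))
            n = len(segment_gene_profile(values, positions, params))
            if n_prev is not None:
                assert n >= n_prev
            n_prev = n


class TestBestInterval:
    def test_interior_bump_found_exactly(self):
        values = np.zeros(100)
        values[40:50] = 1.0
        i, j, stat = best_interval(values, min_probes=5)
        assert (i, j) == (40, 50)
        assert stat == np.inf

    def test_no_admissible_interval(self):
        assert best_interval(np.ones(6), min_probes=5) == (-1, -1, 0.0)


class TestAberrantSegments:
    def _seg(self, mean):
        from microcna.segmentation import Segment

        call = "gain" if mean > 0.30 else ("loss" if mean < -0.30 else "neutral")
        return Segment("S", "G", "chr1", 0, 10, 0, 2000, 10, mean, call)

    def test_threshold_is_strict(self):
        segs = [self._seg(0.30), self._seg(-0.31), self._seg(0.0), self._seg(0.8)]
        kept = aberrant_segments(segs)
        assert [s.mean_log2 for s in kept] == [-0.31, 0.8]

    def test_empty_input(self):
        assert aberrant_segments([]) == []
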