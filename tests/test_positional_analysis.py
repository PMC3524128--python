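import numpy as np
import pytest

from microcna.aberration_calling import MicroAberration
from microcna.io_formats import GeneWindow
from microcna.positional_analysis import (
    QUADRANT_LABELS,
    five_prime_only_breakdown,
    promoter_interval,
    quadrant_bounds,
    tally_quadrants,
)
from microcna.segmentation import Segment


def window(strand="+", start=5000, end=15000, pad=1000, utr5=None):
    u5s, u5e = (utr5 if utr5 else (None, None))
    return GeneWindow.from_span("G1", "chr1", strand, start, end, pad_bp=pad,
                                utr5_start=u5s, utr5_end=u5e)


def micro(start, end, gene="G1", kind="micro-amp"):
    seg = Segment("S1", gene, "chr1", 0, 5, start, end, 5, 0.6, "gain")
    return MicroAberration(segment=seg, kind=kind)


class TestQuadrantBounds:
    def test_plus_strand_left_to_right(self):
        w = GeneWindow.from_span("G1", "chr1", "+", 1000, 3000, pad_bp=1000)  # window [0, 4000)
        bounds = quadrant_bounds(w)
        assert bounds == [
            ("5'End", 0, 1000), ("5'Mid", 1000, 2000), ("3'Mid", 2000, 3000), ("3'End", 3000, 4000)
        ]

    def test_minus_strand_five_prime_is_rightmost(self):
        w = GeneWindow.from_span("G1", "chr1", "-", 1000, 3000, pad_bp=1000)
        bounds = dict((label, (lo, hi)) for label, lo, hi in quadrant_bounds(w))
        assert bounds["5'End"] == (3000, 4000)
        assert bounds["3'End"] == (0, 1000)

    def test_remainder_absorbed_by_last_interval(self):
        w = GeneWindow.from_span("G1", "chr1", "+", 100, 1103, pad_bp=100)  # length 1203
        bounds = quadrant_bounds(w)
        lengths = [hi - lo for _, lo, hi in bounds]
        assert lengths == [300, 300, 300, 303]

    def test_partition_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            start = int(rng.integers(0, 10_000))
            length = int(rng.integers(100, 50_000))
            strand = "+" if rng.random() < 0.5 else "-"
            w = GeneWindow.from_span("G", "chr1", strand, start + 1000, start + 1000 + length, pad_bp=1000)
            bounds = sorted((lo, hi) for _, lo, hi in quadrant_bounds(w))
            assert bounds[0][0] == w.window_start
            assert bounds[-1][1] == w.window_end
            for (alo, ahi), (blo, bhi) in zip(bounds, bounds[1:]):
                assert ahi == blo


class TestTallyQuadrants:
    def test_whole_window_instance_affects_all(self):
        w = window()
        summary = tally_quadrants([micro(w.window_start, w.window_end)], [w])
        assert all(p == 1.0 for p in summary.proportions.values())

    def test_five_prime_confined_instances(self):
        w = window(pad=1000, start=5000, end=15000)  # window [4000, 16000), quadrant 3000
        micros = [micro(4100, 4200), micro(4500, 6000)]
        summary = tally_quadrants(micros, [w])
        assert summary.proportions["5'End"] == 1.0
        assert summary.proportions["5'Mid"] == 0.0
        assert summary.possible_count == 2

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            tally_quadrants([micro(0, 10, gene="NOPE")], [window()])

    def test_matches_per_base_brute_force(self):
        """Quadrant flags equal a per-base overlap oracle on random small cases."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.integers(40, 400))
            w = GeneWindow.from_span("G1", "chr1", strand, 1000, 1000 + glen, pad_bp=50)
            s = int(rng.integers(w.window_start, w.window_end - 1))
            e = int(rng.integers(s + 1, w.window_end + 1))
            m = micro(s, e)
            summary = tally_quadrants([m], [w])
            # oracle: per-base membership of the window split in 4, re-labelled by strand
            length = w.window_end - w.window_start
            q = length // 4
            base_quadrant = np.minimum((np.arange(length)) // q if q else 0, 3)
            labels = QUADRANT_LABELS if strand == "+" else QUADRANT_LABELS[::-1]
            covered = np.zeros(length, dtype=bool)
            covered[s - w.window_start : e - w.window_start] = True
            for gi, label in enumerate(labels):
                expect = bool(np.any(covered & (base_quadrant == gi)))
                assert (summary.proportions[label] == 1.0) == expect, (strand, s, e)

    def test_strand_flip_symmetry(self):
        """Mirroring coordinates and flipping strand leaves the summary invariant."""
        w = window(strand="+", start=5000, end=15000, pad=1000, utr5=(5000, 5300))
        micros = [micro(4100, 4600), micro(7000, 9000), micro(15200, 15900)]
        summary = tally_quadrants(micros, [w])

        # mirror around the window midpoint axis
        origin = w.window_start + w.window_end
        wm = GeneWindow.from_span(
            "G1", "chr1", "-", origin - w.gene_end, origin - w.gene_start, pad_bp=1000,
            utr5_start=origin - 5300, utr5_end=origin - 5000,
        )
        micros_m = [micro(origin - m.segment.genomic_end, origin - m.segment.genomic_start) for m in micros]
        summary_m = tally_quadrants(micros_m, [wm])
        assert summary.proportions == summary_m.proportions
        assert summary.promoter_rate == summary_m.promoter_rate
        assert summary.utr5_rate == summary_m.utr5_rate


class TestPromoterAndUtr5:
    def test_promoter_interval_orientation(self):
        wp = window(strand="+", pad=1000)
        assert promoter_interval(wp) == (wp.window_start, wp.gene_start)
        wm = window(strand="-", pad=1000)
        assert promoter_interval(wm) == (wm.gene_end, wm.window_end)

    def test_no_five_prime_only_instances_gives_na(self):
        w = window()
        prom, utr5 = five_prime_only_breakdown([micro(w.window_start, w.window_end)], [w])
        assert prom is None and utr5 is None

    def test_five_prime_only_promoter_hit(self):
        w = window(pad=1000, utr5=(5000, 5300))
        m = micro(4100, 4600)  # inside the upstream pad: 5'End quadrant and promoter
        prom, utr5 = five_prime_only_breakdown([m], [w])
        assert prom == 1.0
        assert utr5 == 0.0

    def test_biased_generator_promoter_exceeds_utr5(self, small_design):
        """5'-biased implants centred upstream of the TSS hit promoters more than 5'UTRs."""
        from microcna.synthetic_cohort import CohortSimParams, simulate_cohort
        from microcna.aberration_calling import call_aberrations
        from microcna.segmentation import segment_cohort

        windows, probes = small_design
        cohort = simulate_cohort(
            windows, probes,
            CohortSimParams(n_samples=24, macro_rate=0.0, micro_rate=2.0,
                            micro_span_range=(1000, 4000), placement="5prime_bias", seed=6),
        )
        segs = segment_cohort(cohort.log_ratio_matrix, windows)
        micros, _ = call_aberrations(segs)
        summary = tally_quadrants(micros, windows)
        assert summary.proportions["5'End"] > max(
            summary.proportions["5'Mid"], summary.proportions["3'Mid"], summary.proportions["3'End"]
        )
        assert summary.promoter_rate is not None and summary.promoter_rate > 0.5
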