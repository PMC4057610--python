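"""Contig assembly, B/R scoring and candidate calling."""

import numpy as np
import pytest

from gapseq import (
    CallerParams,
    GenomicInterval,
    MappedRead,
    MaskTrack,
    build_contigs,
    call_candidates,
    compute_rank,
    join_contigs,
)
from gapseq.contigs import JoinedContig


def reads_from(spans, chrom="c"):
    return [
        MappedRead(GenomicInterval(chrom, s, e), f"r{i}")
        for i, (s, e) in enumerate(spans)
    ]


class TestBuildContigs:
    def test_two_overlapping_reads_give_b_1_5(self):
        contigs = build_contigs(reads_from([(0, 300), (100, 400)]))
        assert len(contigs) == 1
        c = contigs[0]
        assert c.interval == GenomicInterval("c", 0, 400)
        assert c.read_bp == 600
        assert c.b == pytest.approx(1.5)

    def test_single_read_has_b_1(self):
        (c,) = build_contigs(reads_from([(0, 279)]))
        assert c.b == 1.0

    def test_disjoint_reads_make_separate_contigs(self):
        contigs = build_contigs(reads_from([(0, 100), (200, 300)]))
        assert [c.b for c in contigs] == [1.0, 1.0]
        assert len(contigs) == 2

    def test_abutting_reads_merge(self):
        (c,) = build_contigs(reads_from([(0, 100), (100, 200)]))
        assert c.interval.length == 200 and c.n_reads == 2

    def test_empty_input(self):
        assert build_contigs([]) == []

    def test_read_bp_conserved_and_b_at_least_1(self, rng):
        starts = rng.integers(0, 50_000, 300)
        lengths = rng.integers(50, 500, 300)
        reads = reads_from(list(zip(starts, starts + lengths)))
        contigs = build_contigs(reads)
        assert sum(c.read_bp for c in contigs) == sum(r.length for r in reads)
        assert sum(c.n_reads for c in contigs) == len(reads)
        assert all(c.b >= 1.0 for c in contigs)

    def test_matches_per_base_coverage_oracle(self, rng):
        """Contigs are exactly the maximal runs of covered bases."""
        for _ in range(5):
            n = int(rng.integers(5, 120))
            starts = rng.integers(0, 50_000, n)
            lengths = rng.integers(1, 600, n)
            reads = reads_from(list(zip(starts, starts + lengths)))
            coverage = np.zeros(51_000, dtype=int)
            for r in reads:
                coverage[r.interval.start : r.interval.end] += 1
            padded = np.concatenate([[0], (coverage > 0).astype(int), [0]])
            diffs = np.diff(padded)
            runs = list(zip(np.where(diffs == 1)[0], np.where(diffs == -1)[0]))
            contigs = build_contigs(reads)
            assert [(c.interval.start, c.interval.end) for c in contigs] == runs


class TestJoinContigs:
    def _join(self, spans, gap_reads=(), params=CallerParams()):
        # each span is one 2x-covered pileup: two identical reads -> B = 2
        reads = []
        for i, (s, e) in enumerate(spans):
            reads += reads_from([(s, e), (s, e)])
        reads += reads_from(gap_reads)
        contigs = build_contigs(reads)
        return join_contigs(contigs, reads, None, params), reads

    def test_gap_within_7500_joins(self):
        joined, _ = self._join([(0, 400), (5_000, 5_800)])
        assert len(joined) == 1
        assert joined[0].span == GenomicInterval("c", 0, 5_800)

    def test_gap_beyond_7500_does_not_join(self):
        joined, _ = self._join([(0, 400), (8_400, 8_800)])
        assert joined == []

    def test_joining_is_transitive(self):
        # A-B and B-C gaps of 7000; A-C far beyond the limit
        joined, _ = self._join([(0, 400), (7_400, 7_800), (14_800, 15_200)])
        assert len(joined) == 1
        assert joined[0].n_contigs == 3

    def test_low_b_reads_inside_span_count_toward_read_bp(self):
        joined, _ = self._join([(0, 400), (5_000, 5_400)], gap_reads=[(2_000, 2_300)])
        (jc,) = joined
        assert jc.read_bp == 2 * 400 + 2 * 400 + 300
        assert jc.n_reads == 5

    def test_read_outside_span_midpoint_excluded(self):
        # singleton read past the last member contig: midpoint 5,700
        # lies beyond the span end 5,400 -> not collected
        joined, _ = self._join([(0, 400), (5_000, 5_400)], gap_reads=[(5_500, 5_900)])
        assert joined[0].span.end == 5_400
        assert joined[0].n_reads == 4
        # a read overlapping the last member merges into it and counts fully
        joined, _ = self._join([(0, 400), (5_000, 5_400)], gap_reads=[(5_380, 5_680)])
        assert joined[0].span.end == 5_680
        assert joined[0].n_reads == 5
        assert joined[0].read_bp == 1_600 + 300

    def test_single_high_b_contig_is_discarded(self):
        joined, _ = self._join([(0, 400)])
        assert joined == []

    def test_fully_masked_span_dropped_with_warning(self, caplog):
        reads = reads_from([(0, 400), (0, 400), (5_000, 5_400), (5_000, 5_400)])
        contigs = build_contigs(reads)
        mask = MaskTrack([GenomicInterval("c", 0, 6_000)])
        with caplog.at_level("WARNING", logger="gapseq"):
            assert join_contigs(contigs, reads, mask, CallerParams()) == []
        assert "fully-masked" in caplog.text

    def test_rejoining_output_changes_nothing(self, rng):
        starts = np.sort(rng.integers(0, 200_000, 400))
        lengths = rng.integers(100, 400, 400)
        reads = reads_from(list(zip(starts, starts + lengths)))
        contigs = build_contigs(reads)
        joined = join_contigs(contigs, reads, None)
        spans = [(j.span.start, j.span.end) for j in joined]
        again = join_contigs(
            [c for j in joined for c in j.members], reads, None
        )
        assert [(j.span.start, j.span.end) for j in again] == spans


class TestRank:
    def test_rank_formula(self):
        jc = JoinedContig(
            GenomicInterval("c", 0, 10_000), (), (), 6_000, 2_000, 0.0
        )
        assert compute_rank(jc) == pytest.approx(0.75)

    def test_unmasked_full_coverage_rank_1(self):
        jc = JoinedContig(GenomicInterval("c", 0, 5_000), (), (), 5_000, 0, 0.0)
        assert compute_rank(jc) == pytest.approx(1.0)

    def test_rank_linear_in_read_bp(self):
        base = JoinedContig(GenomicInterval("c", 0, 10_000), (), (), 3_000, 1_000, 0.0)
        double = JoinedContig(GenomicInterval("c", 0, 10_000), (), (), 6_000, 1_000, 0.0)
        assert compute_rank(double) == pytest.approx(2 * compute_rank(base))

    def test_fully_masked_span_raises(self):
        jc = JoinedContig(GenomicInterval("c", 0, 1_000), (), (), 500, 1_000, 0.0)
        with pytest.raises(ValueError, match="masked"):
            compute_rank(jc)


class TestCallCandidates:
    def test_uniform_sparse_reads_give_no_candidates(self):
        reads = reads_from([(i * 1_000, i * 1_000 + 300) for i in range(50)])
        assert call_candidates(reads) == []

    def test_input_order_irrelevant(self, rng):
        starts = rng.integers(0, 30_000, 200)
        reads = reads_from(list(zip(starts, starts + 279)))
        forward = call_candidates(reads)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        backward = call_candidates(shuffled)
        assert [(j.span, j.rank) for j in forward] == [
            (j.span, j.rank) for j in backward
        ]

    def test_raising_thresholds_never_adds_candidates(self, rng):
        starts = rng.integers(0, 40_000, 400)
        reads = reads_from(list(zip(starts, starts + 279)))
        base = len(call_candidates(reads, params=CallerParams()))
        stricter_b = len(call_candidates(reads, params=CallerParams(min_b=1.8)))
        stricter_r = len(call_candidates(reads, params=CallerParams(min_r=1.2)))
        assert stricter_b <= base and stricter_r <= base

    def test_mask_heavy_reads_dropped(self, caplog):
        reads = reads_from([(0, 400), (0, 400)])
        mask = MaskTrack([GenomicInterval("c", 0, 300)])  # 75% of each read
        with caplog.at_level("WARNING", logger="gapseq"):
            assert call_candidates(reads, mask) == []
        assert "dropped 2/2" in caplog.text

    def test_detects_planted_palindrome_with_no_false_calls(self):
        """End-to-end on simulated protocol reads, fixed seed."""
        from gapseq import GapfSimConfig, call_candidates, make_genome, simulate_gapf_reads

        cfg = GapfSimConfig(seed=42)
        sim = make_genome(cfg, with_sequence=False)
        reads = simulate_gapf_reads(sim)
        hits = call_candidates(reads, sim.mask)
        a0, a1 = sim.truths[0].arm_span()
        arm = GenomicInterval(cfg.chrom, a0, a1)
        assert sum(h.span.overlaps(arm) for h in hits) == 1
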