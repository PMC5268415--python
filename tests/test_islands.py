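import numpy as np
import pytest
from scipy import stats

from hmcscan.intervals import ChromSizes, GenomicInterval, IntervalSet
from hmcscan.islands import (
    CallerParams,
    WindowTrack,
    background_rate,
    bh_adjust,
    call_islands,
    count_windows,
    deduplicate_fragments,
    eligible_threshold,
    form_islands,
)
from hmcscan.simulate import simulate_fragments
from oracles import bh_by_hand, brute_force_islands, poisson_upper_tail

CS = ChromSizes({"chr1": 1_000_000}, sex_chroms=set())
PARAMS = CallerParams(effective_genome_fraction=1.0)


def frag(chrom, start, strand="+", length=200):
    return GenomicInterval(chrom, start, start + length, strand)


class TestDeduplicate:
    def test_identical_fragments_reduced_to_r(self):
        frags = IntervalSet([frag("chr1", 100)] * 3)
        assert len(deduplicate_fragments(frags, r=1)) == 1

    def test_distinct_unchanged(self):
        frags = IntervalSet([frag("chr1", s) for s in (0, 300, 600)])
        assert len(deduplicate_fragments(frags, r=1)) == 3

    def test_mixed_multiplicities(self):
        frags = IntervalSet([frag("chr1", 0)] + [frag("chr1", 500)] * 4)
        out = deduplicate_fragments(frags, r=2)
        assert len(out) == 3  # 1xa + 2xb


class TestCountWindows:
    def test_no_fragments_all_zero(self):
        tracks = count_windows(IntervalSet([]), PARAMS, CS)
        assert tracks["chr1"].counts.sum() == 0

    def test_plus_strand_shift(self):
        # read starting at 0, fragment_size 200 -> point 100 -> window [100,200)
        tracks = count_windows(IntervalSet([frag("chr1", 0, "+")]), PARAMS, CS)
        assert tracks["chr1"].counts[1] == 1
        assert tracks["chr1"].counts.sum() == 1

    def test_minus_strand_shift(self):
        # read covering [1000,1200), minus strand: point = 1199-100 = 1099
        tracks = count_windows(IntervalSet([frag("chr1", 1000, "-")]), PARAMS, CS)
        assert tracks["chr1"].counts[10] == 1

    def test_count_conservation(self):
        rng = np.random.default_rng(5)
        frags = IntervalSet([
            frag("chr1", int(s), "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(0, 999_000, size=1000)
        ])
        tracks = count_windows(frags, PARAMS, CS)
        assert tracks["chr1"].counts.sum() == 1000

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="chrZ"):
            count_windows(IntervalSet([frag("chrZ", 0)]), PARAMS, CS)


class TestEligibleThreshold:
    def test_lambda_one_p02(self):
        # P(X>=2)=0.2642, P(X>=3)=0.0803 for Poisson(1)
        assert eligible_threshold(1.0, 0.2) == 3

    def test_p0_near_one_gives_any_nonzero(self):
        assert eligible_threshold(0.5, 0.9999) == 1

    @pytest.mark.parametrize("lam", [0.25, 0.5, 2.0, 7.3])
    @pytest.mark.parametrize("p0", [0.05, 0.2, 0.5])
    def test_matches_brute_force_tail_summation(self, lam, p0):
        l0 = eligible_threshold(lam, p0)
        assert poisson_upper_tail(l0, lam) < p0
        assert l0 == 1 or poisson_upper_tail(l0 - 1, lam) >= p0


class TestFormIslands:
    def track(self, counts):
        return WindowTrack("chr1", 100, np.asarray(counts, dtype=np.int64))

    def test_no_eligible_windows(self):
        assert form_islands(self.track([0, 1, 0]), l0=2, gap_g=100,
                            lambda_bg=0.5) == []

    def test_gap_rule_splits_runs(self):
        counts = [5, 5, 0, 0, 0, 5]
        islands = form_islands(self.track(counts), l0=2, gap_g=100,
                               lambda_bg=0.5)
        assert [(i.span.start, i.span.end) for i in islands] == \
            [(0, 200), (500, 600)]

    def test_gap_included_in_span(self):
        counts = [5, 0, 5]
        islands = form_islands(self.track(counts), l0=2, gap_g=100,
                               lambda_bg=0.5)
        assert [(i.span.start, i.span.end) for i in islands] == [(0, 300)]

    def test_against_brute_force_scan(self):
        rng = np.random.default_rng(17)
        for gap_w in (0, 1, 2):
            counts = rng.poisson(1.0, size=500)
            islands = form_islands(self.track(counts), l0=3,
                                   gap_g=100 * gap_w, lambda_bg=1.0)
            want = brute_force_islands(counts, 3, gap_w)
            got = [(i.span.start // 100, i.span.end // 100 - 1)
                   for i in islands]
            assert got == want

    def test_score_is_sum_of_neglog_pmf_over_eligible(self):
        counts = [4, 0, 3]
        isl = form_islands(self.track(counts), l0=3, gap_g=100,
                           lambda_bg=1.0)[0]
        want = -(stats.poisson.logpmf(4, 1.0) + stats.poisson.logpmf(3, 1.0))
        assert isl.score == pytest.approx(float(want))

    def test_spans_never_overlap(self):
        rng = np.random.default_rng(29)
        counts = rng.poisson(2.0, size=400)
        islands = form_islands(self.track(counts), l0=4, gap_g=200,
                               lambda_bg=2.0)
        spans = sorted((i.span.start, i.span.end) for i in islands)
        assert all(spans[i][1] <= spans[i + 1][0] for i in range(len(spans) - 1))


def test_bh_adjustment_matches_hand_computation():
    pvals = [0.01, 0.02, 0.03, 0.04]
    assert np.allclose(bh_adjust(pvals), [0.04, 0.04, 0.04, 0.04])
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = rng.random(int(rng.integers(1, 30)))
        assert np.allclose(bh_adjust(p), bh_by_hand(p.tolist()))
        assert np.all(bh_adjust(p) >= p - 1e-12)  # q >= p


class TestEndToEnd:
    def test_background_level_island_not_retained(self):
        # matched treatment/control at equal rates: nothing survives q<0.01
        treat, ctrl = simulate_fragments(IntervalSet([]), CS,
                                         n_control=20_000, fold=1.0, seed=42)
        assert len(call_islands(treat, ctrl, CS, PARAMS)) <= 1

    def test_planted_region_recovered(self):
        planted = GenomicInterval("chr1", 500_000, 502_000)
        treat, ctrl = simulate_fragments(IntervalSet([planted]), CS,
                                         n_control=20_000, fold=10.0, seed=7)
        called = call_islands(treat, ctrl, CS, PARAMS)
        hits = [c for c in called
                if c.span.start < planted.end and planted.start < c.span.end]
        assert len(hits) == 1
        overlap = (min(hits[0].span.end, planted.end)
                   - max(hits[0].span.start, planted.start))
        assert overlap >= 0.9 * planted.length

    def test_fdr_monotonicity(self):
        planted = IntervalSet([GenomicInterval("chr1", 100_000 * k, 100_000 * k + 2000)
                               for k in range(1, 6)])
        treat, ctrl = simulate_fragments(planted, CS, n_control=20_000,
                                         fold=4.0, seed=13)
        loose = call_islands(treat, ctrl, CS,
                             CallerParams(effective_genome_fraction=1.0,
                                          fdr_q=0.05))
        strict = call_islands(treat, ctrl, CS,
                              CallerParams(effective_genome_fraction=1.0,
                                           fdr_q=0.01))
        strict_spans = {(i.span.start, i.span.end) for i in strict}
        loose_spans = {(i.span.start, i.span.end) for i in loose}
        assert strict_spans <= loose_spans

    def test_gap_monotonicity(self):
        treat, ctrl = simulate_fragments(
            IntervalSet([GenomicInterval("chr1", 300_000, 310_000)]),
            CS, n_control=20_000, fold=5.0, seed=19)
        counts = {}
        for gap in (0, 100, 200, 400):
            p = CallerParams(effective_genome_fraction=1.0, gap_g=gap)
            counts[gap] = len(call_islands(treat, ctrl, CS, p))
        gaps = sorted(counts)
        assert all(counts[gaps[i]] >= counts[gaps[i + 1]]
                   for i in range(len(gaps) - 1))


def test_background_rate_definition():
    lam = background_rate(10_000, PARAMS, CS)
    assert lam == pytest.approx(10_000 * 100 / 1_000_000)
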