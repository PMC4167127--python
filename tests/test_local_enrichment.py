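"""Binomial enrichment, adjustment, region enumeration and selection."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from locenrich.local_enrichment import (
    EnrichmentResult,
    RegionCandidate,
    adjust_pvalue,
    analyze_motif,
    binomial_pvalue,
    count_in_region,
    enumerate_regions,
    log_adjusted_pvalue,
    min_raw_pvalue,
    group_regions,
    motif_evalue,
    raw_pvalues,
    score_regions,
    select_nonoverlapping,
    success_probability,
)
from locenrich.scanner import BestSite, ScanResult


def make_scan(starts, N, motif_id="M", threshold=5.0):
    sites = [BestSite(i, s, "+", 10.0) for i, s in enumerate(starts)]
    return ScanResult(motif_id, threshold, sites, N, len(starts))


class TestSuccessProbability:
    def test_full_region(self):
        assert success_probability(10, 10) == 1.0

    def test_direct_ratio(self):
        assert success_probability(10, 100) == pytest.approx(0.1)

    @pytest.mark.parametrize("M,N", [(0, 10), (11, 10), (-1, 5)])
    def test_out_of_range_rejected(self, M, N):
        with pytest.raises(ValueError):
            success_probability(M, N)


class TestBinomialPvalue:
    def test_zero_successes_is_one(self):
        assert binomial_pvalue(0, 10, 0.3) == 1.0

    @pytest.mark.parametrize("S,r", [(5, 0.1), (8, 0.5), (12, 0.9)])
    def test_all_successes_closed_form(self, S, r):
        assert binomial_pvalue(S, S, r) == pytest.approx(r**S, rel=1e-12)

    def test_matches_direct_summation(self):
        # P(X >= 5), X ~ Bin(10, 0.2), by exact term-by-term summation
        expected = float(
            sum(
                Fraction(math.comb(10, k))
                * Fraction(1, 5) ** k
                * Fraction(4, 5) ** (10 - k)
                for k in range(5, 11)
            )
        )
        assert binomial_pvalue(5, 10, 0.2) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_pvalue(5, 4, 0.5)
        with pytest.raises(ValueError):
            binomial_pvalue(1, 4, 1.5)


class TestAdjustPvalue:
    def test_single_test_identity(self):
        assert adjust_pvalue(0.037, 1) == pytest.approx(0.037, rel=1e-14)

    def test_extremes_fixed(self):
        assert adjust_pvalue(0.0, 50) == 0.0
        assert adjust_pvalue(1.0, 50) == 1.0

    def test_matches_arbitrary_precision(self):
        exact = float(1 - Fraction(99, 100) ** 100)
        assert adjust_pvalue(0.01, 100) == pytest.approx(exact, rel=1e-12)

    @given(
        st.floats(0.0, 1.0, allow_nan=False),
        st.floats(0.0, 1.0, allow_nan=False),
        st.integers(1, 10_000),
        st.integers(1, 10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_p_and_n(self, p1, p2, n1, n2):
        lo_p, hi_p = sorted((p1, p2))
        lo_n, hi_n = sorted((n1, n2))
        assert adjust_pvalue(lo_p, lo_n) <= adjust_pvalue(hi_p, lo_n) + 1e-15
        assert adjust_pvalue(lo_p, lo_n) <= adjust_pvalue(lo_p, hi_n) + 1e-15
        assert 0.0 <= adjust_pvalue(p1, n1) <= 1.0

    def test_log_form_tracks_linear_form(self):
        for p in (1e-3, 1e-6, 1e-9):
            log_adj = log_adjusted_pvalue(math.log(p), 50)
            assert log_adj == pytest.approx(math.log(adjust_pvalue(p, 50)), rel=1e-6)
        # far below underflow, the log form stays finite and ordered
        assert log_adjusted_pvalue(-2000.0, 100) == pytest.approx(
            math.log(100) - 2000.0
        )


class TestEvalue:
    def test_ceiling_is_compendium_size(self):
        assert motif_evalue(1.0, 884) == 884

    def test_zero(self):
        assert motif_evalue(0.0, 884) == 0.0

    def test_direct_product(self):
        assert motif_evalue(0.5, 2) == 1.0


class TestEnumerateRegions:
    def test_central_parity_enumeration(self):
        regions = enumerate_regions(5, "central", 1, 5, 1)
        assert [(r.M, r.start) for r in regions] == [(1, 2), (3, 1), (5, 0)]

    def test_local_single_width(self):
        regions = enumerate_regions(4, "local", 2, 2, 1)
        assert [(r.start, r.M) for r in regions] == [(0, 2), (1, 2), (2, 2)]

    def test_min_width_above_n_is_clamped_to_n(self):
        regions = enumerate_regions(4, "local", min_width=10, max_width=10)
        assert [(r.start, r.M) for r in regions] == [(0, 4)]

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            enumerate_regions(10, "local", 5, 3, 1)

    def test_local_count_matches_formula(self):
        N = 30
        regions = enumerate_regions(N, "local", 1, N, 1)
        assert len(regions) == N * (N + 1) // 2


class TestCountInRegion:
    def test_full_region_counts_all(self):
        scan = make_scan([0, 3, 3, 7], N=10)
        assert count_in_region(scan, RegionCandidate(0, 10)) == 4

    def test_empty_scan(self):
        scan = ScanResult("M", 5.0, [], 10, 5)
        assert count_in_region(scan, RegionCandidate(2, 3)) == 0

    def test_half_open_span(self):
        scan = make_scan([0, 3, 3, 7], N=10)
        assert count_in_region(scan, RegionCandidate(3, 2)) == 2


class TestVectorisedPvalues:
    def test_raw_pvalues_match_scalar_op(self):
        rng = np.random.default_rng(5)
        N, S = 37, 25
        counts = rng.multinomial(S, np.full(N, 1 / N))
        regions = enumerate_regions(N, "local", 1, N, 1)
        vec = raw_pvalues(counts, S, regions)
        cs = np.concatenate([[0], np.cumsum(counts)])
        for reg, p in zip(regions, vec):
            s = int(cs[reg.end] - cs[reg.start])
            assert p == pytest.approx(
                binomial_pvalue(s, S, reg.M / N), rel=1e-12, abs=1e-300
            )

    def test_min_raw_pvalue_matches_full_evaluation(self):
        rng = np.random.default_rng(6)
        N, S, B = 23, 12, 8
        counts = rng.multinomial(S, np.full(N, 1 / N), size=B)
        regions = enumerate_regions(N, "local", 1, N, 1)
        grouped = group_regions(regions)
        mins = min_raw_pvalue(counts, S, grouped)
        for b in range(B):
            assert mins[b] == pytest.approx(
                raw_pvalues(counts[b], S, regions).min(), rel=1e-12
            )


def _mk_result(p_raw, start, M, evalue=1e-3):
    return EnrichmentResult(
        "M", RegionCandidate(start, M), 0.1, 1, 10, p_raw, 10,
        p_raw, evalue, math.log(max(p_raw, 1e-300)),
    )


class TestSelectNonoverlapping:
    def test_greedy_skips_overlap(self):
        a = _mk_result(1e-5, 0, 10)
        b = _mk_result(1e-4, 5, 10)
        c = _mk_result(1e-3, 20, 10)
        assert select_nonoverlapping([b, c, a], alpha_evalue=10) == [a, c]

    def test_empty_input(self):
        assert select_nonoverlapping([], 10) == []

    def test_significance_gate(self):
        a = _mk_result(1e-5, 0, 10, evalue=0.5)
        b = _mk_result(1e-4, 20, 10, evalue=50.0)
        assert select_nonoverlapping([a, b], alpha_evalue=10) == [a]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_greedy(self, seed):
        """50 random significant regions: output equals an independent
        greedy oracle and is pairwise non-overlapping."""
        rng = np.random.default_rng(seed)
        results = []
        for _ in range(50):
            M = int(rng.integers(1, 30))
            start = int(rng.integers(0, 100 - M))
            results.append(_mk_result(float(rng.random()), start, M))
        chosen = select_nonoverlapping(results, alpha_evalue=10)
        # independent oracle
        expected = []
        for res in sorted(results, key=lambda r: (r.p_raw, r.region.M, r.region.start)):
            lo, hi = res.region.start, res.region.end
            if all(hi <= e.region.start or e.region.end <= lo for e in expected):
                expected.append(res)
        assert chosen == expected
        for i, x in enumerate(chosen):
            for y in chosen[i + 1:]:
                assert not x.region.overlaps(y.region)


class TestAnalyzeMotif:
    def test_all_sites_at_center_closed_form(self):
        """All S sites at the exact central start: the width-1 central
        region has p_raw = (1/N)^S and is the reported winner."""
        N, S = 11, 6
        scan = make_scan([5] * S, N=N)
        results = analyze_motif(scan, mode="central", n_motifs=1)
        assert len(results) == 1
        top = results[0]
        assert (top.region.start, top.region.M) == (5, 1)
        assert top.p_raw == pytest.approx((1 / N) ** S, rel=1e-9)
        assert top.s == S

    def test_empty_scan_returns_empty(self):
        scan = ScanResult("M", 5.0, [], 20, 10)
        assert analyze_motif(scan) == []

    def test_central_equals_filtered_local(self):
        """Central-mode p-values equal local-mode results restricted to
        centered candidates, with n recomputed accordingly."""
        rng = np.random.default_rng(42)
        N, S = 21, 15
        starts = rng.integers(0, N, size=S)
        scan = make_scan(list(starts), N=N)
        central_regions = enumerate_regions(N, "central", 1, N, 1)
        local_regions = enumerate_regions(N, "local", 1, N, 1)
        central = score_regions(scan, central_regions, len(central_regions))
        centered = [
            r for r in score_regions(scan, local_regions, len(local_regions))
            if (N - r.region.M) % 2 == 0
            and r.region.start == (N - r.region.M) // 2
        ]
        assert len(central) == len(centered)
        for c, f in zip(central, centered):
            assert c.region == f.region
            assert c.p_raw == pytest.approx(f.p_raw, rel=1e-12)
            assert c.p_adj == pytest.approx(
                adjust_pvalue(f.p_raw, len(central_regions)), rel=1e-12
            )

    def test_keep_best_reports_something_under_null(self):
        rng = np.random.default_rng(9)
        scan = make_scan(list(rng.integers(0, 50, size=20)), N=50)
        selected = analyze_motif(
            scan, mode="local", n_motifs=884, alpha_evalue=1e-6, keep_best=True
        )
        assert len(selected) == 1

    def test_threshold_count_scales_n(self):
        scan = make_scan([5] * 6, N=11)
        one = analyze_motif(scan, mode="central", n_threshold_tests=1)[0]
        many = analyze_motif(scan, mode="central", n_threshold_tests=7)[0]
        assert many.n_tests == 7 * one.n_tests
        assert many.p_adj >= one.p_adj
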