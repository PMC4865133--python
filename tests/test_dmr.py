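from math import comb

import pytest
from hypothesis import given, settings, strategies as st

from methsilence.dmr import (
    DifferentialWindow,
    GridMismatchError,
    MethylationWindow,
    call_differential_windows,
    compute_window_methylation,
    fisher_exact_two_sided,
    merge_windows,
)
from methsilence.io import CytosineSiteRecord

from conftest import fisher_two_sided_oracle


def site(pos, m, u, context="CG", chrom="Chr1", strand="+"):
    return CytosineSiteRecord(chrom, pos, strand, context, m, u)


def window(start, m_a, u_a, chrom="Chr1", size=50, context="CG"):
    return MethylationWindow(chrom, start, start + size, {context: m_a}, {context: u_a}, {context: 1})


def diff_window(start, delta, p=1e-6, chrom="Chr1", size=50, context="CG"):
    # counts consistent with the requested delta, at depth 100 per genotype
    m_a = 50
    m_b = int(round(50 + delta * 100))
    wa = window(start, m_a, 100 - m_a, chrom, size, context)
    wb = window(start, m_b, 100 - m_b, chrom, size, context)
    return DifferentialWindow(wa, wb, context, delta, p)


class TestWindowMethylation:
    def test_pools_read_counts_within_window(self):
        sites = [site(10, 5, 5), site(40, 10, 0)]
        (w,) = compute_window_methylation(sites, window_size=50, min_coverage=5)
        assert (w.start, w.end) == (0, 50)
        assert w.level("CG") == pytest.approx(15 / 20)
        assert w.level("total") == pytest.approx(0.75)
        assert w.n_sites == {"CG": 2}

    def test_window_grid_is_anchored_at_zero(self):
        sites = [site(51, 5, 5)]  # 1-based position 51 -> 0-based 50 -> second cell
        (w,) = compute_window_methylation(sites, window_size=50)
        assert (w.start, w.end) == (50, 100)

    def test_low_coverage_sites_are_excluded(self):
        sites = [site(10, 2, 2), site(20, 8, 2)]  # first has coverage 4
        (w,) = compute_window_methylation(sites, window_size=50, min_coverage=5)
        assert w.counts("CG") == (8, 2)

    def test_cell_without_qualifying_site_emits_no_window(self):
        assert compute_window_methylation([site(10, 2, 2)], min_coverage=5) == []

    def test_contexts_are_pooled_separately_and_totalled(self):
        sites = [site(10, 8, 2, "CG"), site(20, 1, 9, "CHH")]
        (w,) = compute_window_methylation(sites)
        assert w.level("CG") == pytest.approx(0.8)
        assert w.level("CHH") == pytest.approx(0.1)
        assert w.level("total") == pytest.approx(9 / 20)
        assert w.level("CHG") is None

    @pytest.mark.parametrize("kwargs", [{"window_size": 0}, {"min_coverage": -1}])
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ValueError):
            compute_window_methylation([site(10, 5, 5)], **kwargs)


class TestFisherExact:
    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_two_sided(5, 5, 5, 5) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        # margins (10,10;10,10): only the two extreme tables are as improbable
        expected = 2 / comb(20, 10)
        assert fisher_exact_two_sided(10, 0, 0, 10) == pytest.approx(expected, abs=1e-12)

    def test_moderate_table_matches_enumeration(self):
        expected = float(fisher_two_sided_oracle(3, 7, 8, 2))
        assert fisher_exact_two_sided(3, 7, 8, 2) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_table_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert fisher_exact_two_sided(0, 0, 0, 0) == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 1, 1, 1)

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_full_enumeration_oracle(self, data):
        """Against exact rational enumeration for any table with total <= 60."""
        total = data.draw(st.integers(1, 60))
        a = data.draw(st.integers(0, total))
        b = data.draw(st.integers(0, total - a))
        c = data.draw(st.integers(0, total - a - b))
        d = total - a - b - c
        if a + b == 0 or c + d == 0:
            return
        expected = float(fisher_two_sided_oracle(a, b, c, d))
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(expected, abs=1e-12)


class TestDifferentialWindows:
    def test_strong_loss_is_called_hypo(self):
        wa = [window(0, 40, 10)]
        wb = [window(0, 10, 40)]
        (dw,) = call_differential_windows(wa, wb)
        assert dw.direction == "hypo"
        assert dw.delta == pytest.approx(-0.6)
        assert dw.p == pytest.approx(float(fisher_two_sided_oracle(40, 10, 10, 40)), abs=1e-12)

    def test_small_delta_not_retained_despite_significance(self):
        # |delta| = 0.09 with overwhelming counts: p is tiny but delta fails
        wa = [window(0, 500, 500)]
        wb = [window(0, 410, 590)]
        assert call_differential_windows(wa, wb) == []

    def test_insignificant_p_not_retained_despite_delta(self):
        # delta -0.30 but only 10 reads per genotype: p ~ 0.37
        wa = [window(0, 6, 4)]
        wb = [window(0, 3, 7)]
        assert call_differential_windows(wa, wb) == []

    def test_windows_missing_in_one_genotype_are_skipped(self):
        wa = [window(0, 40, 10), window(50, 40, 10)]
        wb = [window(0, 10, 40)]
        out = call_differential_windows(wa, wb)
        assert [w.start for w in out] == [0]

    def test_mismatched_grid_raises(self):
        wa = [window(0, 40, 10, size=50)]
        wb = [window(0, 10, 40, size=100)]
        with pytest.raises(GridMismatchError):
            call_differential_windows(wa, wb)

    def test_per_context_mode_uses_only_that_context(self):
        wa = [MethylationWindow("Chr1", 0, 50, {"CG": 40, "CHH": 0}, {"CG": 10, "CHH": 50}, {})]
        wb = [MethylationWindow("Chr1", 0, 50, {"CG": 10, "CHH": 0}, {"CG": 40, "CHH": 50}, {})]
        (dw,) = call_differential_windows(wa, wb, context_mode="CG")
        assert dw.delta == pytest.approx(-0.6)
        assert call_differential_windows(wa, wb, context_mode="CHH") == []


class TestMergeWindows:
    def test_gap_of_exactly_max_gap_merges(self):
        dmrs = merge_windows([diff_window(0, -0.3), diff_window(100, -0.3)], max_gap=50)
        assert [(d.start, d.end, d.n_windows) for d in dmrs] == [(0, 150, 2)]

    def test_gap_one_over_max_gap_splits(self):
        dmrs = merge_windows([diff_window(0, -0.3), diff_window(101, -0.3)], max_gap=50)
        assert [(d.start, d.end) for d in dmrs] == [(0, 50), (101, 151)]

    def test_adjacent_opposite_directions_do_not_merge(self):
        dmrs = merge_windows([diff_window(0, -0.3), diff_window(50, +0.3)])
        assert sorted(d.direction for d in dmrs) == ["hyper", "hypo"]
        assert len(dmrs) == 2

    def test_delta_total_recomputed_from_pooled_counts(self):
        (d,) = merge_windows([diff_window(0, -0.2), diff_window(50, -0.4)])
        # pooled: A = 100/200, B = (30+10)/200
        assert d.delta_total == pytest.approx((30 + 10) / 200 - 0.5)
        assert d.p_min == pytest.approx(1e-6)

    @given(
        st.lists(
            st.tuples(st.integers(0, 40), st.booleans()),
            min_size=1,
            max_size=25,
            unique_by=lambda t: t[0],
        ),
        st.integers(0, 120),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_merge_invariants(self, spec, max_gap):
        """Every window lands in exactly one DMR; consecutive same-direction
        DMRs are separated by more than max_gap; window count is conserved."""
        windows = [
            diff_window(cell * 50, -0.3 if hypo else 0.3) for cell, hypo in spec
        ]
        dmrs = merge_windows(windows, max_gap=max_gap)
        assert sum(d.n_windows for d in dmrs) == len(windows)
        for d in dmrs:
            assert all(w.direction == d.direction for w in d.windows)
            assert d.start == d.windows[0].start and d.end == d.windows[-1].end
        by_dir = {}
        for d in dmrs:
            by_dir.setdefault(d.direction, []).append(d)
        for group in by_dir.values():
            group.sort(key=lambda d: d.start)
            for prev, nxt in zip(group, group[1:]):
                assert nxt.start - prev.end > max_gap
        # merging is idempotent: re-merging the emitted regions changes nothing
        again = merge_windows([w for d in dmrs for w in d.windows], max_gap=max_gap)
        assert [(d.chrom, d.start, d.end, d.direction) for d in again] == [
            (d.chrom, d.start, d.end, d.direction) for d in dmrs
        ]
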