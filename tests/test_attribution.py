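import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regimeshift import (
    Regime,
    Segmentation,
    ShiftEvent,
    overlap_within_window,
    percent_change_between,
    shifts_from_segmentation,
)


def seg_from_means(bounds_means, sigma=1.0):
    """Segmentation with given (start, end, mean) triples."""
    regimes = tuple(
        Regime(s, e, post_mean_mu=m, post_mean_sigma=sigma, cpi68=(m - 1, m + 1))
        for s, e, m in bounds_means
    )
    return Segmentation(regimes)


def ev(label, year, delta):
    return ShiftEvent(
        label, year, "up" if delta >= 0 else "down", delta
    )


class TestShiftEvents:
    def test_single_regime_yields_no_events(self):
        seg = seg_from_means([(1900, 1950, 1.0)])
        assert shifts_from_segmentation(seg) == []

    def test_nao_like_down_up_down(self):
        seg = seg_from_means(
            [(1864, 1960, 0.1), (1961, 1971, -2.0), (1972, 1995, 1.5), (1996, 2018, 0.5)]
        )
        events = shifts_from_segmentation(seg, "nao")
        assert [e.year for e in events] == [1961, 1972, 1996]
        assert [e.direction for e in events] == ["down", "up", "down"]
        assert events[1].delta_mean == pytest.approx(3.5)

    def test_variance_only_shift_flagged(self):
        seg = Segmentation(
            (
                Regime(0, 33, post_mean_mu=18.5, post_mean_sigma=12.0, cpi68=(5, 32)),
                Regime(34, 55, post_mean_mu=18.6, post_mean_sigma=4.0, cpi68=(14, 23)),
            )
        )
        (event,) = shifts_from_segmentation(seg, "cod")
        assert event.variance_only
        # 0.1 change against pooled sigma ~8.9 is negligible

    def test_direction_must_match_sign(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ShiftEvent("x", 2000, "up", -1.0)


class TestOverlap:
    def test_zooplankton_1997_precedes_cod_1999(self):
        findings = overlap_within_window(
            [ev("zoo", 1997, -5.0)], [ev("cod", 1974, -8.0), ev("cod", 1999, -5.0)]
        )
        assert findings[0].linked and findings[0].lag_years == 2
        assert findings[0].response_event.year == 1999

    def test_nao_1961_too_early_to_link(self):
        findings = overlap_within_window(
            [ev("nao", 1961, -2.1)], [ev("cod", 1974, -8.0), ev("cod", 1999, -5.0)]
        )
        assert not findings[0].linked
        assert findings[0].lag_years is None

    def test_coincident_years_count_as_linked(self):
        findings = overlap_within_window([ev("sst", 1999, 1.5)], [ev("cod", 1999, -5.0)])
        assert findings[0].linked and findings[0].lag_years == 0

    def test_multiple_drivers_can_share_a_response(self):
        drivers = [ev("zoo", 1997, -5.0), ev("sst", 1996, 1.2), ev("nao", 1996, -1.0)]
        findings = overlap_within_window(drivers, [ev("cod", 1999, -5.0)])
        assert all(f.linked for f in findings)

    @given(st.integers(-500, 500))
    @settings(max_examples=30, derandomize=True)
    def test_translation_invariance(self, shift):
        drivers = [ev("a", 1961, -1.0), ev("a", 1972, 2.0)]
        responses = [ev("b", 1974, -1.0), ev("b", 1999, -1.0)]
        base = overlap_within_window(drivers, responses)
        moved = overlap_within_window(
            [ev("a", d.year + shift, d.delta_mean) for d in drivers],
            [ev("b", r.year + shift, r.delta_mean) for r in responses],
        )
        assert [f.linked for f in base] == [f.linked for f in moved]
        assert [f.lag_years for f in base] == [f.lag_years for f in moved]

    @given(st.integers(0, 10), st.integers(0, 10))
    @settings(max_examples=30, derandomize=True)
    def test_window_monotonicity(self, w1, w2):
        lo, hi = sorted((w1, w2))
        drivers = [ev("a", y, 1.0) for y in (1960, 1970, 1980, 1990)]
        responses = [ev("b", y, 1.0) for y in (1963, 1974, 1992)]
        linked_lo = {
            f.driver_event.year
            for f in overlap_within_window(drivers, responses, lo)
            if f.linked
        }
        linked_hi = {
            f.driver_event.year
            for f in overlap_within_window(drivers, responses, hi)
            if f.linked
        }
        assert linked_lo <= linked_hi


class TestPercentChange:
    def test_cod_like_decline(self):
        seg = seg_from_means(
            [(1919, 1952, 18.5), (1953, 1974, 18.5), (1975, 1998, 10.0), (1999, 2014, 5.0)]
        )
        decline = percent_change_between(seg, [0, 1], 3)
        assert decline == pytest.approx(100 * (1 - 5 / 18.5), abs=1e-9)
        assert decline > 70

    def test_identical_means_give_zero(self):
        seg = seg_from_means([(0, 9, 4.0), (10, 19, 4.0)])
        assert percent_change_between(seg, [0], 1) == pytest.approx(0.0)

    def test_increase_reported_as_negative_decline(self):
        seg = seg_from_means([(0, 9, 2.0), (10, 19, 3.0)])
        assert percent_change_between(seg, [0], 1) == pytest.approx(-50.0)

    def test_nonpositive_baseline_flagged(self):
        seg = seg_from_means([(0, 9, -1.0), (10, 19, 1.0)])
        with pytest.warns(UserWarning, match="non-positive"):
            assert np.isnan(percent_change_between(seg, [0], 1))
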