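import math

import pytest
from hypothesis import assume, given, strategies as st

from cocompare.core import DegenerateStatisticsError, PairedSample
from cocompare.trending import (
    DeltaPair,
    compute_deltas,
    four_quadrant_concordance,
    polar_points,
    polar_statistics,
    to_polar,
)

from oracles import place_polar_point

SCHEDULE = ("T0", "T1", "T2", "T3", "T4", "T5", "T6", "T7")


def pair(subject, tp, ref, test, state="postcal"):
    return PairedSample(subject, tp, ref, test, state)


def dp(dref, dtest):
    return DeltaPair("S", ("T0", "T1"), dref, dtest)


class TestComputeDeltas:
    def test_consecutive_changes(self):
        pairs = [pair("A", "T0", 4, 4), pair("A", "T1", 5, 5), pair("A", "T2", 6, 6)]
        deltas = compute_deltas(pairs, SCHEDULE)
        assert [d.delta_ref for d in deltas] == [1, 1]
        assert [d.gap for d in deltas] == [1, 1]

    def test_single_timepoint_contributes_nothing(self):
        assert compute_deltas([pair("A", "T0", 4, 4)], SCHEDULE) == []

    def test_missing_intermediate_timepoint_is_bridged(self):
        pairs = [pair("A", "T0", 4, 4), pair("A", "T2", 6, 5)]
        (d,) = compute_deltas(pairs, SCHEDULE)
        assert d.interval == ("T0", "T2")
        assert d.gap == 2
        assert d.delta_ref == 2
        assert d.delta_test == 1

    def test_state_mismatch_rejected(self):
        pairs = [pair("A", "T0", 4, 4, "precal"), pair("A", "T1", 5, 5, "precal")]
        with pytest.raises(ValueError, match="precal"):
            compute_deltas(pairs, SCHEDULE, "postcal")
        assert len(compute_deltas(pairs, SCHEDULE, "precal")) == 1


class TestFourQuadrant:
    def test_perfect_concordance(self):
        deltas = [dp(1.0, 0.9), dp(2.0, 1.8), dp(0.8, 1.0)]
        r = four_quadrant_concordance(deltas, 0.75)
        assert r.concordance_with_exclusion == 100.0
        assert r.concordance_without_exclusion == 100.0
        assert r.n_excluded == 0

    def test_hand_worked_example_with_zone(self):
        deltas = [dp(1.0, 0.8), dp(-1.0, 0.5), dp(0.2, 0.1), dp(1.2, 1.1)]
        r = four_quadrant_concordance(deltas, 0.75)
        assert r.n_excluded == 1
        assert r.concordance_with_exclusion == pytest.approx(100 * 2 / 3)
        assert r.concordance_without_exclusion == pytest.approx(75.0)

    def test_boundary_point_not_excluded(self):
        # mean absolute change exactly equal to the zone stays in (strict <)
        r = four_quadrant_concordance([dp(0.75, 0.75)], 0.75)
        assert r.n_excluded == 0
        assert r.concordance_with_exclusion == 100.0

    def test_zero_product_dropped_from_denominator(self):
        r = four_quadrant_concordance([dp(0.0, 1.0)], 0.0)
        assert r.concordance_with_exclusion is None
        assert r.concordance_without_exclusion is None

    def test_all_excluded_is_undefined_not_zero(self):
        r = four_quadrant_concordance([dp(0.1, 0.1)], 0.75)
        assert r.concordance_with_exclusion is None
        assert r.concordance_without_exclusion == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            four_quadrant_concordance([])

    @pytest.mark.parametrize("rule,expected_excluded", [
        ("mean", 1),      # (0.9+0.3)/2 = 0.6 < 0.75
        ("either", 1),    # 0.3 < 0.75
        ("both", 0),      # 0.9 >= 0.75
    ])
    def test_zone_rules(self, rule, expected_excluded):
        r = four_quadrant_concordance([dp(0.9, 0.3)], 0.75, zone_rule=rule)
        assert r.n_excluded == expected_excluded


class TestToPolar:
    def test_identity_line(self):
        p = to_polar(dp(1.0, 1.0))
        assert p.angle == pytest.approx(0.0)
        assert p.radius == pytest.approx(1.0)
        assert not p.reflected

    def test_closed_form_angle(self):
        p = to_polar(dp(1.0, 0.5))
        assert p.angle == pytest.approx(math.degrees(math.atan2(0.5, 1.0)) - 45)
        assert p.angle == pytest.approx(-18.434948, abs=1e-5)
        assert p.radius == pytest.approx(0.75)

    def test_negative_direction_reflected_onto_identity(self):
        p = to_polar(dp(-1.0, -1.0))
        assert p.reflected
        assert p.angle == pytest.approx(0.0)
        assert p.radius == pytest.approx(1.0)

    def test_double_zero_change_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            to_polar(dp(0.0, 0.0))

    @given(
        dref=st.floats(-5, 5),
        dtest=st.floats(-5, 5),
    )
    def test_inverse_reconstruction(self, dref, dtest):
        assume(abs(dref + dtest) > 1e-3)
        p = to_polar(dp(dref, dtest))
        theta = math.radians(p.angle + 45.0)
        c = 2.0 * p.radius / (math.cos(theta) + math.sin(theta))
        if p.reflected:
            c = -c
        assert c * math.cos(theta) == pytest.approx(dref, abs=1e-9)
        assert c * math.sin(theta) == pytest.approx(dtest, abs=1e-9)

    @given(dref=st.floats(-5, 5), dtest=st.floats(-5, 5))
    def test_swapping_methods_negates_angle(self, dref, dtest):
        assume(abs(dref + dtest) > 1e-3)
        a = to_polar(dp(dref, dtest))
        b = to_polar(dp(dtest, dref))
        assert b.angle == pytest.approx(-a.angle, abs=1e-9)

    @given(
        dref=st.floats(-5, 5), dtest=st.floats(-5, 5),
        c=st.floats(0.01, 50),
    )
    def test_positive_scaling_preserves_angle(self, dref, dtest, c):
        assume(abs(dref + dtest) > 1e-3)
        a = to_polar(dp(dref, dtest))
        b = to_polar(dp(c * dref, c * dtest))
        assert b.angle == pytest.approx(a.angle, abs=1e-9)
        assert b.radius == pytest.approx(c * a.radius, rel=1e-9)


class TestPolarStatistics:
    def test_identity_points(self):
        pts, _ = polar_points([dp(1.0, 1.0), dp(2.0, 2.0), dp(-1.5, -1.5)])
        r = polar_statistics(pts)
        assert r.angular_bias == pytest.approx(0.0)
        assert r.polar_concordance_with_exclusion == 100.0

    def test_hand_worked_angles(self):
        deltas = [dp(*place_polar_point(a, 1.0)) for a in (10.0, -10.0, 40.0)]
        pts, _ = polar_points(deltas)
        r = polar_statistics(pts, exclusion_zone=0.5, limit=30.0)
        assert r.angular_bias == pytest.approx(40.0 / 3)
        assert r.polar_concordance_with_exclusion == pytest.approx(100 * 2 / 3)
        assert r.n_excluded == 0

    def test_point_below_zone_leaves_with_exclusion_undefined(self):
        pts, _ = polar_points([dp(0.2, 0.2)])  # radius 0.2 < 0.5
        r = polar_statistics(pts)
        assert r.angular_bias is None
        assert r.polar_concordance_with_exclusion is None
        assert r.polar_concordance_without_exclusion == 100.0

    def test_concordance_limit_inclusive(self):
        deltas = [dp(*place_polar_point(30.0, 1.0))]
        pts, _ = polar_points(deltas)
        r = polar_statistics(pts, limit=30.0)
        assert r.polar_concordance_with_exclusion == 100.0

    def test_zero_change_points_dropped_with_count(self):
        pts, dropped = polar_points([dp(0.0, 0.0), dp(1.0, 1.0)])
        assert dropped == 1
        assert len(pts) == 1

    @given(c=st.floats(0.1, 20))
    def test_scaling_deltas_and_zone_leaves_rates_unchanged(self, c):
        deltas = [dp(1.0, 0.8), dp(-1.0, 0.5), dp(0.3, 0.2), dp(1.2, 1.1)]
        scaled = [dp(c * d.delta_ref, c * d.delta_test) for d in deltas]
        fq1 = four_quadrant_concordance(deltas, 0.75)
        fq2 = four_quadrant_concordance(scaled, 0.75 * c)
        assert fq1.concordance_with_exclusion == fq2.concordance_with_exclusion
        assert fq1.concordance_without_exclusion == fq2.concordance_without_exclusion
        p1, _ = polar_points(deltas)
        p2, _ = polar_points(scaled)
        r1 = polar_statistics(p1, 0.5)
        r2 = polar_statistics(p2, 0.5 * c)
        assert r2.angular_bias == pytest.approx(r1.angular_bias, abs=1e-9)
        assert r1.polar_concordance_with_exclusion == r2.polar_concordance_with_exclusion
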