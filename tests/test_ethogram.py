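import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestcare import intervals as iv
from nestcare.ethogram import (FULL_DAY, FeedingEvent, NestRecording,
                               StateInterval, UnsupportedMetricError,
                               duration_in_window, metric_intervals,
                               normalize_track, proportion_male_feedings)

from conftest import random_integer_intervals, rasterized_length


def make_rec(male_care=(), female_care=(), male_inside=(), female_inside=(),
             stage="incubation", feedings=(), gaps=()):
    start, end = FULL_DAY
    ivs = []
    for parent, state, track in (("male", "care", male_care),
                                 ("female", "care", female_care),
                                 ("male", "inside", male_inside),
                                 ("female", "inside", female_inside)):
        ivs += [StateInterval(parent, state, start + s, start + e)
                for s, e in track]
    feeds = [FeedingEvent(p, start + t) for p, t in feedings]
    return NestRecording(nest_id="N", stage=stage, stage_day=3,
                         record_start=start, record_end=end, intervals=ivs,
                         feedings=feeds,
                         gaps=[(start + s, start + e) for s, e in gaps])


class TestNormalizeTrack:
    def test_overlap_merge(self):
        assert normalize_track([(0, 10), (5, 20)]) == [(0, 20)]

    def test_touching_merge(self):
        assert normalize_track([(0, 10), (10, 20)]) == [(0, 20)]

    def test_empty(self):
        assert normalize_track([]) == []

    def test_inverted_interval_rejected(self):
        with pytest.raises(iv.IntervalError):
            iv.normalize([(10, 5)], context="N1/male/care")

    def test_zero_length_rejected(self):
        with pytest.raises(iv.IntervalError):
            normalize_track([(5, 5)])

    def test_error_names_record(self):
        with pytest.raises(iv.IntervalError, match="N1/male/care"):
            iv.normalize([(10, 5)], context="N1/male/care")

    def test_random_against_raster_oracle(self, rng):
        lo, hi = 0, 40000
        for _ in range(50):
            raw = random_integer_intervals(rng, 200, lo, hi)
            merged = normalize_track(raw)
            occ, _ = rasterized_length(raw, (lo, hi))
            assert iv.total_length(merged) == occ
            # pairwise disjoint, sorted, non-touching
            for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
                assert e1 < s2


class TestMetricIntervals:
    def test_joint_is_intersection(self):
        rec = make_rec(male_care=[(0, 100)], female_care=[(50, 150)])
        got = metric_intervals(rec, "joint_care")
        assert got == [(FULL_DAY[0] + 50, FULL_DAY[0] + 100)]
        assert iv.total_length(got) == 50

    def test_total_is_union(self):
        rec = make_rec(male_care=[(0, 100)], female_care=[(50, 150)])
        got = metric_intervals(rec, "total_care")
        assert got == [(FULL_DAY[0], FULL_DAY[0] + 150)]
        assert iv.total_length(got) == 150

    def test_disjoint_tracks_joint_zero(self):
        rec = make_rec(male_care=[(0, 100)], female_care=[(200, 300)])
        assert metric_intervals(rec, "joint_care") == []

    def test_attendance_unions_care_and_inside(self):
        rec = make_rec(male_care=[(0, 100)], male_inside=[(100, 250)])
        assert metric_intervals(rec, "male_attendance") == [
            (FULL_DAY[0], FULL_DAY[0] + 250)]

    def test_prop_metric_rejected(self):
        rec = make_rec()
        with pytest.raises(UnsupportedMetricError):
            metric_intervals(rec, "prop_male_feedings")

    def test_unknown_metric_rejected(self):
        with pytest.raises(UnsupportedMetricError):
            metric_intervals(make_rec(), "male_sleep")


class TestDurationInWindow:
    def test_full_cover(self):
        d = duration_in_window([(0.0, 3600.0)], (0.0, 3600.0))
        assert (d.occupied, d.observable) == (3600.0, 3600.0)
        assert not d.missing

    def test_empty_intervals(self):
        d = duration_in_window([], (0.0, 3600.0))
        assert (d.occupied, d.observable) == (0.0, 3600.0)

    def test_gap_shrinks_both_sides(self):
        d = duration_in_window([(0.0, 3600.0)], (0.0, 3600.0),
                               gaps=[(0.0, 1800.0)])
        assert (d.occupied, d.observable) == (1800.0, 1800.0)
        assert d.missing  # observable below 95% of nominal width

    def test_zero_observable_flagged(self):
        d = duration_in_window([(0.0, 3600.0)], (0.0, 3600.0),
                               gaps=[(0.0, 3600.0)])
        assert d.observable == 0.0 and d.missing

    def test_random_against_raster_oracle(self, rng):
        for _ in range(50):
            ivs = iv.normalize(random_integer_intervals(rng, 30, 0, 20000))
            gaps = iv.normalize(random_integer_intervals(rng, 3, 0, 20000, 2000))
            w = (3600.0, 10800.0)
            d = duration_in_window(ivs, w, gaps)
            occ, obs = rasterized_length(ivs, w, gaps)
            assert d.occupied == occ
            assert d.observable == obs


class TestProportionMaleFeedings:
    def test_symmetric(self):
        rec = make_rec(stage="provisioning",
                       feedings=[("male", t) for t in (1, 2, 3)]
                       + [("female", t) for t in (4, 5, 6)])
        assert proportion_male_feedings(rec) == 0.5

    def test_no_feedings_missing(self):
        rec = make_rec(stage="provisioning")
        assert math.isnan(proportion_male_feedings(rec))

    def test_incubation_unsupported(self):
        with pytest.raises(UnsupportedMetricError):
            proportion_male_feedings(make_rec(stage="incubation"))

    def test_random_counts_match_enumeration(self, rng):
        for _ in range(20):
            m = int(rng.integers(0, 20))
            f = int(rng.integers(0, 20))
            feeds = [("male", 10 + i) for i in range(m)] + \
                    [("female", 100 + i) for i in range(f)]
            rec = make_rec(stage="provisioning", feedings=feeds)
            got = proportion_male_feedings(rec)
            if m + f == 0:
                assert math.isnan(got)
            else:
                assert got == m / (m + f)

    def test_window_restricts_counts(self):
        rec = make_rec(stage="provisioning",
                       feedings=[("male", 10), ("female", 5000)])
        w = (FULL_DAY[0], FULL_DAY[0] + 100)
        assert proportion_male_feedings(rec, w) == 1.0


intervals_strategy = st.lists(
    st.tuples(st.integers(0, 9999), st.integers(1, 3000)).map(
        lambda t: (float(t[0]), float(t[0] + t[1]))),
    max_size=20)


class TestInvariants:
    @given(male=intervals_strategy, female=intervals_strategy)
    @settings(max_examples=200, deadline=None)
    def test_inclusion_exclusion_exact(self, male, female):
        m = iv.normalize(male)
        f = iv.normalize(female)
        joint = iv.total_length(iv.intersect(m, f))
        total = iv.total_length(iv.union(m, f))
        lm, lf = iv.total_length(m), iv.total_length(f)
        assert lm + lf - joint == pytest.approx(total, abs=1e-9)
        assert joint <= min(lm, lf) + 1e-9
        assert max(lm, lf) <= total + 1e-9
        assert total <= lm + lf + 1e-9

    @given(care=intervals_strategy, inside=intervals_strategy)
    @settings(max_examples=100, deadline=None)
    def test_attendance_dominates_care(self, care, inside):
        c = iv.normalize(care)
        att = iv.union(c, iv.normalize(inside))
        assert iv.total_length(att) >= iv.total_length(c) - 1e-12

    def test_occupied_never_exceeds_observable(self, rng):
        for _ in range(200):
            ivs = iv.normalize(random_integer_intervals(rng, 20, 0, 30000))
            gaps = iv.normalize(random_integer_intervals(rng, 4, 0, 30000, 4000))
            d = duration_in_window(ivs, (0.0, 30000.0), gaps)
            assert 0.0 <= d.occupied <= d.observable
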