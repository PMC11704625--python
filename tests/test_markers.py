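import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogdiag.cohort import SensorDay
from cogdiag.errors import (
    DegenerateBoundsError,
    InsufficientDataError,
    MissingDataError,
)
from cogdiag.markers import (
    MARKER_NAMES,
    MarkerVector,
    ScaleBounds,
    aggregate_behavior,
    apply_scale,
    daily_behavior,
    detect_home,
    ema_markers,
    extract_markers,
    fit_scale,
    markers_frame,
    nback_markers,
    scale_value,
)


def day_at(points, day_index=0, accel=1.0):
    return SensorDay(day_index=day_index, accel_total=accel, locations=np.asarray(points, float))


class TestDetectHome:
    def test_unanimous_mode(self):
        day = day_at(np.zeros((300, 2)))
        assert np.allclose(detect_home(day), (0.0, 0.0))

    def test_majority_cell_wins(self):
        # 200 readings near (100, 100), 100 near (500, 500)
        pts = [(101.0, 102.0)] * 200 + [(503.0, 505.0)] * 100
        home = detect_home(day_at(pts))
        assert np.allclose(home, (101.0, 102.0))

    def test_tie_breaks_to_first_visited(self):
        pts = [(55.0, 55.0)] * 150 + [(5.0, 5.0)] * 150
        assert np.allclose(detect_home(day_at(pts)), (55.0, 55.0))
        # and with the order reversed the other cell wins
        assert np.allclose(detect_home(day_at(pts[::-1])), (5.0, 5.0))

    def test_only_first_300_considered(self):
        pts = [(0.0, 0.0)] * 300 + [(900.0, 900.0)] * 1000
        assert np.allclose(detect_home(day_at(pts)), (0.0, 0.0))

    def test_missing_day_raises(self):
        missing = SensorDay(day_index=0, accel_total=None, locations=None, missing=True)
        with pytest.raises(MissingDataError):
            detect_home(missing)

    def test_frequency_oracle(self):
        # brute-force cell frequency count over a random configuration
        rng = np.random.default_rng(42)
        pts = rng.uniform(-50, 50, size=(300, 2))
        cells = [tuple(c) for c in np.floor(pts / 10.0).astype(int)]
        counts = {}
        first = {}
        for i, c in enumerate(cells):
            counts[c] = counts.get(c, 0) + 1
            first.setdefault(c, i)
        best = max(counts, key=lambda c: (counts[c], -first[c]))
        expect = pts[[i for i, c in enumerate(cells) if c == best]].mean(axis=0)
        assert np.allclose(detect_home(day_at(pts)), expect)


class TestDailyBehavior:
    def test_all_home_zero(self):
        day = day_at(np.zeros((300, 2)), accel=0.0)
        assert daily_behavior(day, np.zeros(2)) == (0.0, 0.0)

    def test_mean_distance(self):
        pts = [(0.0, 0.0), (100.0, 0.0)] * 150
        _, dist = daily_behavior(day_at(pts), np.zeros(2))
        assert dist == pytest.approx(50.0)

    def test_activity_identity(self):
        day = day_at(np.zeros((300, 2)), accel=7.5)
        act, _ = daily_behavior(day, np.zeros(2))
        assert act == 7.5

    def test_max_statistic(self):
        pts = [(0.0, 0.0), (100.0, 0.0)] * 150
        _, dist = daily_behavior(day_at(pts), np.zeros(2), distance_stat="max")
        assert dist == pytest.approx(100.0)


class TestAggregateBehavior:
    def _days(self, dists, accels):
        out = []
        for i, (dist, a) in enumerate(zip(dists, accels)):
            out.append(day_at([(dist, 0.0)] * 300, day_index=i, accel=a))
        return out

    def test_constant_distance(self):
        days = self._days([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        _, _, d_mean, d_var = aggregate_behavior(days, home=np.zeros(2))
        assert (d_mean, d_var) == (2.0, 0.0)

    def test_population_variance(self):
        days = self._days([0.0, 0.0], [1.0, 3.0])
        a_mean, a_var, _, _ = aggregate_behavior(days, home=np.zeros(2))
        assert (a_mean, a_var) == (2.0, 1.0)

    def test_missing_days_excluded(self):
        rng = np.random.default_rng(3)
        dists = rng.uniform(0, 100, 10)
        accels = rng.uniform(0, 50, 10)
        days = self._days(dists, accels)
        for i in (2, 5, 8):
            days[i] = SensorDay(day_index=i, accel_total=None, locations=None, missing=True)
        keep = [i for i in range(10) if i not in (2, 5, 8)]
        a_mean, a_var, d_mean, d_var = aggregate_behavior(days, home=np.zeros(2))
        assert a_mean == pytest.approx(np.mean(accels[keep]))
        assert a_var == pytest.approx(np.var(accels[keep]))
        assert d_mean == pytest.approx(np.mean(dists[keep]))
        assert d_var == pytest.approx(np.var(dists[keep]))

    def test_too_few_days(self):
        days = self._days([1.0], [1.0])
        with pytest.raises(InsufficientDataError):
            aggregate_behavior(days, home=np.zeros(2))


class TestEmaMarkers:
    def test_all_answered_fives(self):
        responses = [(d, q, 5) for d in range(14) for q in range(4)]
        assert ema_markers(responses, 56) == (5.0, 0.0, 1.0)

    def test_half_compliance(self):
        responses = [(d, q, 3) for d in range(7) for q in range(4)]
        responses += [(d, q, None) for d in range(7, 14) for q in range(4)]
        _, _, compliance = ema_markers(responses, 56)
        assert compliance == 0.5

    def test_hand_arithmetic(self):
        mean, var, _ = ema_markers([(0, 0, 1), (0, 1, 5)], 8)
        assert (mean, var) == (3.0, 4.0)

    def test_zero_answered(self):
        mean, var, compliance = ema_markers([(0, 0, None)], 4)
        assert mean is None and var is None and compliance == 0.0


class TestNbackMarkers:
    def test_exact_line(self):
        daily = list(enumerate([0.2, 0.3, 0.4, 0.5, 0.6, 0.7]))
        rate, _, _ = nback_markers(daily)
        assert rate == pytest.approx(0.1)

    def test_constant_series(self):
        daily = [(i, 0.5) for i in range(10)]
        rate, mean, sd = nback_markers(daily)
        assert rate == pytest.approx(0.0)
        assert mean == 0.5 and sd == 0.0

    def test_too_short_for_slope(self):
        rate, mean, sd = nback_markers([(0, 0.5), (1, 0.6)])
        assert rate is None and sd is not None and mean is not None

    def test_unordered_input(self):
        ordered = list(enumerate([0.2, 0.3, 0.4, 0.5, 0.6, 0.7]))
        shuffled = [ordered[i] for i in (3, 0, 5, 2, 4, 1)]
        assert nback_markers(shuffled)[0] == pytest.approx(0.1)

    @given(
        scores=st.lists(st.floats(0, 1), min_size=6, max_size=12),
        shift=st.floats(-5, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_slope_shift_invariance(self, scores, shift):
        base = nback_markers(list(enumerate(scores)))[0]
        shifted = nback_markers([(i, s + shift) for i, s in enumerate(scores)])[0]
        assert shifted == pytest.approx(base, abs=1e-9)

    @given(scores=st.lists(st.floats(0, 1), min_size=6, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_slope_scales_linearly(self, scores):
        base = nback_markers(list(enumerate(scores)))[0]
        doubled = nback_markers([(i, 2.0 * s) for i, s in enumerate(scores)])[0]
        assert doubled == pytest.approx(2.0 * base, abs=1e-9)


def mv(**kwargs):
    base = dict(age=70, sex="female", education_years=14)
    base.update(kwargs)
    return MarkerVector(**base)


class TestScaling:
    def _two_point_reference(self, lo=2.0, hi=7.0):
        fields = {n: lo for n in MARKER_NAMES[3:]}
        a = mv(**fields)
        b = mv(**{n: hi for n in MARKER_NAMES[3:]})
        return [a, b]

    def test_fit_bounds(self):
        bounds = fit_scale(self._two_point_reference())
        assert bounds.bounds["shape_score_sd"] == (2.0, 7.0)

    def test_new_maximum_extends_bounds(self):
        ref = self._two_point_reference()
        hi1 = fit_scale(ref).bounds["EMA_compliance"][1]
        ref.append(mv(**{n: 9.0 for n in MARKER_NAMES[3:]}))
        hi2 = fit_scale(ref).bounds["EMA_compliance"][1]
        assert hi2 > hi1

    def test_constant_marker_errors(self):
        ref = self._two_point_reference(lo=3.0, hi=3.0)
        with pytest.raises(DegenerateBoundsError):
            fit_scale(ref)

    def test_endpoints(self):
        assert scale_value(2.0, 2.0, 7.0) == 0
        assert scale_value(7.0, 2.0, 7.0) == 10

    def test_formula_arithmetic(self):
        assert scale_value(4.5, 2.0, 7.0) == 5

    def test_clamping(self):
        assert scale_value(1.0, 2.0, 7.0) == 0
        assert scale_value(9.9, 2.0, 7.0) == 10

    def test_round_half_up(self):
        # 10*(2.75-2)/5 = 1.5 -> rounds up to 2 (not banker's rounding)
        assert scale_value(2.75, 2.0, 7.0) == 2

    @given(
        xs=st.lists(st.floats(-100, 100), min_size=2, max_size=20),
        lo=st.floats(-10, 0),
        span=st.floats(0.5, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_nondecreasing(self, xs, lo, span):
        scaled = [scale_value(x, lo, lo + span) for x in sorted(xs)]
        assert scaled == sorted(scaled)
        assert all(0 <= s <= 10 for s in scaled)

    def test_apply_scale_map(self):
        ref = self._two_point_reference()
        bounds = fit_scale(ref)
        scaled = apply_scale(ref[0], bounds)
        assert scaled["shape_score_sd"] == 0
        assert scaled["age"] == 70 and scaled["sex"] == "female"
        assert ref[0].scaled is scaled


class TestExtraction:
    def test_default_cohort_complete(self, default_cohort):
        vectors = [extract_markers(r) for r in default_cohort]
        assert all(v.is_complete() for v in vectors)
        assert all(0.0 <= v.EMA_compliance <= 1.0 for v in vectors)
        assert all(v.shape_score_sd >= 0 for v in vectors)

    def test_frame_columns(self, default_cohort):
        vectors = [extract_markers(r) for r in default_cohort]
        frame = markers_frame(default_cohort, vectors)
        assert tuple(frame.columns) == ("id", "pseudonym", "label", *MARKER_NAMES)
        assert len(frame) == 124

    def test_oracle_equivalence_behavior(self, default_cohort):
        """Aggregates equal a brute-force recomputation after explicit
        missing-entry removal."""
        from cogdiag.markers import participant_home

        rec = next(r for r in default_cohort if any(d.missing for d in r.sensor_days))
        v = extract_markers(rec)
        home = participant_home(rec.sensor_days)
        acts, dists = [], []
        for d in rec.sensor_days:
            if d.missing:
                continue
            acts.append(d.accel_total)
            dists.append(float(np.linalg.norm(d.locations - home, axis=1).mean()))
        assert v.physical_activity_level == pytest.approx(np.mean(acts))
        assert v.physical_activity_variance == pytest.approx(np.var(acts))
        assert v.distance_traveled_from_home == pytest.approx(np.mean(dists))
        assert v.distance_traveled_variance == pytest.approx(np.var(dists))

    def test_oracle_equivalence_ema(self, default_cohort):
        rec = default_cohort[0]
        v = extract_markers(rec)
        answered = [val for _, _, val in rec.ema_responses if val is not None]
        assert v.mental_sharpness_mean == pytest.approx(np.mean(answered))
        assert v.mental_sharpness_variance == pytest.approx(np.var(answered))
        assert v.EMA_compliance == pytest.approx(
            len(answered) / (len(rec.sensor_days) * 4)
        )
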