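"""Track aggregation: extraction-method catalogue and feature definitions."""

import numpy as np
import pytest
import yaml

from oracles import grid_stats, iv, random_signal, random_track, sec, signal_per_second, track
from trackfeat.aggregation import (
    FeatureDefinition,
    aggregate_intervals,
    aggregate_signal,
    run_definition,
    threshold_feature,
)
from trackfeat.core import Feature, SignalSegment, SignalTrack
from trackfeat.definition import resample, restrict_signal
from trackfeat.errors import ConfigurationError


def make_signal(points, horizon):
    return resample([(sec(t), float(v)) for t, v in points], step=1,
                    max_gap=10 ** 9, domain=iv(0, horizon),
                    unit_id="u1", track_concept="s")


class TestAggregateSignal:
    def test_constant_signal_all_methods(self):
        sig = make_signal([(0, 97)], 120)
        for method in ("min", "max", "mean", "median", "weighted_average"):
            assert aggregate_signal(sig, iv(0, 120), method) == 97.0

    def test_forced_arithmetic_example(self):
        sig = make_signal([(0, 100), (60, 80)], 90)
        assert aggregate_signal(sig, iv(0, 90), "weighted_average") == pytest.approx(
            (100 * 60 + 80 * 30) / 90
        )
        assert aggregate_signal(sig, iv(0, 90), "median") == 100.0
        assert aggregate_signal(sig, iv(0, 90), "min") == 80.0

    def test_mean_and_weighted_average_are_synonyms(self):
        sig = make_signal([(0, 100), (30, 50)], 100)
        assert aggregate_signal(sig, iv(0, 100), "mean") == aggregate_signal(
            sig, iv(0, 100), "weighted_average"
        )

    def test_undefined_period_yields_none(self):
        sig = make_signal([(0, 97)], 60)
        assert aggregate_signal(sig, iv(100, 200), "mean") is None

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            aggregate_signal(make_signal([(0, 1)], 10), iv(0, 10), "variance")

    def test_all_methods_match_per_second_oracle(self, rng):
        for _ in range(200):
            sig = random_signal(rng, 150)
            a = int(rng.integers(0, 100))
            b = int(rng.integers(a, 151))
            expected = grid_stats(signal_per_second(sig, a, b))
            for method in ("min", "max", "mean", "median", "weighted_average"):
                got = aggregate_signal(sig, iv(a, b), method)
                if expected is None:
                    assert got is None
                else:
                    assert got == pytest.approx(expected[method], abs=1e-9)

    def test_order_invariants(self, rng):
        for _ in range(100):
            sig = random_signal(rng, 100)
            period = iv(0, 100)
            stats = {
                m: aggregate_signal(sig, period, m)
                for m in ("min", "max", "mean", "median")
            }
            if stats["min"] is None:
                continue
            assert stats["min"] <= stats["median"] <= stats["max"]
            assert stats["min"] <= stats["mean"] <= stats["max"]

    def test_mean_invariant_under_breakpoint_refinement(self, rng):
        for _ in range(50):
            sig = random_signal(rng, 100)
            # split every segment in half without changing values
            refined = []
            for s in sig.segments:
                mid = s.start + (s.end - s.start) / 2
                mid = mid.replace(microsecond=0)
                if mid > s.start and mid < s.end:
                    refined.append(SignalSegment(type(s.interval)(s.start, mid), s.value))
                    refined.append(SignalSegment(type(s.interval)(mid, s.end), s.value))
                else:
                    refined.append(s)
            sig2 = SignalTrack("u1", "s", refined, sig.domain)
            a = aggregate_signal(sig, iv(0, 100), "mean")
            b = aggregate_signal(sig2, iv(0, 100), "mean")
            assert (a is None) == (b is None)
            if a is not None:
                assert a == pytest.approx(b, abs=1e-9)


class TestAggregateIntervals:
    def test_duration_and_count_example(self):
        t = track([(0, 60), (120, 150)])
        period = iv(0, 180)
        assert aggregate_intervals(t, period, "sum_duration") == 90
        assert aggregate_intervals(t, period, "count") == 2
        assert aggregate_intervals(t, period, "exists") == 1

    def test_count_distinct(self):
        t = track([(0, 0, "A"), (10, 10, "A"), (20, 20, "B")])
        assert aggregate_intervals(t, iv(0, 60), "count_distinct") == 2
        assert aggregate_intervals(t, iv(0, 60), "count") == 3

    def test_delay_in_seconds_from_period_start(self):
        t = track([(600, 660)])
        assert aggregate_intervals(t, iv(0, 3600), "delay") == 600

    def test_first_and_last_values(self):
        t = track([(10, 20, "A"), (30, 40, "B")])
        assert aggregate_intervals(t, iv(0, 60), "first") == "A"
        assert aggregate_intervals(t, iv(0, 60), "last") == "B"

    def test_empty_clip_results(self):
        t = track([(100, 200)])
        period = iv(0, 50)
        assert aggregate_intervals(t, period, "sum_duration") == 0
        assert aggregate_intervals(t, period, "count") == 0
        assert aggregate_intervals(t, period, "count_distinct") == 0
        assert aggregate_intervals(t, period, "exists") == 0
        assert aggregate_intervals(t, period, "delay") is None
        assert aggregate_intervals(t, period, "first") is None

    def test_clip_respects_half_open_membership(self):
        t = track([(60, 60)])  # point event exactly at the period end
        assert aggregate_intervals(t, iv(0, 60), "count") == 0
        assert aggregate_intervals(t, iv(0, 61), "count") == 1

    def test_clipped_duration_bounded_by_period(self, rng):
        for _ in range(100):
            t = random_track(rng, 200)
            a = int(rng.integers(0, 150))
            b = int(rng.integers(a, 201))
            dur = aggregate_intervals(t, iv(a, b), "sum_duration")
            assert 0 <= dur <= b - a
            assert aggregate_intervals(t, iv(a, b), "count_distinct") <= aggregate_intervals(
                t, iv(a, b), "count"
            )

    def test_clip_before_aggregate_commutes_with_restriction(self, rng):
        for _ in range(50):
            t = random_track(rng, 120, values=("A", "B"))
            a = int(rng.integers(0, 80))
            b = int(rng.integers(a, 121))
            period = iv(a, b)
            pre = t.clip(period)
            for m in ("sum_duration", "count", "count_distinct", "exists"):
                assert aggregate_intervals(t, period, m) == aggregate_intervals(
                    pre, period, m
                )


DEF_PAYLOAD = {
    "definition_id": "d1",
    "feature_concept": "f1",
    "label": "demo feature",
    "source": "demo raw rows",
    "statistical_unit": "person",
    "track_type": "episode",
    "value_rule": "demo rule",
    "final_track": "episodes",
    "period": "study",
    "method": {"name": "sum_duration"},
}


class TestFeatureDefinition:
    def test_seven_items_present(self):
        d = FeatureDefinition.model_validate(DEF_PAYLOAD)
        items = d.items7()
        assert len(items) == 7 and all(v for v in items.values())

    def test_yaml_round_trip_is_lossless(self):
        d = FeatureDefinition.model_validate(DEF_PAYLOAD)
        again = FeatureDefinition.model_validate(
            yaml.safe_load(yaml.safe_dump(d.model_dump(mode="json")))
        )
        assert again == d

    def test_unknown_method_rejected(self):
        bad = dict(DEF_PAYLOAD, method={"name": "variance"})
        with pytest.raises(Exception):
            FeatureDefinition.model_validate(bad)


class TestRunDefinition:
    def setup_method(self):
        self.defn = FeatureDefinition.model_validate(DEF_PAYLOAD)
        self.tracks = {
            "episodes": {
                "u1": track([(0, 60)], unit="u1"),
                "u2": track([(0, 30), (40, 50)], unit="u2"),
            }
        }
        self.periods = {"study": {"u1": iv(0, 100), "u2": iv(0, 100), "u3": iv(0, 100)}}

    def test_one_feature_per_unit_with_zero_for_absent_counting_track(self):
        features, exclusions = run_definition(self.defn, self.tracks, self.periods)
        got = {f.unit_id: f.value_number for f in features}
        assert got == {"u1": 60.0, "u2": 40.0, "u3": 0.0}
        assert exclusions == []
        assert all(f.definition_id == "d1" for f in features)

    def test_value_method_excludes_units_without_records(self):
        defn = FeatureDefinition.model_validate(
            dict(DEF_PAYLOAD, method={"name": "first"})
        )
        features, exclusions = run_definition(defn, self.tracks, self.periods)
        assert {f.unit_id for f in features} == {"u1", "u2"}
        assert [e.unit_id for e in exclusions] == ["u3"]
        # accounting: every unit is either a feature or an exclusion
        assert len(features) + len(exclusions) == len(self.periods["study"])

    def test_dangling_reference_raises_before_computation(self):
        bad = FeatureDefinition.model_validate(dict(DEF_PAYLOAD, final_track="ghost"))
        with pytest.raises(ConfigurationError):
            run_definition(bad, self.tracks, self.periods)

    def test_rerun_is_deterministic(self):
        a = run_definition(self.defn, self.tracks, self.periods)
        b = run_definition(self.defn, self.tracks, self.periods)
        assert a == b

    def test_empty_collections_give_empty_output(self):
        features, exclusions = run_definition(
            self.defn, {"episodes": {}}, {"study": {}}
        )
        assert features == [] and exclusions == []


class TestThresholdFeature:
    def test_indicator(self):
        f = Feature("u1", "mean_ml_kg", value_number=7.5)
        flag = threshold_feature(f, "<", 8.0, feature_concept="compliant")
        assert flag.value_number == 1.0 and flag.feature_concept == "compliant"
        assert threshold_feature(
            Feature("u1", "m", value_number=9.0), "<", 8.0, feature_concept="c"
        ).value_number == 0.0

    def test_categorical_feature_rejected(self):
        with pytest.raises(ConfigurationError):
            threshold_feature(
                Feature("u1", "m", value_concept="A"), "<", 8.0, feature_concept="c"
            )
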