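import numpy as np
import pandas as pd
import pytest

from cogdiag.cohort import HEALTHY, MCI
from cogdiag.engine import (
    DeterministicBackend,
    RuleFiring,
    aggregate,
    apply_rules,
    build_prompt,
    classify,
    cohort_query,
    parse_response,
)
from cogdiag.errors import (
    ConfigError,
    MissingMarkerError,
    QueryError,
    UnparseableResponseError,
)
from cogdiag.induction import Condition, Rule, builtin_numeric_rules, parse_rules
from cogdiag.textmarkers import TextRule

BOX2_RESPONSE = (
    "Diagnosis: Mild cognitive impairment\n"
    "Explanation: Based on the provided information, Sloan's shape_score_sd is 6, "
    "which is greater than 2.5."
)


class TestBuildPrompt:
    def test_sloan_layout(self, sloan):
        markers, journal, ratings, rules = sloan
        prompt = build_prompt("Sloan", markers, journal, ratings, rules).render()
        assert "Rule #3:" in prompt
        assert "shape_score_sd: 6" in prompt
        assert "Sloan's Information:" in prompt
        assert "Diagnosis Rules:" in prompt
        assert prompt.rstrip().endswith("Explanation: ...")

    def test_zero_rules_forbidden(self, sloan):
        markers, journal, ratings, _ = sloan
        with pytest.raises(ConfigError):
            build_prompt("Sloan", markers, journal, ratings, [])

    def test_deterministic_rendering(self, sloan):
        markers, journal, ratings, rules = sloan
        a = build_prompt("Sloan", markers, journal, ratings, rules).render()
        b = build_prompt("Sloan", markers, journal, ratings, rules).render()
        assert a == b

    def test_absent_marker_error_lists_names(self, sloan):
        _, journal, ratings, rules = sloan
        with pytest.raises(MissingMarkerError, match="shape_score_sd"):
            build_prompt("Sloan", {"shape_learning_rate": 9}, journal, ratings, rules)

    def test_only_referenced_markers_included(self, sloan):
        markers, journal, ratings, rules = sloan
        markers = dict(markers, EMA_compliance=7)
        prompt = build_prompt("Sloan", markers, journal, ratings, rules).render()
        assert "EMA_compliance" not in prompt


class TestParseResponse:
    def test_box2_response(self):
        d = parse_response(BOX2_RESPONSE)
        assert d.label == MCI
        assert d.explanation.startswith("Based on the provided information")

    def test_case_insensitive(self):
        assert parse_response("diagnosis: HEALTHY").label == HEALTHY

    def test_no_match_raises(self):
        with pytest.raises(UnparseableResponseError):
            parse_response("I am not sure.")


class TestApplyRules:
    def test_sloan_firing_set(self, sloan):
        markers, journal, ratings, rules = sloan
        firings = apply_rules(markers, journal, ratings, rules)
        fired = {f.index for f in firings if f.fired}
        assert {1, 3} <= fired
        assert 2 not in fired
        assert 5 in fired  # ratings contain values <= 3

    @pytest.mark.parametrize(
        "op,expected", [("<=", True), (">", False)]
    )
    def test_boundary_semantics(self, op, expected):
        rule = Rule((Condition("m", op, 2.5),), MCI)
        (firing,) = apply_rules({"m": 2.5}, [], None, [rule])
        assert firing.fired is expected

    def test_missing_marker_unfires_and_flags(self):
        rule = Rule((Condition("m", ">", 2.5),), MCI)
        (firing,) = apply_rules({"m": None}, [], None, [rule])
        assert not firing.fired and firing.missing

    def test_exhaustive_condition_oracle(self, default_ctx):
        rules = builtin_numeric_rules()
        for pid in list(default_ctx.scaled)[:30]:
            values = default_ctx.scaled[pid]
            firings = apply_rules(values, [], None, rules)
            for firing in firings:
                expect = all(
                    (
                        values[c.marker] <= c.threshold
                        if c.op == "<="
                        else values[c.marker] > c.threshold
                        if c.op == ">"
                        else values[c.marker] == c.threshold
                    )
                    for c in firing.rule.conditions
                )
                assert firing.fired == expect


def firing(consequent, pr=None, index=1):
    rule = Rule((Condition("m", ">", 0.5),), consequent, pr=pr)
    return RuleFiring(index, rule, fired=True)


class TestAggregate:
    def test_no_fired_rules_defaults_healthy(self):
        assert aggregate([]) == HEALTHY

    def test_weighted_sum(self):
        firings = [firing(MCI, 80.0, 1), firing(MCI, None, 2), firing(HEALTHY, 100.0, 3)]
        # mci: 80 + 75 (pseudo-confidence) = 155 > healthy: 100
        assert aggregate(firings) == MCI

    def test_exact_tie_breaks_healthy(self):
        firings = [firing(MCI, 80.0, 1), firing(HEALTHY, 80.0, 2)]
        assert aggregate(firings) == HEALTHY

    @pytest.mark.parametrize("policy", ["confidence_weighted", "majority", "first_match"])
    def test_single_rule_any_policy(self, policy):
        assert aggregate([firing(MCI, 90.0)], policy=policy) == MCI

    def test_unknown_policy(self):
        with pytest.raises(ConfigError, match="policy"):
            aggregate([], policy="coin_flip")

    def test_monotonicity_mci_rule_never_flips_mci(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            firings = [
                firing(rng.choice([HEALTHY, MCI]), float(rng.uniform(50, 100)), i)
                for i in range(rng.integers(1, 6))
            ]
            before = aggregate(firings)
            extra = firings + [firing(MCI, float(rng.uniform(50, 100)), 99)]
            if before == MCI:
                assert aggregate(extra) == MCI


class MockBackend:
    name = "mock"

    def __init__(self, response):
        self.response = response

    def generate(self, prompt):
        if isinstance(self.response, Exception):
            raise self.response
        return self.response


class TestClassify:
    def test_sloan_is_mci(self, sloan):
        markers, journal, ratings, rules = sloan
        d = classify("Sloan", markers, journal, ratings, rules)
        assert d.label == MCI
        fired = {idx for idx, _, _ in d.fired_rules}
        assert {1, 3} <= fired

    def test_healthy_extremes(self):
        markers = {
            "age": 70,
            "sex": "female",
            "education_years": 16,
            "physical_activity_level": 5,
            "physical_activity_variance": 5,
            "distance_traveled_from_home": 10,
            "distance_traveled_variance": 10,
            "mental_sharpness_mean": 6,
            "mental_sharpness_variance": 0,
            "EMA_compliance": 10,
            "shape_learning_rate": 0,
            "shape_score_mean": 10,
            "shape_score_sd": 0,
        }
        d = classify("Avery", markers, [], None, builtin_numeric_rules())
        assert d.label == HEALTHY
        assert all(consequent == HEALTHY for _, consequent, _ in d.fired_rules)

    def test_mock_backend_pass_through(self, sloan):
        markers, journal, ratings, rules = sloan
        d = classify("Sloan", markers, journal, ratings, rules,
                     backend=MockBackend("Diagnosis: healthy\nExplanation: fine."))
        assert d.label == HEALTHY and d.explanation == "fine."

    def test_backend_failure_names_participant(self, sloan):
        markers, journal, ratings, rules = sloan
        with pytest.raises(RuntimeError, match="Sloan"):
            classify("Sloan", markers, journal, ratings, rules,
                     backend=MockBackend(RuntimeError("boom")))

    def test_contract_closure(self, sloan):
        """build_prompt -> deterministic rendering -> parse_response round-trips
        the label produced by direct classification."""
        markers, journal, ratings, rules = sloan
        direct = classify("Sloan", markers, journal, ratings, rules)
        prompt = build_prompt("Sloan", markers, journal, ratings, rules)
        response = DeterministicBackend().generate(prompt.render())
        assert parse_response(response).label == direct.label

    def test_contract_closure_on_cohort(self, default_ctx):
        backend = DeterministicBackend(thresholds=default_ctx.thresholds)
        rules = builtin_numeric_rules()
        from cogdiag.textmarkers import builtin_text_rules

        all_rules = rules + builtin_text_rules()
        for pid in list(default_ctx.scaled)[:10]:
            rec = default_ctx.records[pid]
            direct = classify(rec.pseudonym, default_ctx.scaled[pid], rec.journal_texts,
                              rec.interview_ratings, all_rules, backend=backend)
            prompt = build_prompt(rec.pseudonym, default_ctx.scaled[pid], rec.journal_texts,
                                  rec.interview_ratings, all_rules)
            assert parse_response(backend.generate(prompt.render())).label == direct.label

    def test_end_to_end_determinism(self, default_ctx):
        backend = DeterministicBackend(thresholds=default_ctx.thresholds)
        rules = builtin_numeric_rules()
        ids = list(default_ctx.scaled)[:25]

        def run():
            out = []
            for pid in ids:
                rec = default_ctx.records[pid]
                out.append(
                    classify(rec.pseudonym, default_ctx.scaled[pid], rec.journal_texts,
                             rec.interview_ratings, rules, backend=backend)
                )
            return out

        assert run() == run()


class TestCohortQuery:
    def frame(self):
        return pd.DataFrame(
            {
                "label": [HEALTHY, HEALTHY, MCI, MCI, MCI],
                "shape_score_sd": [2.0, 2.0, 5.0, 7.0, 9.0],
            }
        )

    def test_constant_marker(self):
        t = self.frame()
        assert cohort_query(t, HEALTHY, "shape_score_sd", "mean") == 2.0
        assert cohort_query(t, HEALTHY, "shape_score_sd", "sd") == 0.0

    def test_grouped_mean_brute_force(self):
        t = self.frame()
        expect = np.mean([5.0, 7.0, 9.0])
        assert cohort_query(t, MCI, "shape_score_sd", "mean") == pytest.approx(expect)

    def test_count_partition(self):
        t = self.frame()
        total = cohort_query(t, HEALTHY, "shape_score_sd", "count") + cohort_query(
            t, MCI, "shape_score_sd", "count"
        )
        assert total == len(t)

    @pytest.mark.parametrize(
        "label,marker,stat",
        [("sick", "shape_score_sd", "mean"), (HEALTHY, "nope", "mean"), (HEALTHY, "shape_score_sd", "mode")],
    )
    def test_errors(self, label, marker, stat):
        with pytest.raises(QueryError):
            cohort_query(self.frame(), label, marker, stat)
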