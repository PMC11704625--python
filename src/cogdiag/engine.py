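"""Prompt construction, response parsing, and the deterministic rule engine.

The classifier sits behind the same prompt/response contract an external
text-generation backend would use: a prompt is rendered from rules plus
participant information, and the diagnosis is recovered from the response by
a regular-expression search. The bundled deterministic backend applies the
rules directly and renders its verdict in the same response format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Protocol, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import HEALTHY, MCI
from .errors import (
    ConfigError,
    MissingMarkerError,
    QueryError,
    UnparseableResponseError,
)
from .induction import Rule, parse_rules
from .markers import MARKER_NAMES
from .textmarkers import (
    TextRule,
    TextThresholds,
    evaluate_text_rules,
    journal_features,
    parse_text_rules,
    serialize_text_rule,
)

AnyRule = Union[Rule, TextRule]

SYSTEM_MESSAGE = (
    'You are a knowledgeable health assistant designed to diagnose someone as '
    '"healthy" or "with mild cognitive impairment" using diagnosis rules and '
    "relevant personal information."
)

_CLASS_TEXT = {HEALTHY: "Healthy", MCI: "Mild cognitive impairment"}

_DIAGNOSIS_RE = re.compile(
    r"diagnosis:\s*(healthy|mild cognitive impairment)", re.IGNORECASE
)
_EXPLANATION_RE = re.compile(r"explanation:\s*(.*)", re.IGNORECASE | re.DOTALL)

_JOURNAL_SEP = " ||| "

POLICIES = ("confidence_weighted", "majority", "first_match")
DEFAULT_TEXT_CONFIDENCE = 75.0


@dataclass(frozen=True)
class PromptContext:
    """The classification prompt in its canonical layout."""

    name: str
    system_message: str
    rule_block: tuple[str, ...]
    marker_block: tuple[str, ...]
    answer_format_instruction: str = "Answer using the format:\nDiagnosis: ...\nExplanation: ..."

    def render(self) -> str:
        lines = [self.system_message, ""]
        lines.append(
            f"Diagnose {self.name} as healthy or mild cognitive impairment by "
            f"applying the following rules to {self.name}'s information."
        )
        lines.append("Diagnosis Rules:")
        lines.extend(f"Rule #{i}: {text}" for i, text in enumerate(self.rule_block, start=1))
        lines.append(f"{self.name}'s Information:")
        lines.extend(self.marker_block)
        lines.append(self.answer_format_instruction)
        return "\n".join(lines)


@dataclass(frozen=True)
class RuleFiring:
    index: int  # 1-based rule number in the prompt/ruleset order
    rule: AnyRule
    fired: bool
    missing: bool = False


@dataclass(frozen=True)
class Diagnosis:
    label: str
    explanation: str
    fired_rules: tuple[tuple[int, str, float], ...] = ()  # (rule number, consequent, weight)
    policy: str = "confidence_weighted"


class Backend(Protocol):
    """Abstract prompt -> response-text contract."""

    name: str

    def generate(self, prompt: str) -> str: ...


def _rule_text(rule: AnyRule) -> str:
    if isinstance(rule, Rule):
        return rule.text()
    return serialize_text_rule(rule)


def _referenced_markers(rules: Sequence[AnyRule]) -> tuple[list[str], bool, bool]:
    numeric: set[str] = set()
    has_journal = False
    has_session = False
    for rule in rules:
        if isinstance(rule, Rule):
            numeric.update(c.marker for c in rule.conditions)
        elif rule.source == "speech":
            has_journal = True
        else:
            has_session = True
    ordered = [m for m in MARKER_NAMES if m in numeric]
    ordered += sorted(numeric - set(MARKER_NAMES))
    return ordered, has_journal, has_session


def build_prompt(
    name: str,
    scaled_markers: Mapping[str, object],
    journal_texts: Sequence[str],
    ratings: Optional[Mapping[str, Optional[int]]],
    rules: Sequence[AnyRule],
) -> PromptContext:
    """Render the classification prompt. The information block names only the
    markers referenced by at least one rule, plus journal text and interview
    ratings when text rules are present."""
    if not rules:
        raise ConfigError("the rule block must not be empty")
    referenced, has_journal, has_session = _referenced_markers(rules)
    absent = [m for m in referenced if m not in scaled_markers]
    if absent:
        raise MissingMarkerError(f"rules reference absent markers: {absent}")
    marker_lines = []
    for m in referenced:
        v = scaled_markers[m]
        marker_lines.append(f"{m}: {'missing' if v is None else v}")
    if has_journal:
        marker_lines.append(f"journal_text: {_JOURNAL_SEP.join(journal_texts)}")
    if has_session:
        items = ratings or {}
        rendered = "; ".join(
            f"{test}: {'missing' if val is None else val}" for test, val in items.items()
        )
        marker_lines.append(f"interview_assessment: {rendered}")
    return PromptContext(
        name=name,
        system_message=SYSTEM_MESSAGE,
        rule_block=tuple(_rule_text(r) for r in rules),
        marker_block=tuple(marker_lines),
    )


def parse_response(text: str) -> Diagnosis:
    """Extract the diagnosis label (case-insensitive) and trailing explanation."""
    m = _DIAGNOSIS_RE.search(text)
    if m is None:
        raise UnparseableResponseError(text)
    label = HEALTHY if m.group(1).lower() == "healthy" else MCI
    em = _EXPLANATION_RE.search(text)
    explanation = em.group(1).strip() if em else ""
    return Diagnosis(label=label, explanation=explanation)


def apply_rules(
    scaled_markers: Mapping[str, object],
    journal_texts: Sequence[str],
    ratings: Optional[Mapping[str, Optional[int]]],
    rules: Sequence[AnyRule],
    thresholds: Optional[TextThresholds] = None,
) -> list[RuleFiring]:
    """Evaluate every rule. A rule fires iff all its conditions hold;
    conditions on missing markers leave the rule unfired and flagged."""
    firings: list[RuleFiring] = []
    feats = journal_features(journal_texts)
    text_rules = [(i, r) for i, r in enumerate(rules, start=1) if isinstance(r, TextRule)]
    text_outcomes = {}
    if text_rules:
        outcomes = evaluate_text_rules(
            feats, ratings, thresholds, [r for _, r in text_rules]
        )
        text_outcomes = {i: o for (i, _), o in zip(text_rules, outcomes)}
    for i, rule in enumerate(rules, start=1):
        if isinstance(rule, Rule):
            verdict = rule.matches(dict(scaled_markers))
            firings.append(
                RuleFiring(i, rule, fired=bool(verdict), missing=verdict is None)
            )
        else:
            o = text_outcomes[i]
            firings.append(RuleFiring(i, rule, fired=o.fired, missing=o.missing))
    return firings


def _weight(rule: AnyRule, text_confidence: float) -> float:
    pr = getattr(rule, "pr", None)
    return float(pr) if pr is not None else text_confidence


def _consequent(rule: AnyRule) -> str:
    return rule.consequent if isinstance(rule, Rule) else rule.direction


def aggregate(
    firings: Sequence[RuleFiring],
    policy: str = "confidence_weighted",
    text_confidence: float = DEFAULT_TEXT_CONFIDENCE,
) -> str:
    """Combine fired rules into a label. Ties and the no-fired-rule case
    default to healthy, the cohort's majority class."""
    if policy not in POLICIES:
        raise ConfigError(f"unknown aggregation policy {policy!r}; choose from {POLICIES}")
    fired = [f for f in firings if f.fired]
    if not fired:
        return HEALTHY
    if policy == "first_match":
        return _consequent(fired[0].rule)
    if policy == "majority":
        votes = sum(1 if _consequent(f.rule) == MCI else -1 for f in fired)
        return MCI if votes > 0 else HEALTHY
    score = sum(
        (_weight(f.rule, text_confidence) if _consequent(f.rule) == MCI else -_weight(f.rule, text_confidence))
        for f in fired
    )
    return MCI if score > 0 else HEALTHY


def _explanation(
    firings: Sequence[RuleFiring], label: str, text_confidence: float, full: bool
) -> str:
    supporting = [f for f in firings if f.fired and _consequent(f.rule) == label]
    if not supporting:
        return (
            "Based on the provided information, no diagnosis rules fired, so the "
            "majority-class diagnosis of healthy is returned."
        )
    numbers = ", ".join(f"#{f.index}" for f in supporting)
    head = (
        f"Based on the provided information, rule(s) {numbers} fired, supporting a "
        f"diagnosis of {_CLASS_TEXT[label].lower()}."
    )
    if not full:
        return head
    detail = " ".join(f"Rule #{f.index}: {_rule_text(f.rule)}." for f in firings if f.fired)
    return f"{head} Fired rules: {detail}"


@dataclass
class DeterministicBackend:
    """Pure rule-application backend honoring the prompt/response contract."""

    thresholds: Optional[TextThresholds] = None
    policy: str = "confidence_weighted"
    text_confidence: float = DEFAULT_TEXT_CONFIDENCE
    full_explanation: bool = False
    name: str = "deterministic"
    deterministic: bool = True

    def decide(
        self,
        scaled_markers: Mapping[str, object],
        journal_texts: Sequence[str],
        ratings: Optional[Mapping[str, Optional[int]]],
        rules: Sequence[AnyRule],
    ) -> Diagnosis:
        firings = apply_rules(scaled_markers, journal_texts, ratings, rules, self.thresholds)
        label = aggregate(firings, self.policy, self.text_confidence)
        fired = tuple(
            (f.index, _consequent(f.rule), _weight(f.rule, self.text_confidence))
            for f in firings
            if f.fired
        )
        return Diagnosis(
            label=label,
            explanation=_explanation(firings, label, self.text_confidence, self.full_explanation),
            fired_rules=fired,
            policy=self.policy,
        )

    def generate(self, prompt: str) -> str:
        """Parse a rendered prompt back into rules and markers, decide, and
        answer in the requested format."""
        markers, journal_texts, ratings, rules = _parse_prompt(prompt)
        diagnosis = self.decide(markers, journal_texts, ratings, rules)
        return f"Diagnosis: {_CLASS_TEXT[diagnosis.label]}\nExplanation: {diagnosis.explanation}"


def _parse_prompt(prompt: str):
    lines = prompt.splitlines()
    try:
        r_start = next(i for i, l in enumerate(lines) if l.strip() == "Diagnosis Rules:")
        i_start = next(i for i, l in enumerate(lines) if l.endswith("'s Information:"))
        a_start = next(i for i, l in enumerate(lines) if l.startswith("Answer using the format"))
    except StopIteration as exc:
        raise UnparseableResponseError(prompt) from exc
    rules: list[AnyRule] = []
    for line in lines[r_start + 1 : i_start]:
        text = re.sub(r"^Rule #\d+:\s*", "", line).strip()
        if not text:
            continue
        try:
            rules.extend(parse_rules(text))
        except Exception:
            rules.extend(parse_text_rules(text))
    markers: dict[str, object] = {}
    journal_texts: list[str] = []
    ratings: Optional[dict[str, Optional[int]]] = None
    for line in lines[i_start + 1 : a_start]:
        if ":" not in line:
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "journal_text":
            journal_texts = value.split(_JOURNAL_SEP) if value else []
        elif key == "interview_assessment":
            ratings = {}
            for item in value.split(";"):
                if ":" not in item:
                    continue
                test, _, rating = item.rpartition(":")
                rating = rating.strip()
                ratings[test.strip()] = None if rating == "missing" else int(rating)
        else:
            if value == "missing":
                markers[key] = None
            else:
                try:
                    markers[key] = int(value)
                except ValueError:
                    try:
                        markers[key] = float(value)
                    except ValueError:
                        markers[key] = value
    return markers, journal_texts, ratings, rules


def classify(
    name: str,
    scaled_markers: Mapping[str, object],
    journal_texts: Sequence[str],
    ratings: Optional[Mapping[str, Optional[int]]],
    rules: Sequence[AnyRule],
    backend: Optional[Backend] = None,
    thresholds: Optional[TextThresholds] = None,
    policy: str = "confidence_weighted",
    text_confidence: float = DEFAULT_TEXT_CONFIDENCE,
) -> Diagnosis:
    """Classify one participant.

    The deterministic backend applies the rules directly; any other backend
    is exercised through the prompt/response contract (build prompt, generate,
    regex-extract the diagnosis)."""
    if backend is None:
        backend = DeterministicBackend(
            thresholds=thresholds, policy=policy, text_confidence=text_confidence
        )
    if getattr(backend, "deterministic", False):
        return backend.decide(scaled_markers, journal_texts, ratings, rules)
    prompt = build_prompt(name, scaled_markers, journal_texts, ratings, rules)
    try:
        response = backend.generate(prompt.render())
    except Exception as exc:
        raise type(exc)(f"backend failure for participant {name!r}: {exc}") from exc
    return parse_response(response)


_QUERY_STATS = ("mean", "sd", "median", "min", "max", "count")


def cohort_query(table: pd.DataFrame, label: str, marker: str, statistic: str) -> float:
    """Grouped summary statistic of one marker over participants with the
    given label, from a flat marker table with a ``label`` column."""
    if statistic not in _QUERY_STATS:
        raise QueryError(f"unknown statistic {statistic!r}; choose from {_QUERY_STATS}")
    if marker not in table.columns:
        raise QueryError(f"unknown marker {marker!r}")
    if label not in set(table["label"]):
        raise QueryError(f"unknown label {label!r}")
    values = table.loc[table["label"] == label, marker].dropna()
    if statistic == "count":
        return float(len(values))
    arr = values.to_numpy(dtype=float)
    if statistic == "mean":
        return float(arr.mean())
    if statistic == "sd":
        return float(arr.std())
    if statistic == "median":
        return float(np.median(arr))
    return float(arr.min() if statistic == "min" else arr.max())
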