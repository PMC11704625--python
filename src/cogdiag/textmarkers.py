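"""Deterministic text features and text-rule evaluation.

Journal features (vocabulary, sentence length, emotion-word counts) are
computed with plain tokenization and bundled lexicons; the eleven built-in
text rules are evaluated as computable predicates against cohort-relative
thresholds instead of a qualitative judgment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import HEALTHY, MCI
from .errors import RuleParseError

_WORD_RE = re.compile(r"[a-z']+")
_SENT_RE = re.compile(r"[.!?]+")


@lru_cache(maxsize=None)
def _lexicon(name: str) -> frozenset[str]:
    text = resources.files("cogdiag.data").joinpath(name).read_text("utf-8")
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


def positive_lexicon() -> frozenset[str]:
    return _lexicon("lexicon_positive.txt")


def negative_lexicon() -> frozenset[str]:
    return _lexicon("lexicon_negative.txt")


def tokenize(text: str) -> list[str]:
    return _WORD_RE.findall(text.lower())


def split_sentences(text: str) -> list[str]:
    return [s.strip() for s in _SENT_RE.split(text) if s.strip()]


@dataclass(frozen=True)
class JournalFeatures:
    entry_count: int
    is_empty: bool
    vocabulary_size: int
    mean_sentence_length: float
    sentence_complexity: float
    positive_word_count: int
    negative_word_count: int


def journal_features(texts: Sequence[str]) -> JournalFeatures:
    """Compute journal features over a participant's stored entries.

    Entries are lowercase word-tokenized; sentences split on terminal
    punctuation. ``sentence_complexity`` is the mean words-per-sentence
    stand-in (no parser); ``entry_count`` counts non-empty entries.
    """
    non_empty = [t for t in texts if t.strip()]
    if not non_empty:
        return JournalFeatures(0, True, 0, 0.0, 0.0, 0, 0)
    blob = " ".join(non_empty)
    tokens = tokenize(blob)
    sentences = split_sentences(blob)
    per_sentence = [len(tokenize(s)) for s in sentences] or [0]
    msl = float(np.mean(per_sentence))
    pos, neg = positive_lexicon(), negative_lexicon()
    return JournalFeatures(
        entry_count=len(non_empty),
        is_empty=False,
        vocabulary_size=len(set(tokens)),
        mean_sentence_length=msl,
        sentence_complexity=msl,
        positive_word_count=sum(1 for t in tokens if t in pos),
        negative_word_count=sum(1 for t in tokens if t in neg),
    )


@dataclass(frozen=True)
class TextThresholds:
    """Cohort-relative thresholds for the vocabulary/sentence predicates."""

    vocabulary_size: float
    mean_sentence_length: float
    sentence_complexity: float


def fit_text_thresholds(
    features: Sequence[JournalFeatures], quantile: float = 0.5
) -> TextThresholds:
    """Threshold each continuous journal feature at a reference-cohort
    quantile (median by default), over non-empty journals."""
    usable = [f for f in features if not f.is_empty]
    if not usable:
        raise ValueError("no non-empty journals in the reference cohort")
    return TextThresholds(
        vocabulary_size=float(np.quantile([f.vocabulary_size for f in usable], quantile)),
        mean_sentence_length=float(
            np.quantile([f.mean_sentence_length for f in usable], quantile)
        ),
        sentence_complexity=float(
            np.quantile([f.sentence_complexity for f in usable], quantile)
        ),
    )


# ---------------------------------------------------------------------------
# Text rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TextRule:
    predicate: str
    direction: str  # HEALTHY or MCI
    source: str  # "speech" | "testing_session"


#: predicate id -> (canonical antecedent phrase, source)
PREDICATE_PHRASES: dict[str, tuple[str, str]] = {
    "journal_empty": ("journal_text is empty", "speech"),
    "journal_rich": (
        "journal_text has a large vocabulary, long sentences, and/or high sentence complexity",
        "speech",
    ),
    "journal_poor": (
        "journal_text has a small vocabulary, short sentences, and/or low sentence complexity",
        "speech",
    ),
    "journal_positive": ("journal_text uses positive emotion words", "speech"),
    "journal_negative": ("journal_text uses negative emotion words", "speech"),
    "journal_multi_entry": ("journal_text appears to have more than 1 entry", "speech"),
    "journal_single_entry": ("journal_text appears to only have 1 entry", "speech"),
    "some_ratings_low": ("some interview_assessment ratings are <= 3", "testing_session"),
    "most_ratings_high": ("most interview_assessment ratings are >= 4", "testing_session"),
    "ratings_confident": (
        "the interview_assessment explanations suggest the participant confidently "
        "answered the questions correctly",
        "testing_session",
    ),
    "ratings_struggled": (
        "the interview_assessment explanations suggest the participant struggled to "
        "answer the questions correctly",
        "testing_session",
    ),
}

_PHRASE_TO_PREDICATE = {
    " ".join(phrase.split()).lower(): pred for pred, (phrase, _) in PREDICATE_PHRASES.items()
}

_CLASS_TEXT = {HEALTHY: "healthy", MCI: "mild cognitive impairment"}
_TEXT_CLASS = {v: k for k, v in _CLASS_TEXT.items()}

_RULE_LINE_RE = re.compile(
    r"^if\s+(?P<body>.+?)\s+then\s+more\s+likely\s+"
    r"(?P<cls>healthy|mild cognitive impairment)\s*$",
    re.IGNORECASE,
)


def _ratings_values(ratings: Optional[Mapping[str, Optional[int]]]) -> Optional[list[int]]:
    if not ratings:
        return None
    vals = [v for v in ratings.values() if v is not None]
    return vals or None


def _eval_predicate(
    predicate: str,
    f: JournalFeatures,
    ratings: Optional[Mapping[str, Optional[int]]],
    thresholds: Optional[TextThresholds],
) -> Optional[bool]:
    """True/False, or None when the needed inputs are missing."""
    if predicate == "journal_empty":
        return f.is_empty
    if predicate in ("journal_rich", "journal_poor"):
        if f.is_empty:
            return False
        if thresholds is None:
            return None
        # Conjunctive surrogate for the qualitative "and/or" judgment: the
        # disjunctive reading fires on roughly half of any cohort by
        # construction of the median threshold, which destroys the rule's
        # direction; requiring every feature on the same side preserves it.
        if predicate == "journal_rich":
            return (
                f.vocabulary_size > thresholds.vocabulary_size
                and f.mean_sentence_length > thresholds.mean_sentence_length
                and f.sentence_complexity > thresholds.sentence_complexity
            )
        return (
            f.vocabulary_size < thresholds.vocabulary_size
            and f.mean_sentence_length < thresholds.mean_sentence_length
            and f.sentence_complexity < thresholds.sentence_complexity
        )
    if predicate == "journal_positive":
        return f.positive_word_count >= 1
    if predicate == "journal_negative":
        return f.negative_word_count >= 1
    if predicate == "journal_multi_entry":
        return f.entry_count > 1
    if predicate == "journal_single_entry":
        return f.entry_count == 1
    vals = _ratings_values(ratings)
    if vals is None:
        return None
    if predicate == "some_ratings_low":
        return any(v <= 3 for v in vals)  # "some" = at least one
    if predicate == "most_ratings_high":
        return sum(v >= 4 for v in vals) > len(vals) / 2  # strict majority
    if predicate == "ratings_confident":
        return all(v >= 4 for v in vals)
    if predicate == "ratings_struggled":
        return float(np.mean(vals)) <= 3.0
    raise RuleParseError(f"unknown predicate {predicate!r}")


@dataclass(frozen=True)
class TextRuleOutcome:
    rule: TextRule
    fired: bool
    missing: bool = False


def evaluate_text_rules(
    features: JournalFeatures,
    ratings: Optional[Mapping[str, Optional[int]]],
    thresholds: Optional[TextThresholds],
    rules: Optional[Sequence[TextRule]] = None,
) -> list[TextRuleOutcome]:
    """Evaluate text rules; rules whose inputs are absent report not-fired
    with a missing flag."""
    rules = list(rules) if rules is not None else builtin_text_rules()
    out = []
    for rule in rules:
        verdict = _eval_predicate(rule.predicate, features, ratings, thresholds)
        if verdict is None:
            out.append(TextRuleOutcome(rule, fired=False, missing=True))
        else:
            out.append(TextRuleOutcome(rule, fired=bool(verdict)))
    return out


def parse_text_rules(dsl_text: str) -> list[TextRule]:
    """Parse text rules written as ``if <predicate or phrase> then more
    likely <class>``, one per line; ``#`` starts a comment."""
    rules: list[TextRule] = []
    for line_no, raw in enumerate(dsl_text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _RULE_LINE_RE.match(line)
        if m is None:
            raise RuleParseError("not an if-then rule", line_no=line_no, token=line[:40])
        body = " ".join(m.group("body").split()).lower()
        predicate = _PHRASE_TO_PREDICATE.get(body, body if body in PREDICATE_PHRASES else None)
        if predicate is None:
            raise RuleParseError("unknown predicate", line_no=line_no, token=m.group("body"))
        phrase, source = PREDICATE_PHRASES[predicate]
        rules.append(
            TextRule(predicate=predicate, direction=_TEXT_CLASS[m.group("cls").lower()], source=source)
        )
    return rules


def serialize_text_rules(rules: Sequence[TextRule]) -> str:
    return "\n".join(serialize_text_rule(r) for r in rules) + ("\n" if rules else "")


def serialize_text_rule(rule: TextRule) -> str:
    phrase, _ = PREDICATE_PHRASES[rule.predicate]
    return f"if {phrase} then more likely {_CLASS_TEXT[rule.direction]}"


@lru_cache(maxsize=1)
def _builtin_text_rules() -> tuple[TextRule, ...]:
    text = resources.files("cogdiag.data").joinpath("text_rules.txt").read_text("utf-8")
    return tuple(parse_text_rules(text))


def builtin_text_rules(source: Optional[str] = None) -> list[TextRule]:
    """The bundled eleven text rules, optionally filtered by source."""
    rules = list(_builtin_text_rules())
    if source is not None:
        rules = [r for r in rules if r.source == source]
    return rules
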