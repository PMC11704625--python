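"""Decision-tree rule induction and the if-then rule language.

A small CART-style tree (Gini impurity, binary axis-aligned splits) is fit on
the scaled marker table; every path prefix becomes a candidate conjunctive
rule annotated with its support (pa: antecedent-matching participants) and
confidence (pr: percent of matching participants carrying the consequent
label). Candidates pass a support floor and a strict confidence filter, and
retained single-condition stump rules gain their measured inversion.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import FEMALE, HEALTHY, MALE, MCI
from .errors import RuleParseError

_CLASS_TEXT = {HEALTHY: "healthy", MCI: "mild cognitive impairment"}
_TEXT_CLASS = {v: k for k, v in _CLASS_TEXT.items()}

CATEGORICAL_MARKERS = ("sex",)


@dataclass(frozen=True)
class Condition:
    marker: str
    op: str  # "<=", ">", "="
    threshold: float | str

    def __post_init__(self) -> None:
        if self.op not in ("<=", ">", "="):
            raise RuleParseError(f"unknown comparator {self.op!r}")
        if self.op == "=" and not isinstance(self.threshold, str):
            raise RuleParseError("'=' comparisons are for categorical markers only")

    def holds(self, value) -> Optional[bool]:
        """Truth of the condition at ``value``; None when the value is missing."""
        if value is None:
            return None
        if self.op == "<=":
            return value <= self.threshold
        if self.op == ">":
            return value > self.threshold
        return value == self.threshold

    def complement(self) -> "Condition":
        if self.op == "<=":
            return Condition(self.marker, ">", self.threshold)
        if self.op == ">":
            return Condition(self.marker, "<=", self.threshold)
        other = FEMALE if self.threshold == MALE else MALE
        return Condition(self.marker, "=", other)

    def text(self) -> str:
        thr = self.threshold
        if isinstance(thr, float) and thr == int(thr):
            thr = f"{thr:.1f}"
        return f"{self.marker} {self.op} {thr}"


@dataclass(frozen=True)
class Rule:
    conditions: tuple[Condition, ...]
    consequent: str  # HEALTHY or MCI
    pr: Optional[float] = None  # confidence percent
    pa: Optional[int] = None  # support count
    provenance: str = "tree"  # tree | inversion | literature | text

    def __post_init__(self) -> None:
        if not self.conditions:
            raise RuleParseError("a rule needs at least one condition")
        if self.pr is not None and not 0 <= self.pr <= 100:
            raise RuleParseError(f"pr out of range: {self.pr}")
        if self.pa is not None and self.pa < 0:
            raise RuleParseError(f"pa out of range: {self.pa}")

    def matches(self, values: dict) -> Optional[bool]:
        """Conjunction truth over a marker map; None if any marker is missing
        while the rest do not already falsify the rule."""
        saw_missing = False
        for cond in self.conditions:
            verdict = cond.holds(values.get(cond.marker))
            if verdict is False:
                return False
            if verdict is None:
                saw_missing = True
        return None if saw_missing else True

    def text(self) -> str:
        body = " and ".join(c.text() for c in self.conditions)
        return f"if {body} then more likely {_CLASS_TEXT[self.consequent]}"


# ---------------------------------------------------------------------------
# Rule DSL
# ---------------------------------------------------------------------------

_LINE_RE = re.compile(
    r"^if\s+(?P<body>.+?)\s+then\s+more\s+likely\s+"
    r"(?P<cls>healthy|mild cognitive impairment)\s*"
    r"(?:#\s*pr=(?P<pr>\d+(?:\.\d+)?)\s+pa=(?P<pa>\d+)\s*)?$",
    re.IGNORECASE,
)
_COND_RE = re.compile(r"^(?P<marker>\w+)\s*(?P<op><=|≤|>|=)\s*(?P<thr>\S+)$")


def parse_rules(dsl_text: str) -> list[Rule]:
    """Parse the rule DSL: ``if <cond> (and <cond>)* then more likely
    <class>``, optionally annotated ``# pr=.. pa=..``; one rule per line."""
    rules: list[Rule] = []
    for line_no, raw in enumerate(dsl_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _LINE_RE.match(line)
        if m is None:
            raise RuleParseError("not an if-then rule", line_no=line_no, token=line[:60])
        conditions = []
        for part in re.split(r"\s+and\s+", m.group("body"), flags=re.IGNORECASE):
            cm = _COND_RE.match(part.strip())
            if cm is None:
                raise RuleParseError("malformed condition", line_no=line_no, token=part.strip())
            op = "<=" if cm.group("op") == "≤" else cm.group("op")
            thr_text = cm.group("thr")
            if op == "=":
                thr: float | str = thr_text.lower()
                if thr not in (FEMALE, MALE):
                    raise RuleParseError("unknown category", line_no=line_no, token=thr_text)
            else:
                try:
                    thr = float(thr_text)
                except ValueError:
                    raise RuleParseError("non-numeric threshold", line_no=line_no, token=thr_text)
            conditions.append(Condition(cm.group("marker"), op, thr))
        pr = float(m.group("pr")) if m.group("pr") else None
        pa = int(m.group("pa")) if m.group("pa") else None
        rules.append(
            Rule(tuple(conditions), _TEXT_CLASS[m.group("cls").lower()], pr=pr, pa=pa)
        )
    return rules


def serialize_rule(rule: Rule) -> str:
    line = rule.text()
    if rule.pr is not None and rule.pa is not None:
        line += f"  # pr={rule.pr:.2f} pa={rule.pa}"
    return line


def serialize_rules(rules: Sequence[Rule]) -> str:
    return "\n".join(serialize_rule(r) for r in rules) + ("\n" if rules else "")


@lru_cache(maxsize=1)
def _builtin_numeric_rules() -> tuple[Rule, ...]:
    text = resources.files("cogdiag.data").joinpath("numeric_rules.txt").read_text("utf-8")
    return tuple(parse_rules(text))


def builtin_numeric_rules() -> list[Rule]:
    """The bundled twenty numeric rules with their printed pr/pa annotations."""
    return list(_builtin_numeric_rules())


# ---------------------------------------------------------------------------
# Tree fitting
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    sample_ids: np.ndarray
    label: str  # majority label of reaching samples
    depth: int
    condition: Optional[Condition] = None  # split sending samples left when true
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.condition is None

    def serialize(self) -> str:
        if self.is_leaf:
            return f"leaf({self.label},n={len(self.sample_ids)})"
        return (
            f"[{self.condition.text()} n={len(self.sample_ids)} "
            f"L:{self.left.serialize()} R:{self.right.serialize()}]"
        )


def _gini(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    p = np.mean(y == MCI)
    return 2.0 * p * (1.0 - p)


def _majority(y: np.ndarray) -> str:
    # ties break to healthy, the cohort's majority class
    return MCI if np.sum(y == MCI) > len(y) / 2 else HEALTHY


def _candidate_conditions(df: pd.DataFrame, idx: np.ndarray) -> list[Condition]:
    conds: list[Condition] = []
    for col in df.columns:
        vals = df[col].to_numpy()[idx]
        if col in CATEGORICAL_MARKERS:
            if len(set(vals)) > 1:
                conds.append(Condition(col, "=", FEMALE))
            continue
        uniq = np.unique(vals.astype(float))
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        conds.extend(Condition(col, "<=", float(t)) for t in mids)
    return conds


def _split_mask(df: pd.DataFrame, idx: np.ndarray, cond: Condition) -> np.ndarray:
    vals = df[cond.marker].to_numpy()[idx]
    if cond.op == "=":
        return vals == cond.threshold
    return vals.astype(float) <= cond.threshold  # fitted splits are always "<="


def fit_tree(
    df: pd.DataFrame,
    labels: Sequence[str],
    max_depth: int = 2,
    min_leaf: Optional[int] = None,
    seed: int = 0,
) -> TreeNode:
    """Fit a binary Gini decision tree on the marker table.

    ``min_leaf`` defaults to the rule support floor, ceil(0.10 * n). The fit
    is deterministic: candidate splits are scanned in fixed column order and
    exact gain ties keep the first candidate; ``seed`` only randomizes
    bootstrap resampling in :func:`induce_rules`.
    """
    y = np.asarray(labels)
    if len(y) != len(df):
        raise ValueError("markers and labels length mismatch")
    if df.isna().any().any():
        raise ValueError("tree fitting requires complete markers")
    if min_leaf is None:
        min_leaf = support_floor(len(y))
    if len(set(y)) < 2:
        warnings.warn("single-class input; returning a one-leaf tree", stacklevel=2)
        return TreeNode(sample_ids=np.arange(len(y)), label=_majority(y), depth=0)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(sample_ids=idx, label=_majority(y[idx]), depth=depth)
        if depth >= max_depth or len(set(y[idx])) < 2:
            return node
        parent_imp = _gini(y[idx])
        best = None  # (weighted_impurity, cond, mask)
        for cond in _candidate_conditions(df, idx):
            mask = _split_mask(df, idx, cond)
            n_l = int(mask.sum())
            n_r = len(idx) - n_l
            if n_l < min_leaf or n_r < min_leaf:
                continue
            w_imp = (n_l * _gini(y[idx[mask]]) + n_r * _gini(y[idx[~mask]])) / len(idx)
            if best is None or w_imp < best[0] - 1e-12:
                best = (w_imp, cond, mask)
        if best is None or parent_imp - best[0] <= 1e-12:
            return node
        _, cond, mask = best
        node.condition = cond
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node

    return build(np.arange(len(y)), 0)


# ---------------------------------------------------------------------------
# Rule extraction and filtering
# ---------------------------------------------------------------------------

def support_floor(n_train: int, min_support_frac: float = 0.10) -> int:
    return math.ceil(min_support_frac * n_train)


def measure_rule(conditions: Sequence[Condition], df: pd.DataFrame, labels: Sequence[str]):
    """(pa, pr, majority consequent) of an antecedent on the training table."""
    y = np.asarray(labels)
    mask = np.ones(len(df), dtype=bool)
    for cond in conditions:
        vals = df[cond.marker].to_numpy()
        if cond.op == "=":
            mask &= vals == cond.threshold
        elif cond.op == "<=":
            mask &= vals.astype(float) <= cond.threshold
        else:
            mask &= vals.astype(float) > cond.threshold
    pa = int(mask.sum())
    if pa == 0:
        return 0, None, None
    consequent = _majority(y[mask])
    pr = 100.0 * float(np.sum(y[mask] == consequent)) / pa
    return pa, pr, consequent


def extract_rules(tree: TreeNode, df: pd.DataFrame, labels: Sequence[str]) -> list[Rule]:
    """One candidate rule per path prefix (every node below the root); the
    consequent is the majority training label among antecedent matches."""
    candidates: list[Rule] = []

    def walk(node: TreeNode, path: tuple[Condition, ...]) -> None:
        if node.is_leaf:
            return
        for cond, child in ((node.condition, node.left), (node.condition.complement(), node.right)):
            antecedent = path + (cond,)
            pa, pr, consequent = measure_rule(antecedent, df, labels)
            if pa > 0:
                candidates.append(
                    Rule(antecedent, consequent, pr=pr, pa=pa, provenance="tree")
                )
            walk(child, antecedent)

    walk(tree, ())
    return candidates


def filter_rules(
    candidates: Sequence[Rule],
    n_train: int,
    min_support_frac: float = 0.10,
    min_confidence_pct: float = 70.0,
) -> list[Rule]:
    """Keep rules with pa >= ceil(min_support_frac * n_train) and pr strictly
    above min_confidence_pct, sorted by pr then pa descending."""
    floor = support_floor(n_train, min_support_frac)
    kept = [
        r
        for r in candidates
        if r.pa is not None and r.pa >= floor and r.pr is not None and r.pr > min_confidence_pct
    ]
    return sorted(kept, key=lambda r: (-r.pr, -r.pa))


def add_inversions(
    retained: Sequence[Rule],
    df: pd.DataFrame,
    labels: Sequence[str],
    n_train: Optional[int] = None,
    min_support_frac: float = 0.10,
) -> list[Rule]:
    """Append the complementary rule of every retained single-condition stump
    rule. Inversions are exempt from the confidence filter but must still
    clear the support floor; their pr/pa/consequent are measured on the
    training table."""
    n_train = n_train if n_train is not None else len(df)
    floor = support_floor(n_train, min_support_frac)
    out = list(retained)
    seen = {(r.conditions, r.consequent) for r in retained}
    for rule in retained:
        if len(rule.conditions) != 1 or rule.provenance != "tree":
            continue
        comp = (rule.conditions[0].complement(),)
        pa, pr, consequent = measure_rule(comp, df, labels)
        if pa < floor or consequent is None:
            continue
        key = (comp, consequent)
        if key in seen:
            continue
        seen.add(key)
        out.append(Rule(comp, consequent, pr=pr, pa=pa, provenance="inversion"))
    return out


def induce_rules(
    df: pd.DataFrame,
    labels: Sequence[str],
    max_depth: int = 2,
    seed: int = 0,
    n_trees: int = 1,
    min_support_frac: float = 0.10,
    min_confidence_pct: float = 70.0,
) -> list[Rule]:
    """Full induction: fit tree(s), extract path-prefix candidates, filter,
    and add stump inversions. With ``n_trees > 1`` extra trees are fit on
    seeded bootstrap resamples and rules are de-duplicated (pr/pa always
    re-measured on the full training table)."""
    y = np.asarray(labels)
    n = len(y)
    all_candidates: list[Rule] = []
    seen: set = set()
    rng = np.random.default_rng(seed)
    for t in range(n_trees):
        if t == 0:
            sub_df, sub_y = df, y
        else:
            idx = rng.integers(0, n, size=n)
            sub_df, sub_y = df.iloc[idx].reset_index(drop=True), y[idx]
        tree = fit_tree(sub_df, sub_y, max_depth=max_depth, min_leaf=support_floor(n, min_support_frac))
        for rule in extract_rules(tree, sub_df, sub_y):
            # re-measure on the full training table so pr/pa are comparable
            pa, pr, consequent = measure_rule(rule.conditions, df, y)
            if pa == 0:
                continue
            key = (rule.conditions, consequent)
            if key in seen:
                continue
            seen.add(key)
            all_candidates.append(replace(rule, pa=pa, pr=pr, consequent=consequent))
    retained = filter_rules(all_candidates, n, min_support_frac, min_confidence_pct)
    return add_inversions(retained, df, y, n, min_support_frac)
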