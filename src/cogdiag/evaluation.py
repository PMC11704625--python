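"""Cohort splitting, metrics, wrapper selection, and repeated-run evaluation.

The split protocol draws a class-balanced held-out test set (24 per class by
default) from marker-complete participants, keeps everyone else as the
reference set, and samples a class-balanced training set (25 per class) from
the reference set. Rule groups are induced per marker family; a greedy
wrapper adds groups while internal cross-validated accuracy improves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import HEALTHY, MCI, ParticipantRecord
from .engine import AnyRule, DeterministicBackend, classify
from .errors import SplitError
from .induction import Rule, induce_rules
from .markers import MARKER_GROUPS, MarkerVector, apply_scale, extract_markers, fit_scale
from .textmarkers import (
    JournalFeatures,
    TextThresholds,
    builtin_text_rules,
    fit_text_thresholds,
    journal_features,
)

#: Row order of the single-vs-fused comparison (six families, then fusion).
GROUP_ORDER = ("demographics", "behavior", "nback", "ema", "journal", "test_session")
TEXT_GROUPS = {"journal": "speech", "test_session": "testing_session"}


@dataclass(frozen=True)
class CohortSplit:
    reference: tuple[str, ...]
    training: tuple[str, ...]
    test: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        assert not set(self.test) & set(self.reference)
        assert set(self.training) <= set(self.reference)


def make_split(
    labels: Mapping[str, str],
    eligible: Optional[set[str]] = None,
    seed: int = 0,
    test_per_class: int = 24,
    train_per_class: int = 25,
) -> CohortSplit:
    """Draw the reference/training/test split.

    Test members come only from marker-complete (eligible) participants, with
    equal class counts; the reference set is everyone else; the training set
    is an equal-class sample from eligible reference members.
    """
    eligible = set(labels) if eligible is None else eligible
    rng = np.random.default_rng(seed)
    by_class = {
        cls: sorted(pid for pid in labels if labels[pid] == cls and pid in eligible)
        for cls in (HEALTHY, MCI)
    }
    for cls, ids in by_class.items():
        if len(ids) < test_per_class + train_per_class:
            raise SplitError(
                f"class {cls!r} has {len(ids)} eligible participants; "
                f"need >= {test_per_class + train_per_class}"
            )
    test: list[str] = []
    for cls in (HEALTHY, MCI):
        test.extend(rng.choice(by_class[cls], size=test_per_class, replace=False))
    test_set = set(test)
    reference = tuple(sorted(pid for pid in labels if pid not in test_set))
    training: list[str] = []
    for cls in (HEALTHY, MCI):
        pool = sorted(pid for pid in by_class[cls] if pid not in test_set)
        training.extend(rng.choice(pool, size=train_per_class, replace=False))
    return CohortSplit(
        reference=reference,
        training=tuple(sorted(training)),
        test=tuple(sorted(test)),
        seed=seed,
    )


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    mci_precision: float
    mci_recall: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "mci_precision": self.mci_precision,
            "mci_recall": self.mci_recall,
            "mcc": self.mcc,
        }


def compute_metrics(
    predictions: Sequence[str], labels: Sequence[str], positive_class: str = MCI
) -> Metrics:
    """Accuracy, positive-class precision/recall, and the Matthews correlation
    coefficient (0 by convention when any denominator factor is 0)."""
    if len(predictions) != len(labels):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(labels)} labels"
        )
    if not labels:
        raise ValueError("empty inputs")
    pred = np.asarray(predictions)
    true = np.asarray(labels)
    tp = int(np.sum((pred == positive_class) & (true == positive_class)))
    fp = int(np.sum((pred == positive_class) & (true != positive_class)))
    fn = int(np.sum((pred != positive_class) & (true == positive_class)))
    tn = int(np.sum((pred != positive_class) & (true != positive_class)))
    accuracy = (tp + tn) / len(true)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return Metrics(accuracy, precision, recall, mcc)


# ---------------------------------------------------------------------------
# Pipeline context: markers, scaling, text features for one cohort+split
# ---------------------------------------------------------------------------

@dataclass
class PipelineContext:
    records: dict[str, ParticipantRecord]
    labels: dict[str, str]
    raw: dict[str, MarkerVector]
    scaled: dict[str, dict]
    features: dict[str, JournalFeatures]
    thresholds: Optional[TextThresholds]
    split: CohortSplit


def eligibility(raw: Mapping[str, MarkerVector]) -> set[str]:
    """Participants with complete behavior, EMA, and shape-test markers."""
    needed = MARKER_GROUPS["behavior"] + MARKER_GROUPS["ema"] + MARKER_GROUPS["nback"]
    return {pid for pid, mv in raw.items() if mv.is_complete(needed)}


def build_context(
    records: Sequence[ParticipantRecord],
    split: Optional[CohortSplit] = None,
    seed: int = 0,
    ema_per_day: int = 4,
) -> PipelineContext:
    """Extract markers for every participant, fit scale bounds and text
    thresholds on the reference set, and scale everyone."""
    rec_map = {r.id: r for r in records}
    labels = {r.id: r.label for r in records}
    raw = {r.id: extract_markers(r, ema_per_day=ema_per_day) for r in records}
    if split is None:
        split = make_split(labels, eligibility(raw), seed=seed)
    bounds = fit_scale([raw[pid] for pid in split.reference])
    scaled = {pid: apply_scale(mv, bounds) for pid, mv in raw.items()}
    features = {r.id: journal_features(r.journal_texts) for r in records}
    ref_feats = [features[pid] for pid in split.reference]
    try:
        thresholds = fit_text_thresholds(ref_feats)
    except ValueError:
        thresholds = None
    return PipelineContext(rec_map, labels, raw, scaled, features, thresholds, split)


def group_rules(
    ctx: PipelineContext,
    group: str,
    train_ids: Sequence[str],
    max_depth: int = 2,
    seed: int = 0,
) -> list[AnyRule]:
    """Rules for one marker family: induced from the training markers for
    numeric families; the fixed bundled text rules for journal/test-session."""
    if group in TEXT_GROUPS:
        return list(builtin_text_rules(TEXT_GROUPS[group]))
    columns = list(MARKER_GROUPS[group])
    df = pd.DataFrame([{c: ctx.scaled[pid][c] for c in columns} for pid in train_ids])
    y = [ctx.labels[pid] for pid in train_ids]
    return list(induce_rules(df, y, max_depth=max_depth, seed=seed))


def rules_for_groups(
    ctx: PipelineContext,
    groups: Sequence[str],
    train_ids: Sequence[str],
    max_depth: int = 2,
    seed: int = 0,
) -> list[AnyRule]:
    rules: list[AnyRule] = []
    for g in groups:
        rules.extend(group_rules(ctx, g, train_ids, max_depth=max_depth, seed=seed))
    return rules


def predict(
    ctx: PipelineContext,
    rules: Sequence[AnyRule],
    ids: Sequence[str],
    policy: str = "confidence_weighted",
) -> list[str]:
    backend = DeterministicBackend(thresholds=ctx.thresholds, policy=policy)
    preds = []
    for pid in ids:
        rec = ctx.records[pid]
        if not rules:
            preds.append(HEALTHY)  # majority class
            continue
        d = classify(
            rec.pseudonym,
            ctx.scaled[pid],
            rec.journal_texts,
            rec.interview_ratings,
            rules,
            backend=backend,
        )
        preds.append(d.label)
    return preds


# ---------------------------------------------------------------------------
# Wrapper selection
# ---------------------------------------------------------------------------

def _stratified_folds(
    ids: Sequence[str], labels: Mapping[str, str], n_folds: int, rng: np.random.Generator
) -> list[list[str]]:
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for cls in (HEALTHY, MCI):
        members = sorted(pid for pid in ids if labels[pid] == cls)
        members = list(np.asarray(members)[rng.permutation(len(members))])
        for i, pid in enumerate(members):
            folds[i % n_folds].append(pid)
    return folds


def _cv_score(
    ctx: PipelineContext,
    groups: Sequence[str],
    folds: Sequence[Sequence[str]],
    policy: str,
    seed: int,
) -> tuple[float, int]:
    """(mean fold accuracy, total rule count) for a candidate group set."""
    accs = []
    n_rules = 0
    for k, holdout in enumerate(folds):
        train = [pid for j, fold in enumerate(folds) if j != k for pid in fold]
        rules = rules_for_groups(ctx, groups, train, seed=seed)
        n_rules = max(n_rules, len(rules))
        preds = predict(ctx, rules, holdout, policy)
        accs.append(compute_metrics(preds, [ctx.labels[p] for p in holdout]).accuracy)
    return float(np.mean(accs)), n_rules


def wrapper_select(
    ctx: PipelineContext,
    groups: Sequence[str] = GROUP_ORDER,
    seed: int = 0,
    n_folds: int = 5,
    policy: str = "confidence_weighted",
) -> list[str]:
    """Greedy forward selection over rule groups, scored by deterministic-
    engine accuracy on a stratified internal cross-validation of the training
    set. Stops when no addition improves; ties prefer fewer rules, then the
    fixed group order."""
    if not groups:
        raise ValueError("no groups to select from")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(ctx.split.training, ctx.labels, n_folds, rng)
    selected: list[str] = []
    best_score = -1.0
    remaining = list(groups)
    while remaining:
        scored = []
        for order_idx, g in enumerate(remaining):
            score, n_rules = _cv_score(ctx, selected + [g], folds, policy, seed)
            scored.append((score, -n_rules, -order_idx, g))
        scored.sort(reverse=True)
        top_score, _, _, top_group = scored[0]
        if top_score <= best_score:
            break
        best_score = top_score
        selected.append(top_group)
        remaining.remove(top_group)
    return selected


# ---------------------------------------------------------------------------
# Repeated-run evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    runs: list[dict[str, float]]
    mean: dict[str, float]
    sd: dict[str, float]
    n_runs: int
    selected_groups: Optional[list[str]] = None
    config: dict = field(default_factory=dict)
    run_predictions: list[list[str]] = field(default_factory=list)
    run_truth: list[list[str]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "runs": self.runs,
            "mean": self.mean,
            "sd": self.sd,
            "n_runs": self.n_runs,
            "selected_groups": self.selected_groups,
            "config": self.config,
            "run_predictions": self.run_predictions,
            "run_truth": self.run_truth,
        }


def _summarize(
    runs: list[dict[str, float]], config: dict, selected=None, preds=None, truths=None
) -> EvaluationReport:
    keys = list(runs[0])
    mean = {k: float(np.mean([r[k] for r in runs])) for k in keys}
    sd = {k: float(np.std([r[k] for r in runs])) for k in keys}
    return EvaluationReport(
        runs, mean, sd, len(runs), selected, config, preds or [], truths or []
    )


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> float:
    """Plain Welch two-sample t statistic (for comparing metric runs)."""
    x_a, y_a = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    se = math.sqrt(x_a.var(ddof=1) / len(x_a) + y_a.var(ddof=1) / len(y_a))
    return float((x_a.mean() - y_a.mean()) / se) if se > 0 else 0.0


def evaluate(
    records: Sequence[ParticipantRecord],
    groups: Sequence[str] = GROUP_ORDER,
    n_runs: int = 30,
    seed: int = 0,
    resample: str = "split",
    split: Optional[CohortSplit] = None,
    use_wrapper: bool = False,
    policy: str = "confidence_weighted",
) -> EvaluationReport:
    """Run the full pipeline ``n_runs`` times and report mean +/- SD.

    ``resample='split'`` re-draws the reference/training/test split each run
    (the configurable stand-in for backend nondeterminism); ``resample='none'``
    repeats the identical deterministic run, collapsing the SD to zero.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if resample not in ("split", "none"):
        raise ValueError(f"unknown resample mode {resample!r}")
    runs: list[dict[str, float]] = []
    all_preds: list[list[str]] = []
    all_truth: list[list[str]] = []
    selected: Optional[list[str]] = None
    fixed_ctx: Optional[PipelineContext] = None
    for i in range(n_runs):
        run_seed = seed + i if resample == "split" else seed
        if resample == "none" and fixed_ctx is not None:
            ctx = fixed_ctx
        else:
            ctx = build_context(records, split=split if resample == "none" else None, seed=run_seed)
            if resample == "none":
                fixed_ctx = ctx
        if use_wrapper:
            selected = wrapper_select(ctx, groups, seed=run_seed, policy=policy)
            active = selected or list(groups)
        else:
            active = list(groups)
        rules = rules_for_groups(ctx, active, ctx.split.training, seed=run_seed)
        if not rules:
            warnings.warn(
                f"no rules survived for groups {list(active)}; "
                "falling back to majority-class predictions",
                stacklevel=2,
            )
        preds = predict(ctx, rules, ctx.split.test, policy)
        truth = [ctx.labels[p] for p in ctx.split.test]
        runs.append(compute_metrics(preds, truth).as_dict())
        all_preds.append(preds)
        all_truth.append(truth)
    config = {
        "groups": list(groups),
        "n_runs": n_runs,
        "seed": seed,
        "resample": resample,
        "use_wrapper": use_wrapper,
        "policy": policy,
    }
    return _summarize(runs, config, selected, all_preds, all_truth)


def compare_single_vs_fused(
    records: Sequence[ParticipantRecord],
    seed: int = 0,
    n_runs: int = 1,
    resample: str = "none",
    policy: str = "confidence_weighted",
) -> list[tuple[str, EvaluationReport]]:
    """One report per single marker family, one for all families fused, and
    one for wrapper selection — eight rows in a fixed order."""
    rows: list[tuple[str, EvaluationReport]] = []
    for g in GROUP_ORDER:
        rows.append(
            (g, evaluate(records, [g], n_runs=n_runs, seed=seed, resample=resample, policy=policy))
        )
    rows.append(
        ("all", evaluate(records, GROUP_ORDER, n_runs=n_runs, seed=seed, resample=resample, policy=policy))
    )
    rows.append(
        (
            "wrapper",
            evaluate(
                records,
                GROUP_ORDER,
                n_runs=n_runs,
                seed=seed,
                resample=resample,
                use_wrapper=True,
                policy=policy,
            ),
        )
    )
    return rows
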