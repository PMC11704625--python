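"""Numeric marker extraction and 0-10 integer rescaling.

Markers are computed from raw per-participant streams: daily behavior
aggregates (activity level, distance from home), EMA summaries, and
shape-test (n-back) summaries, plus pass-through demographics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import ParticipantRecord, SensorDay
from .errors import DegenerateBoundsError, InsufficientDataError, MissingDataError

#: Column order of the flat marker table (demographics first).
MARKER_NAMES = (
    "age",
    "sex",
    "education_years",
    "physical_activity_level",
    "physical_activity_variance",
    "distance_traveled_from_home",
    "distance_traveled_variance",
    "mental_sharpness_mean",
    "mental_sharpness_variance",
    "EMA_compliance",
    "shape_learning_rate",
    "shape_score_mean",
    "shape_score_sd",
)

#: Real-valued markers that get min-max rescaled to the 0-10 integer axis.
#: Age and education are already small integers and pass through unscaled;
#: sex stays categorical.
REAL_VALUED_MARKERS = MARKER_NAMES[3:]

MARKER_GROUPS: dict[str, tuple[str, ...]] = {
    "demographics": ("age", "sex", "education_years"),
    "behavior": (
        "physical_activity_level",
        "physical_activity_variance",
        "distance_traveled_from_home",
        "distance_traveled_variance",
    ),
    "nback": ("shape_learning_rate", "shape_score_mean", "shape_score_sd"),
    "ema": ("mental_sharpness_mean", "mental_sharpness_variance", "EMA_compliance"),
}

GRID_METERS = 10.0


@dataclass
class MarkerVector:
    age: int
    sex: str
    education_years: int
    physical_activity_level: Optional[float] = None
    physical_activity_variance: Optional[float] = None
    distance_traveled_from_home: Optional[float] = None
    distance_traveled_variance: Optional[float] = None
    mental_sharpness_mean: Optional[float] = None
    mental_sharpness_variance: Optional[float] = None
    EMA_compliance: Optional[float] = None
    shape_learning_rate: Optional[float] = None
    shape_score_mean: Optional[float] = None
    shape_score_sd: Optional[float] = None
    scaled: Optional[dict] = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in MARKER_NAMES}

    def is_complete(self, names: Sequence[str] = REAL_VALUED_MARKERS) -> bool:
        return all(getattr(self, n) is not None for n in names)


@dataclass(frozen=True)
class ScaleBounds:
    """Per-marker (min, max) learned from a reference cohort."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if hi < lo:
                raise DegenerateBoundsError(f"max < min for marker {name!r}")


def _snap(points: np.ndarray, grid: float = GRID_METERS) -> np.ndarray:
    return np.floor(points / grid).astype(np.int64)


def _modal_cell_mask(points: np.ndarray, grid: float) -> np.ndarray:
    """Boolean mask of the points in the most populous grid cell; ties break
    to the cell visited earliest."""
    cells = _snap(points, grid)
    # pack the cell pair into one integer key for fast grouping
    key = cells[:, 0] * (1 << 32) + cells[:, 1]
    uniq, first, counts = np.unique(key, return_index=True, return_counts=True)
    top = counts == counts.max()
    best = uniq[top][np.argmin(first[top])]
    return key == best


def detect_home(day: SensorDay, grid: float = GRID_METERS) -> np.ndarray:
    """Locate the day's home: the most frequently visited 10 m grid cell among
    the first 300 readings, ties broken by earliest visit. Returns the
    centroid of the readings in the winning cell."""
    if day.missing or day.locations is None or len(day.locations) == 0:
        raise MissingDataError(f"day {day.day_index} has no location readings")
    pts = np.asarray(day.locations, dtype=float)[:300]
    return pts[_modal_cell_mask(pts, grid)].mean(axis=0)


def participant_home(days: Sequence[SensorDay], grid: float = GRID_METERS) -> np.ndarray:
    """Participant-level home: centroid of daily homes in the modal home cell
    over the collection period (ties broken by earliest day)."""
    homes = [detect_home(d, grid) for d in days if not d.missing]
    if not homes:
        raise InsufficientDataError("no non-missing sensor days")
    homes_a = np.asarray(homes)
    return homes_a[_modal_cell_mask(homes_a, grid)].mean(axis=0)


def daily_behavior(
    day: SensorDay, home: np.ndarray, distance_stat: str = "mean"
) -> tuple[float, float]:
    """Daily (activity, distance-from-home). Activity is the day's total
    acceleration; distance aggregates per-reading Euclidean distances from
    home with the configured statistic (mean by default)."""
    if day.missing:
        raise MissingDataError(f"day {day.day_index} is missing")
    dists = np.linalg.norm(np.asarray(day.locations, dtype=float) - home, axis=1)
    agg = float(dists.mean()) if distance_stat == "mean" else float(dists.max())
    return float(day.accel_total), agg


def aggregate_behavior(
    days: Sequence[SensorDay], home: np.ndarray | None = None, distance_stat: str = "mean"
) -> tuple[float, float, float, float]:
    """Mean and population variance of daily activity and daily distance over
    non-missing days only.

    Returns (activity_mean, activity_variance, distance_mean, distance_variance).
    """
    present = [d for d in days if not d.missing]
    if len(present) < 2:
        raise InsufficientDataError(f"need >= 2 non-missing days, got {len(present)}")
    if home is None:
        home = participant_home(days)
    acts, dists = zip(*(daily_behavior(d, home, distance_stat) for d in present))
    acts_a, dists_a = np.asarray(acts), np.asarray(dists)
    return (
        float(acts_a.mean()),
        float(acts_a.var()),
        float(dists_a.mean()),
        float(dists_a.var()),
    )


def ema_markers(
    responses: Sequence[tuple[int, int, Optional[int]]], n_scheduled: int
) -> tuple[Optional[float], Optional[float], float]:
    """(mean, variance, compliance) of EMA responses.

    Mean/variance are over answered prompts; compliance is answered divided
    by scheduled. With zero answered prompts the mean and variance are
    reported missing and compliance is 0.
    """
    answered = [v for _, _, v in responses if v is not None]
    if n_scheduled <= 0:
        raise InsufficientDataError("no scheduled EMA prompts")
    if not answered:
        return None, None, 0.0
    arr = np.asarray(answered, dtype=float)
    return float(arr.mean()), float(arr.var()), len(answered) / n_scheduled


def nback_markers(
    daily: Sequence[tuple[int, float]]
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(learning_rate, mean, sd) of daily shape-test accuracies.

    The learning rate is the OLS slope of the first 6 scores (by day order)
    against 0..5; mean and population SD run over all scores.
    """
    if not daily:
        return None, None, None
    ordered = sorted(daily, key=lambda t: t[0])
    scores = np.asarray([s for _, s in ordered], dtype=float)
    rate = None
    if len(scores) >= 6:
        rate = float(np.polyfit(np.arange(6.0), scores[:6], 1)[0])
    mean = float(scores.mean())
    sd = float(scores.std()) if len(scores) >= 2 else None
    return rate, mean, sd


def extract_markers(
    record: ParticipantRecord, ema_per_day: int = 4, distance_stat: str = "mean"
) -> MarkerVector:
    """Compute the full raw marker vector for one participant."""
    mv = MarkerVector(
        age=record.age, sex=record.sex, education_years=record.education_years
    )
    try:
        act_m, act_v, dist_m, dist_v = aggregate_behavior(
            record.sensor_days, distance_stat=distance_stat
        )
        mv.physical_activity_level = act_m
        mv.physical_activity_variance = act_v
        mv.distance_traveled_from_home = dist_m
        mv.distance_traveled_variance = dist_v
    except InsufficientDataError:
        pass
    n_scheduled = len(record.sensor_days) * ema_per_day
    if n_scheduled > 0:
        mean, var, compliance = ema_markers(record.ema_responses, n_scheduled)
        mv.mental_sharpness_mean = mean
        mv.mental_sharpness_variance = var
        mv.EMA_compliance = compliance
    rate, nb_mean, nb_sd = nback_markers(record.nback_daily)
    mv.shape_learning_rate = rate
    mv.shape_score_mean = nb_mean
    mv.shape_score_sd = nb_sd
    return mv


def fit_scale(reference: Sequence[MarkerVector]) -> ScaleBounds:
    """Learn per-marker (min, max) over the reference cohort, ignoring
    missing values. A constant marker is a degenerate-bounds error."""
    bounds: dict[str, tuple[float, float]] = {}
    for name in REAL_VALUED_MARKERS:
        vals = [getattr(mv, name) for mv in reference if getattr(mv, name) is not None]
        if len(vals) < 2:
            raise DegenerateBoundsError(f"marker {name!r} has fewer than 2 values")
        lo, hi = min(vals), max(vals)
        if hi == lo:
            raise DegenerateBoundsError(f"marker {name!r} is constant at {lo}")
        bounds[name] = (float(lo), float(hi))
    return ScaleBounds(bounds)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def scale_value(x: float, lo: float, hi: float) -> int:
    """Map x to the 0-10 integer axis by min-max with round-half-up; inputs
    outside [lo, hi] clamp to the endpoints."""
    v = round_half_up(10.0 * (x - lo) / (hi - lo))
    return max(0, min(10, v))


def apply_scale(raw: MarkerVector, bounds: ScaleBounds) -> dict:
    """Produce the scaled marker map: real-valued markers on the 0-10 axis,
    demographics passed through (age/education as integers, sex categorical)."""
    scaled: dict = {"age": raw.age, "sex": raw.sex, "education_years": raw.education_years}
    for name in REAL_VALUED_MARKERS:
        x = getattr(raw, name)
        if x is None:
            scaled[name] = None
            continue
        lo, hi = bounds.bounds[name]
        scaled[name] = scale_value(x, lo, hi)
    raw.scaled = scaled
    return scaled


def markers_frame(
    records: Sequence[ParticipantRecord],
    vectors: Sequence[MarkerVector],
    scaled: bool = False,
) -> pd.DataFrame:
    """Flat marker table, one row per participant, marker columns named
    exactly as in the rule language."""
    rows = []
    for rec, mv in zip(records, vectors):
        base = {"id": rec.id, "pseudonym": rec.pseudonym, "label": rec.label}
        values = mv.scaled if scaled else mv.as_dict()
        if scaled and values is None:
            raise MissingDataError(f"participant {rec.id} has no scaled markers")
        base.update({name: values[name] for name in MARKER_NAMES})
        rows.append(base)
    return pd.DataFrame(rows, columns=["id", "pseudonym", "label", *MARKER_NAMES])
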