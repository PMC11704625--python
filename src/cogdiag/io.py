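"""Cohort / marker / report serialization with atomic writes.

The cohort container is schema-versioned JSON; the flat marker table is CSV
with columns named exactly as in the rule language.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, LABELS, ParticipantRecord, SensorDay
from .errors import SchemaError
from .markers import ScaleBounds

SCHEMA_VERSION = 1


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write-temp-then-rename so a crash never leaves a partial artifact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _day_to_json(day: SensorDay) -> dict:
    if day.missing:
        return {"day_index": day.day_index, "missing": True}
    return {
        "day_index": day.day_index,
        "missing": False,
        "accel_total": day.accel_total,
        "locations": np.asarray(day.locations).tolist(),
    }


def _record_to_json(rec: ParticipantRecord) -> dict:
    return {
        "id": rec.id,
        "pseudonym": rec.pseudonym,
        "label": rec.label,
        "age": rec.age,
        "sex": rec.sex,
        "education_years": rec.education_years,
        "sensor_days": [_day_to_json(d) for d in rec.sensor_days],
        "ema_responses": [list(t) for t in rec.ema_responses],
        "nback_daily": [list(t) for t in rec.nback_daily],
        "journal_texts": list(rec.journal_texts),
        "interview_ratings": dict(rec.interview_ratings),
    }


def cohort_to_json(records: Sequence[ParticipantRecord], config: CohortConfig | None = None) -> str:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "generator": "cogdiag",
        "config": None if config is None else {**config.__dict__},
        "participants": [_record_to_json(r) for r in records],
    }
    return json.dumps(doc, sort_keys=True, separators=(",", ":"))


def write_cohort(
    records: Sequence[ParticipantRecord], path: str | Path, config: CohortConfig | None = None
) -> None:
    atomic_write_text(path, cohort_to_json(records, config))


_REQUIRED_FIELDS = (
    "id",
    "pseudonym",
    "label",
    "age",
    "sex",
    "education_years",
    "sensor_days",
    "ema_responses",
    "nback_daily",
    "journal_texts",
    "interview_ratings",
)


def _record_from_json(obj: dict, pos: int) -> ParticipantRecord:
    pid = obj.get("id", f"<participant #{pos}>")
    for name in _REQUIRED_FIELDS:
        if name not in obj:
            raise SchemaError(f"participant {pid}: missing field {name!r}")
    if obj["label"] not in LABELS:
        raise SchemaError(f"participant {pid}: unknown label {obj['label']!r}")
    days = []
    for d in obj["sensor_days"]:
        if d.get("missing", False):
            days.append(SensorDay(day_index=d["day_index"], accel_total=None, locations=None, missing=True))
        else:
            days.append(
                SensorDay(
                    day_index=d["day_index"],
                    accel_total=d["accel_total"],
                    locations=np.asarray(d["locations"], dtype=float),
                    missing=False,
                )
            )
    return ParticipantRecord(
        id=obj["id"],
        pseudonym=obj["pseudonym"],
        label=obj["label"],
        age=obj["age"],
        sex=obj["sex"],
        education_years=obj["education_years"],
        sensor_days=days,
        ema_responses=[tuple(t) for t in obj["ema_responses"]],
        nback_daily=[tuple(t) for t in obj["nback_daily"]],
        journal_texts=list(obj["journal_texts"]),
        interview_ratings=dict(obj["interview_ratings"]),
    )


def read_cohort(path: str | Path) -> list[ParticipantRecord]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise SchemaError("not a cohort document (no schema_version)")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise SchemaError(f"unknown schema version {doc['schema_version']!r}")
    return [_record_from_json(obj, i) for i, obj in enumerate(doc.get("participants", []))]


def write_markers_csv(frame: pd.DataFrame, path: str | Path) -> None:
    atomic_write_text(path, frame.to_csv(index=False))


def read_markers_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_bounds(bounds: ScaleBounds, path: str | Path) -> None:
    atomic_write_text(path, json.dumps({"bounds": bounds.bounds}, indent=1, sort_keys=True))


def read_bounds(path: str | Path) -> ScaleBounds:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return ScaleBounds({k: tuple(v) for k, v in doc["bounds"].items()})


def write_json(obj, path: str | Path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=1, sort_keys=True))


def read_config_yaml(path: str | Path) -> CohortConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if "class_effects" in doc:
        doc["class_effects"] = {k: tuple(v) for k, v in doc["class_effects"].items()}
    try:
        return CohortConfig(**doc)
    except TypeError as exc:
        raise SchemaError(f"invalid cohort config: {exc}") from exc
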