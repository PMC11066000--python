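"""CSV schemas and file I/O for the protocol pipeline.

All files are UTF-8 CSV with a mandatory header row; post-operative days
are 1-based integers (day 1 = first post-operative day, day 0 = surgery
day for intra-operative events).

Schemas
-------
ledger
    animal_id, group, enrolled, severity, event_day, event_kind,
    exclusion_reason — one row per event; animals without events appear
    as a single row with blank event fields.
assessments
    animal_id, group, day, rt1, rt2, rt3, ot_distance, preop_weight_g,
    weight_g — one row per animal-day of raw measurements.
scores
    animal_id, day, r_score, o_score, b_score, total, severity.
tracks
    animal_id, day, frame, x, y — marker positions in tracker pixels.
autopsy
    animal_id, day, seg1..seg6 — segment grades 0-3.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .behavior import body_weight_loss, mean_rotarod
from .exceptions import SchemaError, ValidationError
from .scoring import RobComponents, RobScore, ScoringCriteria, compute_rob
from .survival import EVENT_KINDS, AnimalRecord, CohortLedger, Event

__all__ = [
    "read_ledger",
    "write_ledger",
    "read_assessments",
    "write_assessments",
    "read_scores",
    "write_scores",
    "read_tracks",
    "write_tracks",
    "read_autopsy",
    "write_autopsy",
    "score_assessments",
    "severities_from_scores",
]

LEDGER_COLUMNS = [
    "animal_id", "group", "enrolled", "severity", "event_day", "event_kind", "exclusion_reason",
]
ASSESSMENT_COLUMNS = [
    "animal_id", "group", "day", "rt1", "rt2", "rt3", "ot_distance", "preop_weight_g", "weight_g",
]
SCORE_COLUMNS = ["animal_id", "day", "r_score", "o_score", "b_score", "total", "severity"]
TRACK_COLUMNS = ["animal_id", "day", "frame", "x", "y"]
AUTOPSY_COLUMNS = ["animal_id", "day"] + [f"seg{i}" for i in range(1, 7)]


def _require_columns(df: pd.DataFrame, columns: Iterable[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required columns {missing}")


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str], name: str) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{name}: row {row + 2}, column '{col}': "
                f"value {out.loc[row, col]!r} is not numeric"
            )
        out[col] = coerced
    return out


# ---------------------------------------------------------------------------
# ledger

def write_ledger(ledger: CohortLedger, path) -> None:
    rows = []
    for a in ledger:
        base = {
            "animal_id": a.animal_id,
            "group": a.group,
            "enrolled": True,
            "severity": a.severity,
            "exclusion_reason": a.exclusion_reason,
        }
        if a.events:
            for e in a.events:
                rows.append({**base, "event_day": e.day, "event_kind": e.kind})
        else:
            rows.append({**base, "event_day": None, "event_kind": None})
    pd.DataFrame(rows, columns=LEDGER_COLUMNS).to_csv(path, index=False)


def read_ledger(path) -> CohortLedger:
    df = pd.read_csv(path, dtype={"animal_id": str})
    _require_columns(df, ["animal_id", "group"], "ledger")
    animals: list[AnimalRecord] = []
    for animal_id, sub in df.groupby("animal_id", sort=False):
        events = []
        for _, row in sub.iterrows():
            kind = row.get("event_kind")
            if isinstance(kind, str) and kind:
                if kind not in EVENT_KINDS:
                    raise SchemaError(
                        f"ledger: animal {animal_id}: unknown event kind {kind!r}"
                    )
                try:
                    day = int(row["event_day"])
                except (TypeError, ValueError):
                    raise SchemaError(
                        f"ledger: animal {animal_id}: event {kind!r} has no valid day "
                        f"({row.get('event_day')!r})"
                    ) from None
                events.append(Event(day, kind))
        first = sub.iloc[0]
        severity = first.get("severity")
        reason = first.get("exclusion_reason")
        animals.append(
            AnimalRecord(
                animal_id=str(animal_id),
                group=str(first["group"]),
                severity=severity if isinstance(severity, str) and severity else None,
                events=events,
                exclusion_reason=reason if isinstance(reason, str) and reason else None,
            )
        )
    ledger = CohortLedger(animals)
    ledger.validate()
    return ledger


# ---------------------------------------------------------------------------
# assessments / scores

def write_assessments(df: pd.DataFrame, path) -> None:
    _require_columns(df, ASSESSMENT_COLUMNS, "assessments")
    df.to_csv(path, index=False, columns=ASSESSMENT_COLUMNS)


def read_assessments(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str})
    if df.empty:
        return pd.DataFrame(columns=ASSESSMENT_COLUMNS)
    _require_columns(df, ASSESSMENT_COLUMNS, "assessments")
    return _coerce_numeric(
        df, ["day", "rt1", "rt2", "rt3", "ot_distance", "preop_weight_g", "weight_g"],
        "assessments",
    )


def write_scores(df: pd.DataFrame, path) -> None:
    _require_columns(df, SCORE_COLUMNS, "scores")
    df.to_csv(path, index=False, columns=SCORE_COLUMNS)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str})
    if df.empty:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    _require_columns(df, SCORE_COLUMNS, "scores")
    return _coerce_numeric(df, ["day", "r_score", "o_score", "b_score", "total"], "scores")


def score_assessments(
    assessments: pd.DataFrame,
    criteria: ScoringCriteria | None = None,
    prescored: bool = False,
) -> pd.DataFrame:
    """Score every animal-day row of an assessments table.

    Sub-scores are always recomputed from the raw trial latencies, track
    distance and weights; ``prescored=True`` instead accepts pre-binned
    r/o/b sub-score columns (an explicit traceability override for
    ledgers that kept only binned values).
    """
    criteria = criteria or ScoringCriteria.default()
    rows = []
    for idx, row in assessments.iterrows():
        try:
            if prescored:
                score = RobScore.from_subscores(
                    int(row["r_score"]), int(row["o_score"]), int(row["b_score"]), criteria
                )
            else:
                rt = mean_rotarod([row["rt1"], row["rt2"], row["rt3"]])
                bwl = body_weight_loss(row["preop_weight_g"], row["weight_g"])
                score = compute_rob(
                    RobComponents(rt, float(row["ot_distance"]), bwl), criteria
                )
        except (ValidationError, KeyError, TypeError) as exc:
            raise SchemaError(
                f"assessments row {int(idx) + 2} (animal {row.get('animal_id')!r}, "
                f"day {row.get('day')!r}): {exc}"
            ) from exc
        rows.append(
            {
                "animal_id": row["animal_id"],
                "day": int(row["day"]),
                "r_score": score.r_score,
                "o_score": score.o_score,
                "b_score": score.b_score,
                "total": score.total,
                "severity": score.severity,
            }
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def severities_from_scores(scores: pd.DataFrame, day: int = 1) -> dict[str, str]:
    """Map animal id -> severity class from the scores table at ``day``."""
    sub = scores[scores["day"] == day]
    return dict(zip(sub["animal_id"].astype(str), sub["severity"].astype(str)))


# ---------------------------------------------------------------------------
# tracks / autopsy

def write_tracks(df: pd.DataFrame, path) -> None:
    _require_columns(df, TRACK_COLUMNS, "tracks")
    df.to_csv(path, index=False, columns=TRACK_COLUMNS)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str})
    if df.empty:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    _require_columns(df, TRACK_COLUMNS, "tracks")
    return _coerce_numeric(df, ["day", "frame", "x", "y"], "tracks")


def write_autopsy(df: pd.DataFrame, path) -> None:
    _require_columns(df, AUTOPSY_COLUMNS, "autopsy")
    df.to_csv(path, index=False)


def read_autopsy(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str})
    if df.empty:
        return pd.DataFrame(columns=AUTOPSY_COLUMNS)
    _require_columns(df, AUTOPSY_COLUMNS, "autopsy")
    return _coerce_numeric(df, ["day"] + [f"seg{i}" for i in range(1, 7)], "autopsy")
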