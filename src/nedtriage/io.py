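"""Survey file I/O and the batch triage pipeline.

Surveys travel as CSV (one row per patient-month: ``patient_id``,
``month_index``, ``completion_date`` in ISO-8601, one column per item,
optional ``preference_response``) or as JSON-lines with the same fields.
The reader is fail-closed: unknown columns, out-of-range values, and
duplicate patient-months are rejected with row numbers, all collected
before reporting.  Due dates are enrollment + round(30.44 * month) days;
enrollment is inferred from each patient's first completed survey unless
supplied.
"""

from __future__ import annotations

import json
import logging
import math
import os
import tempfile
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .alerts import (
    DAYS_PER_MONTH, DEFAULT_CARE_STEPS, TriageResult, expected_due_date,
    triage_month,
)
from .config import ConfigError, ThresholdConfig, load_thresholds
from .schema import (
    DEFAULT_SCHEMA, ItemResponse, ResponseValidationError, SurveyRecord,
    SurveySchema, load_schema, PREFERENCE_VALUES,
)

logger = logging.getLogger("nedtriage")

_META_COLUMNS = ("patient_id", "month_index", "completion_date",
                 "preference_response")


class SurveyIOError(ValueError):
    """One or more rows of a survey file failed validation."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("survey file validation failed:\n  "
                         + "\n  ".join(self.errors))


def _parse_date(value) -> Optional[date]:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    return date.fromisoformat(str(value))


def _row_to_record(row: Mapping, item_ids: Sequence[str]) -> SurveyRecord:
    responses = []
    for iid in item_ids:
        raw = row.get(iid)
        if raw is None or raw == "" or (isinstance(raw, float) and math.isnan(raw)):
            responses.append(ItemResponse(item_id=iid, value=0, answered=False))
        else:
            responses.append(ItemResponse(item_id=iid, value=int(raw)))
    pref = row.get("preference_response")
    if pref is not None and (pref == "" or (isinstance(pref, float) and math.isnan(pref))):
        pref = None
    return SurveyRecord(
        patient_id=str(row["patient_id"]),
        month_index=int(row["month_index"]),
        completion_date=_parse_date(row.get("completion_date")),
        responses=tuple(responses),
        preference_response=pref,
    )


def read_surveys(path, schema: SurveySchema = DEFAULT_SCHEMA,
                 ) -> Dict[str, List[SurveyRecord]]:
    """Read and validate a survey CSV or JSON-lines file.

    Returns records grouped by patient, month-ordered.  All row-level
    problems are collected and raised together as :class:`SurveyIOError`.
    """
    path = Path(path)
    item_ids = [it.item_id for it in DEFAULT_SCHEMA.items] \
        if schema is DEFAULT_SCHEMA else [it.item_id for it in schema.items]
    if path.suffix in (".jsonl", ".ndjson", ".json"):
        rows = [json.loads(line) for line in
                path.read_text(encoding="utf-8").splitlines() if line.strip()]
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        rows = df.to_dict(orient="records")

    errors: List[str] = []
    if rows:
        known = set(item_ids) | set(_META_COLUMNS)
        unknown = [c for c in rows[0] if c not in known]
        if unknown:
            errors.append(f"unknown column(s): {', '.join(sorted(unknown))}")
    grouped: Dict[str, Dict[int, SurveyRecord]] = {}
    if not errors:
        from .schema import validate_record
        for lineno, row in enumerate(rows, start=2):  # 1-based + header
            try:
                rec = _row_to_record(row, item_ids)
                validate_record(rec, schema)
            except (ResponseValidationError, KeyError, ValueError) as exc:
                errors.append(f"row {lineno}: {exc}")
                continue
            months = grouped.setdefault(rec.patient_id, {})
            if rec.month_index in months:
                errors.append(
                    f"row {lineno}: duplicate (patient {rec.patient_id}, "
                    f"month {rec.month_index})")
                continue
            months[rec.month_index] = rec
    if errors:
        raise SurveyIOError(errors)
    return {pid: [months[m] for m in sorted(months)]
            for pid, months in sorted(grouped.items())}


def write_surveys(records: Sequence[SurveyRecord], path,
                  schema: SurveySchema = DEFAULT_SCHEMA) -> None:
    """Write survey records as CSV or JSON-lines (by file extension)."""
    path = Path(path)
    item_ids = [it.item_id for it in schema.items]
    rows = []
    for rec in records:
        row: dict = {
            "patient_id": rec.patient_id,
            "month_index": rec.month_index,
            "completion_date": (rec.completion_date.isoformat()
                                if rec.completion_date else ""),
        }
        rmap = rec.response_map
        for iid in item_ids:
            resp = rmap.get(iid)
            row[iid] = "" if resp is None or not resp.answered else resp.value
        row["preference_response"] = rec.preference_response or ""
        rows.append(row)
    if path.suffix in (".jsonl", ".ndjson", ".json"):
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, sort_keys=True) + "\n")
    else:
        cols = list(_META_COLUMNS[:3]) + item_ids + ["preference_response"]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def infer_enrollment_date(records: Sequence[SurveyRecord]) -> Optional[date]:
    """Enrollment inferred from the first completed survey: its completion
    date minus the nominal offset of its month index."""
    for rec in records:
        if rec.completion_date is not None:
            return rec.completion_date - timedelta(
                days=round(DAYS_PER_MONTH * rec.month_index))
    return None


@dataclass(frozen=True)
class MissedMonth:
    """An expected check-in with no survey on file: automatically overdue."""

    patient_id: str
    month_index: int
    due_date: Optional[date]


def triage_patient(
    records: Sequence[SurveyRecord],
    schema: SurveySchema = DEFAULT_SCHEMA,
    thresholds: Optional[ThresholdConfig] = None,
    enrollment_date: Optional[date] = None,
    horizon: Optional[int] = None,
    content_table=DEFAULT_CARE_STEPS,
) -> Tuple[List[TriageResult], List[MissedMonth]]:
    """Run the triage engine over one patient's months in order.

    Histories are threaded from month to month.  Months with no record
    between the first survey and ``horizon`` (default: the last observed
    month) are returned as :class:`MissedMonth` overdue flags.
    """
    thresholds = thresholds or ThresholdConfig()
    records = sorted(records, key=lambda r: r.month_index)
    if enrollment_date is None:
        enrollment_date = infer_enrollment_date(records)
    results: List[TriageResult] = []
    histories: Mapping = {}
    observed = set()
    for rec in records:
        result = triage_month(rec, histories, schema, thresholds,
                              enrollment_date=enrollment_date,
                              content_table=content_table)
        histories = result.histories
        results.append(result)
        observed.add(rec.month_index)
    missed: List[MissedMonth] = []
    if records:
        last = horizon - 1 if horizon is not None else records[-1].month_index
        pid = records[0].patient_id
        for m in range(records[0].month_index, last + 1):
            if m not in observed:
                due = (expected_due_date(enrollment_date, m)
                       if enrollment_date else None)
                missed.append(MissedMonth(pid, m, due))
    return results, missed


class RunConfig(BaseModel):
    """Batch-run configuration: input, config, and output locations."""

    model_config = ConfigDict(frozen=True)

    surveys: str
    out_dir: str
    schema_path: Optional[str] = None
    thresholds_path: Optional[str] = None
    horizon: Optional[int] = None


def _alert_row(result: TriageResult) -> dict:
    d = result.dashboard
    payload = result.alert.to_dict()
    payload.update({
        "patient_id": d.patient_id,
        "month_index": d.month_index,
        "scores": dict(result.scores),
        "care_steps": dict(result.feedback.care_steps),
        "contributing_questions": list(d.contributing_questions),
    })
    return payload


def run_triage(config: RunConfig,
               schema: Optional[SurveySchema] = None,
               thresholds: Optional[ThresholdConfig] = None) -> dict:
    """Triage every patient in a survey file and write the outputs.

    Writes ``alerts.jsonl`` (one audit-ready alert per patient-month)
    and ``dashboard.csv`` (the flat nurse-dashboard export, including
    overdue rows for missed months) atomically into ``out_dir``.
    Returns summary counts.  Any component error removes partial
    outputs and propagates.  Pre-loaded ``schema``/``thresholds``
    objects override the paths in ``config``.
    """
    schema = schema or load_schema(config.schema_path)
    thresholds = thresholds or load_thresholds(config.thresholds_path)
    grouped = read_surveys(config.surveys, schema)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    alert_rows: List[dict] = []
    dash_rows: List[dict] = []
    counts = {"green": 0, "yellow": 0, "orange": 0, "red": 0}
    overdue_count = 0
    for pid, records in grouped.items():
        results, missed = triage_patient(records, schema, thresholds,
                                         horizon=config.horizon)
        for res in results:
            alert_rows.append(_alert_row(res))
            counts[res.alert.level] += 1
            overdue_count += int(res.alert.overdue)
            row = {"patient_id": pid,
                   "month_index": res.dashboard.month_index,
                   "level": res.alert.level,
                   "overdue": res.alert.overdue}
            for dom in schema.scored_domains:
                row[f"state_{dom}"] = res.alert.domain_states[dom].state
            row["contributing_questions"] = ";".join(
                res.dashboard.contributing_questions)
            row["preference_response"] = res.alert.preference_response or ""
            dash_rows.append(row)
        for miss in missed:
            overdue_count += 1
            row = {"patient_id": pid, "month_index": miss.month_index,
                   "level": "", "overdue": True}
            for dom in schema.scored_domains:
                row[f"state_{dom}"] = ""
            row["contributing_questions"] = ""
            row["preference_response"] = ""
            dash_rows.append(row)

    dash_rows.sort(key=lambda r: (r["patient_id"], r["month_index"]))
    alerts_path = out_dir / "alerts.jsonl"
    dash_path = out_dir / "dashboard.csv"
    try:
        _atomic_write(alerts_path, "".join(
            json.dumps(row, sort_keys=True) + "\n" for row in alert_rows))
        dash_cols = (["patient_id", "month_index", "level", "overdue"]
                     + [f"state_{d}" for d in schema.scored_domains]
                     + ["contributing_questions", "preference_response"])
        _atomic_write(dash_path, pd.DataFrame(
            dash_rows, columns=dash_cols).to_csv(index=False))
    except Exception:
        for p in (alerts_path, dash_path):
            p.unlink(missing_ok=True)
        raise
    summary = {"n_patients": len(grouped), "n_records": len(alert_rows),
               "alerts": counts, "overdue": overdue_count}
    logger.info("triage complete: %s", summary)
    return summary


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except Exception:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
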