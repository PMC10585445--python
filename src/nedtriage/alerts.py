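"""Global alert engine: combine domain states, honor patient preference,
flag overdue surveys, and assemble patient feedback and the nurse
dashboard summary.

There are four global alert levels:

* **green** — every domain normal; no support necessary.
* **yellow** — a Δ threshold exceeded for the first time in some domain.
* **orange** — a repeat exceedance or a clinically urgent symptom; the
  patient is prompted for their preference on a nurse consultation.
* **red** — the patient accepted a nurse consultation while one or more
  orange domain states are present; direct nurse interaction required.

Red is reachable *only* through an accepted preference on an orange
alert: the escalation honors patient autonomy.  A declined orange stays
orange on the dashboard — the nurse may still act at their discretion.
Tailored self-management feedback is always the first line of response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from types import MappingProxyType
from typing import Mapping, Optional, Sequence

from .config import ConfigError, ThresholdConfig
from .domains import (
    GREEN, ORANGE, RED, SEVERITY, YELLOW,
    DomainHistory, DomainState, step_domain,
)
from .questions import UrgentFlag, collect_urgent_flags
from .schema import SurveyRecord, SurveySchema, score_survey

#: Mean calendar month in days; due date for month m is enrollment +
#: round(30.44 * m) days.
DAYS_PER_MONTH = 30.44

ACCEPTED = "accepted"
DECLINED = "declined"
NO_RESPONSE = "no_response"


class PreferenceContractError(ValueError):
    """An accepted consultation preference was recorded without an orange alert."""


@dataclass(frozen=True)
class GlobalAlert:
    """The combined 4-level alert for one patient-month."""

    level: str
    domain_states: Mapping[str, DomainState]
    urgent_flags: tuple[UrgentFlag, ...]
    preference_prompted: bool
    preference_response: Optional[str]
    overdue: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain_states",
                           MappingProxyType(dict(self.domain_states)))

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "domain_states": {
                d: {"state": s.state, "reasons": list(s.reasons)}
                for d, s in self.domain_states.items()},
            "urgent_flags": [
                {"tag": f.tag, "item_id": f.item_id, "domain_id": f.domain_id,
                 "value": f.value} for f in self.urgent_flags],
            "preference_prompted": self.preference_prompted,
            "preference_response": self.preference_response,
            "overdue": self.overdue,
        }


@dataclass(frozen=True)
class FeedbackPlan:
    """Self-management education references, one per alerting domain."""

    care_steps: Mapping[str, str]  # domain_id -> content reference key
    first_line: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "care_steps",
                           MappingProxyType(dict(self.care_steps)))


@dataclass(frozen=True)
class DashboardSummary:
    """What the nurse dashboard shows for one patient-month."""

    patient_id: str
    month_index: int
    level: str
    domain_states: Mapping[str, DomainState]
    contributing_questions: tuple[str, ...]
    overdue: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain_states",
                           MappingProxyType(dict(self.domain_states)))


@dataclass(frozen=True)
class TriageResult:
    alert: GlobalAlert
    feedback: FeedbackPlan
    dashboard: DashboardSummary
    scores: Mapping[str, int]
    histories: Mapping[str, DomainHistory]


# Placeholder education-content references (synthetic stand-ins for the
# clinic's care-step library); real deployments supply their own table
# keyed by (domain_id, state).
DEFAULT_CARE_STEPS: Mapping[tuple[str, str], str] = MappingProxyType({
    (dom, state): f"care-steps/{dom}/{state}"
    for dom in ("urinary_incontinence", "urinary_obstruction", "bowel",
                "sexual", "hormonal")
    for state in (YELLOW, ORANGE)
})


def combine_domain_states(
    states: Mapping[str, DomainState],
    expected_domains: Optional[Sequence[str]] = None,
) -> str:
    """Combine per-domain states into the pre-preference global level:
    the maximum severity under green < yellow < orange."""
    if expected_domains is not None:
        missing = [d for d in expected_domains if d not in states]
        if missing:
            raise ValueError(f"missing domain state(s): {', '.join(missing)}")
    if not states:
        raise ValueError("no domain states to combine")
    return max((s.state for s in states.values()), key=SEVERITY.__getitem__)


def apply_patient_preference(combined: str, preference: Optional[str]) -> str:
    """Escalate orange to red when the patient accepts a nurse consultation.

    The preference prompt only exists for orange alerts; an accepted
    response recorded against any other level is a contract violation.
    Green and yellow pass through unchanged.
    """
    preference = preference or NO_RESPONSE
    if combined == ORANGE:
        return RED if preference == ACCEPTED else ORANGE
    if preference == ACCEPTED:
        raise PreferenceContractError(
            f"accepted consultation preference recorded with a "
            f"{combined} alert; the prompt is only pushed on orange")
    return combined


def detect_overdue(
    completion_date: Optional[date],
    expected_due_date: date,
    grace_days: int = 21,
) -> bool:
    """True iff the survey is missing or completed strictly outside the
    grace window (3 weeks by default) around its expected due date."""
    if completion_date is None:
        return True
    return abs((completion_date - expected_due_date).days) > grace_days


def expected_due_date(enrollment_date: date, month_index: int) -> date:
    """Due date of follow-up month ``month_index`` given enrollment."""
    return enrollment_date + timedelta(days=round(DAYS_PER_MONTH * month_index))


def select_feedback(
    states: Mapping[str, DomainState],
    content_table: Mapping[tuple[str, str], str] = DEFAULT_CARE_STEPS,
) -> FeedbackPlan:
    """One care-step content reference per non-green domain."""
    care_steps: dict[str, str] = {}
    for dom, st in states.items():
        if st.state == GREEN:
            continue
        key = (dom, st.state)
        try:
            care_steps[dom] = content_table[key]
        except KeyError:
            raise ConfigError(
                f"no care-step content configured for {key}") from None
    return FeedbackPlan(care_steps=care_steps, first_line=bool(care_steps))


def _contributing_questions(
    states: Mapping[str, DomainState],
    urgent_flags: Sequence[UrgentFlag],
    schema: SurveySchema,
) -> tuple[str, ...]:
    """Item ids feeding a non-green domain: the urgent items plus the
    scored items of every domain with a Δ exceedance."""
    items: set[str] = set()
    for flag in urgent_flags:
        if states[flag.domain_id].state != GREEN:
            items.add(flag.item_id)
    for dom, st in states.items():
        if st.state != GREEN and st.has_exceedance:
            items.update(it.item_id for it in schema.domain_items(dom))
    return tuple(sorted(items))


def triage_month(
    record: SurveyRecord,
    histories: Mapping[str, DomainHistory],
    schema: SurveySchema,
    thresholds: ThresholdConfig,
    enrollment_date: Optional[date] = None,
    content_table: Mapping[tuple[str, str], str] = DEFAULT_CARE_STEPS,
) -> TriageResult:
    """Run the full triage pipeline for one patient-month.

    Deterministic composition: score the survey, collect urgent flags,
    step each domain's state machine, combine, apply the patient's
    consultation preference (consulted only when the combined level is
    orange), select feedback, and flag overdue completion.  Overdue is
    computed independently of the alert level and requires
    ``enrollment_date``; without it the flag is False.

    Returns the alert, feedback plan, dashboard summary, the domain
    scores, and the updated histories (the input mapping is not mutated).
    """
    score_set = score_survey(record, schema)
    flags_by_domain = collect_urgent_flags(
        record, schema, thresholds.urgency_cutoff, thresholds.per_tag_cutoffs)
    all_flags = tuple(f for flags in flags_by_domain.values() for f in flags)

    states: dict[str, DomainState] = {}
    new_histories: dict[str, DomainHistory] = dict(histories)
    for dom in schema.scored_domains:
        state, hist = step_domain(
            histories.get(dom), dom, score_set.scores[dom],
            record.month_index, thresholds,
            urgent_flags=flags_by_domain.get(dom, ()),
            complete=score_set.complete[dom])
        states[dom] = state
        new_histories[dom] = hist

    combined = combine_domain_states(states, schema.scored_domains)
    prompted = combined == ORANGE
    level = apply_patient_preference(
        combined, record.preference_response if prompted else NO_RESPONSE)

    overdue = False
    if enrollment_date is not None:
        due = expected_due_date(enrollment_date, record.month_index)
        overdue = detect_overdue(record.completion_date, due,
                                 thresholds.overdue_grace_days)

    alert = GlobalAlert(
        level=level, domain_states=states, urgent_flags=all_flags,
        preference_prompted=prompted,
        preference_response=record.preference_response, overdue=overdue)
    feedback = select_feedback(states, content_table)
    dashboard = DashboardSummary(
        patient_id=record.patient_id, month_index=record.month_index,
        level=level, domain_states=states,
        contributing_questions=_contributing_questions(states, all_flags, schema),
        overdue=overdue)
    return TriageResult(alert=alert, feedback=feedback, dashboard=dashboard,
                        scores=score_set.scores, histories=new_histories)
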