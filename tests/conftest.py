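"""Shared fixtures: building survey records from target domain scores."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from nedtriage import (
    DEFAULT_SCHEMA, ItemResponse, SurveyRecord, ThresholdConfig,
)

# Greedy fill order per domain, non-urgent items first, so a target
# domain score never lands on an urgency-flagged item unless forced.
FILL_ORDER = {
    "urinary_incontinence": ["ui_leak_frequency", "ui_pad_use", "ui_leak_problem"],
    "urinary_obstruction": ["uo_frequency", "uo_pain_burning", "uo_weak_stream"],
    "bowel": ["bw_urgency", "bw_frequency", "bw_problem"],
    "sexual": ["sx_erection_quality", "sx_erection_ability", "sx_function_problem"],
    "hormonal": ["hr_hot_flashes", "hr_fatigue", "hr_depression"],
}
NONSCORING = ["ns_hematuria", "ns_bloody_stools"]
ENROLLMENT = date(2025, 1, 1)


def record_from_scores(scores=None, month=0, patient_id="p1",
                       completion_date="auto", overrides=None,
                       preference=None) -> SurveyRecord:
    """Build a survey record hitting the given per-domain scores.

    ``scores`` maps domain -> 0..12 (missing domains score 0);
    ``overrides`` maps item_id -> value, applied last (e.g. to set
    urgent items); ``completion_date="auto"`` places the completion on
    the nominal due date for ``month``.
    """
    values = {}
    for dom, order in FILL_ORDER.items():
        remaining = (scores or {}).get(dom, 0)
        for iid in order:
            v = min(4, remaining)
            values[iid] = v
            remaining -= v
        assert remaining == 0, f"score for {dom} not representable"
    for iid in NONSCORING:
        values[iid] = 0
    values.update(overrides or {})
    if completion_date == "auto":
        completion_date = ENROLLMENT + timedelta(days=round(30.44 * month))
    return SurveyRecord(
        patient_id=patient_id, month_index=month,
        completion_date=completion_date,
        responses=tuple(ItemResponse(item_id=i, value=v)
                        for i, v in values.items()),
        preference_response=preference,
    )


def engine_domain_states(seq, domain="bowel", thresholds=None):
    """Drive the incremental per-domain state machine over a list where
    index = month and value = score or None (missing month)."""
    from nedtriage import step_domain
    thresholds = thresholds or ThresholdConfig()
    hist = None
    states = {}
    for month, score in enumerate(seq):
        if score is None:
            continue
        state, hist = step_domain(hist, domain, score, month, thresholds)
        states[month] = state.state
    return states


@pytest.fixture
def schema():
    return DEFAULT_SCHEMA


@pytest.fixture
def thresholds():
    return ThresholdConfig()
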