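"""Synthetic longitudinal EPIC-CP cohorts with controlled symptom dynamics.

No open clinical dataset of monthly EPIC-CP responses exists, so the
package ships a generator that emulates the monthly check-in stream the
triage engine consumes.  Four trajectory profiles cover the dynamics the
algorithm is designed to catch:

* ``stable`` — a chronic but unchanging symptom fingerprint (should
  never alert);
* ``gradual_worsening`` — slow-creeping scores (caught by the baseline Δ
  even when each monthly step is below the local threshold);
* ``acute_event`` — a sudden jump at a known month (caught by the local
  Δ);
* ``improve_then_creep`` — a high post-treatment score, recovery, then a
  slow rise (the refreshing-baseline motivation: alerts must fire
  against the recovered baseline, not the stale high one).

Every patient trajectory comes with a ground-truth event log (the true
threshold-crossing months and injected urgent-symptom events) so tests
can verify the engine recovers exactly the planted events.  All
randomness flows from one seeded :class:`numpy.random.Generator`; the
same config and seed always reproduce the identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .alerts import ORANGE, expected_due_date, triage_month
from .config import ThresholdConfig
from .schema import (
    DEFAULT_SCHEMA, SCORED_DOMAINS, ItemResponse, SurveyRecord, SurveySchema,
)

PROFILE_KINDS = ("stable", "gradual_worsening", "acute_event",
                 "improve_then_creep")


@dataclass(frozen=True)
class TrajectoryProfile:
    """Generative description of one synthetic patient's symptom evolution.

    ``start``/``drift`` map domain -> starting score and per-month drift;
    unlisted domains default to a mild stable score.  ``urgent_event_prob``
    maps an urgency tag to its per-month event probability.  ``noise`` is
    the per-domain-month probability of an ordinal +/-1 jitter on the
    domain score.
    """

    kind: str
    start: Mapping[str, float] = field(default_factory=dict)
    drift: Mapping[str, float] = field(default_factory=dict)
    acute_month: Optional[int] = None
    acute_magnitude: Mapping[str, float] = field(default_factory=dict)
    drop_month: Optional[int] = None
    drop_to: Mapping[str, float] = field(default_factory=dict)
    urgent_event_prob: Mapping[str, float] = field(default_factory=dict)
    noise: float = 0.0
    default_start: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}")

    # -- factories -----------------------------------------------------

    @classmethod
    def stable(cls, start: Optional[Mapping[str, float]] = None,
               noise: float = 0.0, **kw) -> "TrajectoryProfile":
        return cls(kind="stable", start=dict(start or {}), noise=noise, **kw)

    @classmethod
    def gradual_worsening(cls, domain: str = "bowel", rate: float = 1.0,
                          start: float = 2.0, noise: float = 0.0,
                          **kw) -> "TrajectoryProfile":
        return cls(kind="gradual_worsening", start={domain: start},
                   drift={domain: rate}, noise=noise, **kw)

    @classmethod
    def acute_event(cls, domain: str = "bowel", month: int = 6,
                    magnitude: float = 4.0, start: float = 2.0,
                    noise: float = 0.0, **kw) -> "TrajectoryProfile":
        return cls(kind="acute_event", start={domain: start},
                   acute_month=month, acute_magnitude={domain: magnitude},
                   noise=noise, **kw)

    @classmethod
    def improve_then_creep(cls, domain: str = "bowel", start: float = 9.0,
                           drop_month: int = 6, drop_to: float = 2.0,
                           creep: float = 1.0, noise: float = 0.0,
                           **kw) -> "TrajectoryProfile":
        return cls(kind="improve_then_creep", start={domain: start},
                   drop_month=drop_month, drop_to={domain: drop_to},
                   drift={domain: creep}, noise=noise, **kw)

    # -- the noiseless trajectory ---------------------------------------

    def true_score(self, domain: str, month: int) -> int:
        """Noiseless domain score at a month, clamped to 0..12."""
        start = self.start.get(domain, self.default_start)
        if self.kind == "stable":
            val = start
        elif self.kind == "gradual_worsening":
            val = start + self.drift.get(domain, 0.0) * month
        elif self.kind == "acute_event":
            val = start
            if self.acute_month is not None and month >= self.acute_month:
                val += self.acute_magnitude.get(domain, 0.0)
        else:  # improve_then_creep
            if self.drop_month is None or month < self.drop_month:
                val = start
            else:
                val = (self.drop_to.get(domain, 0.0)
                       + self.drift.get(domain, 0.0) * (month - self.drop_month))
        return int(np.clip(round(val), 0, 12))


class SimulationConfig(BaseModel):
    """Cohort-level simulation parameters.

    Defaults emulate a modest remote-monitoring roster: 100 patients
    followed monthly for a year, ~10% of check-ins skipped entirely, ~5%
    completed late enough to trip the 3-week overdue rule, and a 50/50
    chance a prompted patient accepts the nurse consultation.
    """

    model_config = ConfigDict(frozen=True)

    n_patients: int = 100
    n_months: int = 12
    missing_prob: float = 0.1
    overdue_prob: float = 0.05
    preference_accept_prob: float = 0.5
    enrollment_start: date = date(2025, 1, 1)
    enrollment_stagger_days: int = 60
    seed: int = 0


def _decompose_score(score: int, items, rng: np.random.Generator,
                     jitter: bool) -> Dict[str, int]:
    """Split a 0..12 domain score into item categories 0..4 summing to it.

    Non-urgent items are filled first (deterministic greedy, up to 4
    each) so that a trajectory's domain score never lands on an
    urgency-flagged item by accident: urgent symptoms are injected only
    as explicit events, or when the score is too high (> 4 x the number
    of non-urgent items) to be carried by non-urgent items alone.  When
    ``jitter`` is set, units are randomly redistributed among the
    non-urgent items, preserving the sum and the 0..4 bounds.
    """
    free = [it.item_id for it in items if it.urgency_flag is None]
    urgent = [it.item_id for it in items if it.urgency_flag is not None]
    vals: Dict[str, int] = {}
    remaining = score
    for iid in free + urgent:
        v = min(4, remaining)
        vals[iid] = v
        remaining -= v
    if jitter and len(free) > 1 and 0 < sum(vals[i] for i in free) < 4 * len(free):
        for _ in range(int(rng.integers(0, 2 * len(free)))):
            i, j = rng.integers(0, len(free), size=2)
            a, b = free[int(i)], free[int(j)]
            if vals[a] > 0 and vals[b] < 4 and a != b:
                vals[a] -= 1
                vals[b] += 1
    return vals


def _replay_exceedances(
    scores_by_month: Sequence[Tuple[int, int]],
    local_thr: int,
    base_thr: int,
    interval: int,
) -> List[int]:
    """Ground-truth threshold-crossing months for one domain.

    Straightforward replay of the dual-Δ definition (local vs previous
    completed survey, baseline vs refreshing baseline) over the final
    generated scores; kept inline so the log is derived from the
    generative record, not from the engine under test.
    """
    out: List[int] = []
    prior: Optional[Tuple[int, int]] = None
    base: Optional[Tuple[int, int]] = None  # (month, score)
    for month, score in scores_by_month:
        if prior is not None:
            local_d = score - prior[1]
            base_d = score - base[1]
            if local_d > local_thr or base_d > base_thr:
                out.append(month)
        if base is None:
            base = (month, score)
        elif month - base[0] >= interval:
            base = (month, score)
        prior = (month, score)
    return out


def simulate_patient(
    profile: TrajectoryProfile,
    config: SimulationConfig,
    patient_id: str,
    rng: np.random.Generator,
    schema: SurveySchema = DEFAULT_SCHEMA,
    thresholds: Optional[ThresholdConfig] = None,
    enrollment_date: Optional[date] = None,
) -> Tuple[List[SurveyRecord], dict]:
    """Generate one patient's ordered survey records plus their ground truth.

    Month 0 (enrollment) is always completed; later months are skipped
    with ``missing_prob``.  Completion dates are the due date plus a
    small delay, inflated past the grace window with ``overdue_prob``.
    Urgent non-scoring items fire as Bernoulli events; urgent scored
    items are bumped to category 2 when their event fires (which also
    raises the domain score, and the ground truth reflects that).
    """
    thresholds = thresholds or ThresholdConfig()
    if enrollment_date is None:
        enrollment_date = config.enrollment_start
    urgent_items = {it.urgency_flag: it for it in schema.items
                    if it.urgency_flag is not None}
    nonscoring_ids = [it.item_id for it in schema.items if not it.scored]

    records: List[SurveyRecord] = []
    final_scores: Dict[str, List[Tuple[int, int]]] = {
        d: [] for d in schema.scored_domains}
    urgent_events: Dict[str, List[int]] = {}
    missing_months: List[int] = []
    overdue_months: List[int] = []

    for month in range(config.n_months):
        if month > 0 and rng.random() < config.missing_prob:
            missing_months.append(month)
            overdue_months.append(month)  # never completed => overdue
            continue
        # domain scores: noiseless trajectory plus optional ordinal jitter
        responses: List[ItemResponse] = []
        month_scores: Dict[str, int] = {}
        item_values: Dict[str, int] = {}
        for dom in schema.scored_domains:
            score = profile.true_score(dom, month)
            if profile.noise > 0 and rng.random() < profile.noise:
                score = int(np.clip(score + rng.choice((-1, 1)), 0, 12))
            items = schema.domain_items(dom)
            item_values.update(
                _decompose_score(score, items, rng, jitter=profile.noise > 0))
            month_scores[dom] = score
        for iid in nonscoring_ids:
            item_values[iid] = 0
        # injected urgent-symptom events
        for tag, prob in profile.urgent_event_prob.items():
            if tag not in urgent_items or prob <= 0:
                continue
            if rng.random() < prob:
                item = urgent_items[tag]
                if item.scored:
                    bumped = max(item_values[item.item_id], 2)
                    month_scores[item.domain_id] += bumped - item_values[item.item_id]
                    item_values[item.item_id] = bumped
                else:
                    item_values[item.item_id] = 1
        # ground truth: any urgency-flagged item at/above the cutoff this
        # month (injected events, plus high scores spilling onto a scored
        # urgent item) is an urgent month for its tag
        for tag, item in urgent_items.items():
            v = item_values[item.item_id]
            fired = (v >= 1) if not item.scored else (v >= thresholds.urgency_cutoff)
            if fired:
                urgent_events.setdefault(tag, []).append(month)
        for dom, score in month_scores.items():
            final_scores[dom].append((month, score))
        # completion timing
        due = expected_due_date(enrollment_date, month)
        if rng.random() < config.overdue_prob:
            delay = int(thresholds.overdue_grace_days + 1 + rng.integers(0, 21))
            overdue_months.append(month)
        else:
            delay = int(rng.integers(0, 8))
        responses = [ItemResponse(item_id=it.item_id,
                                  value=item_values[it.item_id])
                     for it in schema.items]
        records.append(SurveyRecord(
            patient_id=patient_id, month_index=month,
            completion_date=due + timedelta(days=delay),
            responses=tuple(responses)))

    exceedance_months = {
        dom: _replay_exceedances(final_scores[dom], *thresholds.for_domain(dom),
                                 thresholds.refresh_interval_months)
        for dom in schema.scored_domains}
    urgent_months = sorted({m for ms in urgent_events.values() for m in ms})
    alert_months = sorted({m for ms in exceedance_months.values() for m in ms}
                          | set(urgent_months))
    truth = {
        "patient_id": patient_id,
        "profile_kind": profile.kind,
        "enrollment_date": enrollment_date.isoformat(),
        "missing_months": missing_months,
        "overdue_months": sorted(overdue_months),
        "urgent_events": {t: ms for t, ms in sorted(urgent_events.items())},
        "exceedance_months": exceedance_months,
        "alert_months": alert_months,
        "first_alert_month": alert_months[0] if alert_months else None,
    }
    return records, truth


def _apply_preferences(
    records: List[SurveyRecord],
    accept_prob: float,
    rng: np.random.Generator,
    schema: SurveySchema,
    thresholds: ThresholdConfig,
    enrollment_date: date,
) -> List[SurveyRecord]:
    """Sample consultation preferences for the months the engine would
    prompt (combined level orange).  Preference never feeds back into
    domain states, so this second pass is exact."""
    out: List[SurveyRecord] = []
    histories: Mapping = {}
    for rec in records:
        result = triage_month(rec, histories, schema, thresholds,
                              enrollment_date=enrollment_date)
        histories = result.histories
        if result.alert.preference_prompted:
            pref = ("accepted" if rng.random() < accept_prob else "declined")
            rec = replace(rec, preference_response=pref)
        out.append(rec)
    return out


def simulate_cohort(
    profiles: Sequence[TrajectoryProfile] | Sequence[Tuple[TrajectoryProfile, float]],
    config: SimulationConfig,
    schema: SurveySchema = DEFAULT_SCHEMA,
    thresholds: Optional[ThresholdConfig] = None,
) -> Tuple[List[SurveyRecord], dict]:
    """Generate a cohort from a profile mixture, with its ground-truth log.

    ``profiles`` is a sequence of profiles (equal weights) or of
    ``(profile, weight)`` pairs with weights summing to 1.  Returns the
    flat month-ordered record list and ``{patient_id: truth}``.
    """
    thresholds = thresholds or ThresholdConfig()
    if profiles and isinstance(profiles[0], tuple):
        profs = [p for p, _ in profiles]
        weights = np.asarray([w for _, w in profiles], dtype=float)
        if not np.isclose(weights.sum(), 1.0):
            raise ValueError(f"mixture weights sum to {weights.sum():g}, not 1")
    else:
        profs = list(profiles)
        weights = np.full(len(profs), 1.0 / len(profs))

    master = np.random.default_rng(config.seed)
    patient_rngs = master.spawn(config.n_patients)
    all_records: List[SurveyRecord] = []
    truth_log: dict = {}
    for i, prng in enumerate(patient_rngs):
        pid = f"P{i + 1:04d}"
        profile = profs[int(prng.choice(len(profs), p=weights))]
        enrollment = config.enrollment_start + timedelta(
            days=int(prng.integers(0, config.enrollment_stagger_days + 1)))
        recs, truth = simulate_patient(profile, config, pid, prng,
                                       schema=schema, thresholds=thresholds,
                                       enrollment_date=enrollment)
        if config.preference_accept_prob > 0:
            recs = _apply_preferences(recs, config.preference_accept_prob,
                                      prng, schema, thresholds, enrollment)
        all_records.extend(recs)
        truth_log[pid] = truth
    return all_records, truth_log
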