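"""EPIC-CP questionnaire schema, response containers, and scoring.

The Expanded Prostate Cancer Index Composite for Clinical Practice
(EPIC-CP) is a one-page patient-reported outcome instrument covering five
symptom domains: urinary incontinence, urinary irritation/obstruction,
bowel function, sexual function, and hormonal function.  Each scored item
is an ordinal category from 0 ("no problem") to 4 ("big problem"); each
domain is scored out of 12 and the total out of 60, higher meaning worse.
Two additional non-scoring binary items (hematuria, bloody stools) are
clinically important but never contribute to any score.

This module defines the schema objects, validates survey records against
them, and computes per-domain and total scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from types import MappingProxyType
from typing import Iterable, Mapping, Optional, Sequence

import yaml

#: Canonical scored domain identifiers, in instrument order.
SCORED_DOMAINS = (
    "urinary_incontinence",
    "urinary_obstruction",
    "bowel",
    "sexual",
    "hormonal",
)

#: Pseudo-domain grouping the non-scoring binary items.
NONSCORING_DOMAIN = "nonscoring"

#: The five clinically urgent symptom tags.
URGENCY_TAGS = (
    "pain_burning_urination",
    "weak_stream_incomplete_emptying",
    "hematuria",
    "bloody_stools",
    "depression",
)

DOMAIN_MAX_SCORE = 12
PREFERENCE_VALUES = ("accepted", "declined", "no_response")


class SchemaError(ValueError):
    """A questionnaire schema violates a structural invariant."""


class ResponseValidationError(ValueError):
    """A survey record is inconsistent with the schema."""


@dataclass(frozen=True)
class ItemDefinition:
    """One questionnaire item.

    Parameters
    ----------
    item_id : str
        Short unique key for the item.
    domain_id : str
        Domain the item belongs to (one of :data:`SCORED_DOMAINS` or
        ``"nonscoring"``).
    scored : bool
        Whether the item contributes to domain/total scores.  Scored
        items are ordinal 0..4; non-scoring items are binary 0/1
        (absent/present).
    weight : float
        Score contribution multiplier.  The default layout uses weight 1
        with 3 items per domain; alternative layouts (e.g. 4 items in a
        domain) must choose weights so the domain maximum stays 12.
    urgency_flag : str, optional
        Which clinically urgent symptom this item can signal, if any.
    alert_domain : str, optional
        For non-scoring urgent items: the scored domain their urgency is
        clinically attributed to (hematuria -> urinary_obstruction,
        bloody stools -> bowel).  Scored items alert on their own domain.
    text : str
        Display label.
    """

    item_id: str
    domain_id: str
    scored: bool = True
    min_category: int = 0
    max_category: int = 4
    weight: float = 1.0
    urgency_flag: Optional[str] = None
    alert_domain: Optional[str] = None
    text: str = ""

    @property
    def urgency_domain(self) -> Optional[str]:
        """Domain an urgent response on this item escalates."""
        if self.urgency_flag is None:
            return None
        return self.alert_domain or self.domain_id


def _default_items() -> tuple[ItemDefinition, ...]:
    # Item labels are synthetic placeholders keyed to the five domains and
    # five urgency tags; the licensed instrument text is not reproduced.
    d = ItemDefinition
    return (
        d("ui_leak_frequency", "urinary_incontinence", text="Urine leakage frequency"),
        d("ui_pad_use", "urinary_incontinence", text="Pad use for urinary leakage"),
        d("ui_leak_problem", "urinary_incontinence", text="Urine leakage as a problem"),
        d("uo_pain_burning", "urinary_obstruction",
          urgency_flag="pain_burning_urination", text="Pain or burning with urination"),
        d("uo_weak_stream", "urinary_obstruction",
          urgency_flag="weak_stream_incomplete_emptying",
          text="Weak urine stream / incomplete emptying"),
        d("uo_frequency", "urinary_obstruction", text="Frequent urination"),
        d("bw_urgency", "bowel", text="Bowel urgency"),
        d("bw_frequency", "bowel", text="Increased stool frequency"),
        d("bw_problem", "bowel", text="Bowel habits as a problem"),
        d("sx_erection_quality", "sexual", text="Erection quality"),
        d("sx_erection_ability", "sexual", text="Ability to have an erection"),
        d("sx_function_problem", "sexual", text="Sexual function as a problem"),
        d("hr_hot_flashes", "hormonal", text="Hot flashes"),
        d("hr_depression", "hormonal", urgency_flag="depression",
          text="Feeling depressed"),
        d("hr_fatigue", "hormonal", text="Lack of energy"),
        d("ns_hematuria", NONSCORING_DOMAIN, scored=False, max_category=1,
          urgency_flag="hematuria", alert_domain="urinary_obstruction",
          text="Blood in urine (hematuria)"),
        d("ns_bloody_stools", NONSCORING_DOMAIN, scored=False, max_category=1,
          urgency_flag="bloody_stools", alert_domain="bowel",
          text="Blood in stools"),
    )


@dataclass(frozen=True)
class SurveySchema:
    """A validated questionnaire layout: items grouped into domains."""

    items: tuple[ItemDefinition, ...]
    version: str = "epic-cp-default"

    def __post_init__(self) -> None:
        self._validate()

    # -- lookups -------------------------------------------------------

    @property
    def items_by_id(self) -> Mapping[str, ItemDefinition]:
        return MappingProxyType({it.item_id: it for it in self.items})

    @property
    def scored_domains(self) -> tuple[str, ...]:
        seen: list[str] = []
        for it in self.items:
            if it.scored and it.domain_id not in seen:
                seen.append(it.domain_id)
        return tuple(seen)

    def domain_items(self, domain_id: str) -> tuple[ItemDefinition, ...]:
        return tuple(it for it in self.items
                     if it.scored and it.domain_id == domain_id)

    @property
    def urgency_tags(self) -> tuple[str, ...]:
        return tuple(it.urgency_flag for it in self.items
                     if it.urgency_flag is not None)

    @property
    def max_total(self) -> int:
        return DOMAIN_MAX_SCORE * len(self.scored_domains)

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        if not self.items:
            raise SchemaError("schema has no items")
        seen_ids: set[str] = set()
        for it in self.items:
            if it.item_id in seen_ids:
                raise SchemaError(f"duplicate item_id {it.item_id!r}")
            seen_ids.add(it.item_id)
            if it.scored:
                if it.domain_id == NONSCORING_DOMAIN:
                    raise SchemaError(
                        f"item {it.item_id!r}: scored item in nonscoring domain")
                if (it.min_category, it.max_category) != (0, 4):
                    raise SchemaError(
                        f"item {it.item_id!r}: scored items must have "
                        f"category range 0..4, got "
                        f"{it.min_category}..{it.max_category}")
                if it.weight <= 0:
                    raise SchemaError(
                        f"item {it.item_id!r}: weight must be positive")
            else:
                if (it.min_category, it.max_category) != (0, 1):
                    raise SchemaError(
                        f"item {it.item_id!r}: non-scoring items must be "
                        "binary (range 0..1)")
            if it.urgency_flag is not None and it.urgency_flag not in URGENCY_TAGS:
                raise SchemaError(
                    f"item {it.item_id!r}: unknown urgency tag "
                    f"{it.urgency_flag!r}")
            if it.alert_domain is not None and it.alert_domain == NONSCORING_DOMAIN:
                raise SchemaError(
                    f"item {it.item_id!r}: alert_domain cannot be nonscoring")
        # every scored domain must max out at exactly 12
        for dom in self.scored_domains:
            mx = sum(it.weight * it.max_category for it in self.domain_items(dom))
            if not math.isclose(mx, DOMAIN_MAX_SCORE, abs_tol=1e-9):
                raise SchemaError(
                    f"domain {dom!r}: maximum score is {mx:g}, must be "
                    f"{DOMAIN_MAX_SCORE}")
        # urgency tags must be unique across items
        tags = self.urgency_tags
        if len(tags) != len(set(tags)):
            raise SchemaError("an urgency tag is declared on more than one item")
        for it in self.items:
            if it.alert_domain is not None and it.alert_domain not in self.scored_domains:
                raise SchemaError(
                    f"item {it.item_id!r}: alert_domain {it.alert_domain!r} "
                    "is not a scored domain")


DEFAULT_SCHEMA = SurveySchema(items=_default_items())


def load_schema(config=None) -> SurveySchema:
    """Build a validated :class:`SurveySchema`.

    ``config`` may be ``None`` (built-in default EPIC-CP layout), a path
    to a YAML file, or an already-parsed mapping with keys ``version``
    and ``items`` (a list of item mappings mirroring
    :class:`ItemDefinition` fields).
    """
    if config is None:
        return DEFAULT_SCHEMA
    if isinstance(config, (str, bytes)) or hasattr(config, "read_text"):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping) or "items" not in config:
        raise SchemaError("schema config must be a mapping with an 'items' list")
    items = []
    for raw in config["items"]:
        try:
            items.append(ItemDefinition(**dict(raw)))
        except TypeError as exc:
            raise SchemaError(
                f"malformed item definition {raw!r}: {exc}") from None
    return SurveySchema(items=tuple(items),
                        version=str(config.get("version", "custom")))


# ---------------------------------------------------------------------------
# responses and scoring


@dataclass(frozen=True)
class ItemResponse:
    """One answered (or explicitly unanswered) item.

    For scored items ``value`` is the ordinal category 0..4; for
    non-scoring items it is 0 (absent) or 1 (present).
    """

    item_id: str
    value: int = 0
    answered: bool = True


@dataclass(frozen=True)
class SurveyRecord:
    """One patient-month EPIC-CP response set."""

    patient_id: str
    month_index: int
    completion_date: Optional[date]
    responses: tuple[ItemResponse, ...]
    preference_response: Optional[str] = None

    def __post_init__(self) -> None:
        if self.month_index < 0:
            raise ResponseValidationError(
                f"month_index must be >= 0, got {self.month_index}")
        if (self.preference_response is not None
                and self.preference_response not in PREFERENCE_VALUES):
            raise ResponseValidationError(
                f"preference_response must be one of {PREFERENCE_VALUES}, "
                f"got {self.preference_response!r}")

    @property
    def response_map(self) -> dict[str, ItemResponse]:
        return {r.item_id: r for r in self.responses}


@dataclass(frozen=True)
class DomainScoreSet:
    """Per-domain scores, total, and completeness flags for one survey."""

    scores: Mapping[str, int]
    total: int
    complete: Mapping[str, bool]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", MappingProxyType(dict(self.scores)))
        object.__setattr__(self, "complete", MappingProxyType(dict(self.complete)))


def validate_record(record: SurveyRecord, schema: SurveySchema) -> None:
    """Raise :class:`ResponseValidationError` on any schema violation."""
    items = schema.items_by_id
    seen: set[str] = set()
    for resp in record.responses:
        item = items.get(resp.item_id)
        if item is None:
            raise ResponseValidationError(
                f"unknown item_id {resp.item_id!r} "
                f"(patient {record.patient_id}, month {record.month_index})")
        if resp.item_id in seen:
            raise ResponseValidationError(
                f"duplicate response for item {resp.item_id!r} "
                f"(patient {record.patient_id}, month {record.month_index})")
        seen.add(resp.item_id)
        if resp.answered and not (item.min_category <= resp.value <= item.max_category):
            raise ResponseValidationError(
                f"item {resp.item_id!r}: value {resp.value} outside "
                f"{item.min_category}..{item.max_category} "
                f"(patient {record.patient_id}, month {record.month_index})")


def score_survey(record: SurveyRecord, schema: SurveySchema) -> DomainScoreSet:
    """Compute per-domain and total scores for one survey.

    Each domain score is the (weighted) sum of its answered scored items,
    rounded to the nearest integer on the 0..12 scale; non-scoring items
    never contribute.  A domain is flagged incomplete if any of its
    scored items is unanswered or missing from the record; unanswered
    items contribute 0 — no value is ever imputed.
    """
    validate_record(record, schema)
    responses = record.response_map
    scores: dict[str, int] = {}
    complete: dict[str, bool] = {}
    for dom in schema.scored_domains:
        acc = 0.0
        dom_complete = True
        for item in schema.domain_items(dom):
            resp = responses.get(item.item_id)
            if resp is None or not resp.answered:
                dom_complete = False
                continue
            acc += item.weight * resp.value
        scores[dom] = int(round(acc))
        complete[dom] = dom_complete
    return DomainScoreSet(scores=scores, total=sum(scores.values()),
                          complete=complete)
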