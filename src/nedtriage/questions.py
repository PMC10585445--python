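"""Question-level workflow: normal vs clinically urgent responses.

Every item response is classified as normal or clinically urgent.  Only
the five designated urgent symptoms can ever raise a flag: pain/burning
with urination, weak stream/incomplete emptying, hematuria, bloody
stools, and depression.  These reflect differential diagnoses (urinary
tract infection, radiation-related bleeding, need for psychological
support) that warrant investigation whenever the patient reports them,
independent of how the domain score is trending.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .schema import ItemDefinition, ItemResponse, SurveyRecord, SurveySchema

NORMAL = "normal"
CLINICALLY_URGENT = "clinically_urgent"

#: Default minimum category on a scored urgent item that raises the flag.
#: 1 means any reported problem triggers — the safety-first default;
#: raise it (per tag if desired) to trade sensitivity against alert fatigue.
DEFAULT_URGENCY_CUTOFF = 1


@dataclass(frozen=True)
class UrgentFlag:
    """A clinically urgent response on one item at one month."""

    tag: str
    item_id: str
    domain_id: str  # scored domain the urgency escalates
    value: int


def classify_item(response: ItemResponse, item: ItemDefinition,
                  urgency_cutoff: int = DEFAULT_URGENCY_CUTOFF) -> str:
    """Classify one response as ``"normal"`` or ``"clinically_urgent"``.

    A response is clinically urgent iff the item carries an urgency tag
    and either the non-scoring item is present, or the scored item's
    category is at or above ``urgency_cutoff``.
    """
    if item.urgency_flag is None or not response.answered:
        return NORMAL
    if not item.scored:
        return CLINICALLY_URGENT if response.value >= 1 else NORMAL
    return CLINICALLY_URGENT if response.value >= urgency_cutoff else NORMAL


def collect_urgent_flags(
    record: SurveyRecord,
    schema: SurveySchema,
    urgency_cutoff: int = DEFAULT_URGENCY_CUTOFF,
    per_tag_cutoffs: Optional[Mapping[str, int]] = None,
) -> dict[str, tuple[UrgentFlag, ...]]:
    """Collect urgent flags for one survey, grouped by scored domain.

    Non-scoring urgent items attach to their clinically associated scored
    domain (hematuria -> urinary_obstruction, bloody stools -> bowel);
    scored urgent items attach to their own domain.  ``per_tag_cutoffs``
    overrides ``urgency_cutoff`` for individual tags.
    """
    items = schema.items_by_id
    grouped: dict[str, list[UrgentFlag]] = {}
    for resp in record.responses:
        item = items.get(resp.item_id)
        if item is None or item.urgency_flag is None:
            continue
        cutoff = urgency_cutoff
        if per_tag_cutoffs and item.urgency_flag in per_tag_cutoffs:
            cutoff = per_tag_cutoffs[item.urgency_flag]
        if classify_item(resp, item, cutoff) == CLINICALLY_URGENT:
            dom = item.urgency_domain
            grouped.setdefault(dom, []).append(
                UrgentFlag(tag=item.urgency_flag, item_id=item.item_id,
                           domain_id=dom, value=resp.value))
    return {dom: tuple(flags) for dom, flags in grouped.items()}
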