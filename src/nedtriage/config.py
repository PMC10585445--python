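"""Engine configuration: change-score thresholds and tuning knobs.

The per-domain Δ thresholds are minimal clinically important differences
(MCIDs) on the 0–12 domain scale.  Defaults follow the expert-codefined
values: Δ>0 for urinary incontinence and hormonal function, Δ>1 for
urinary obstruction, bowel function, and sexual function; local (versus
the previous completed survey) and baseline (versus the refreshing
baseline) thresholds default equal per domain.  All of them are tunable,
including per patient, to trade sensitivity against alert fatigue.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .questions import DEFAULT_URGENCY_CUTOFF

DEFAULT_LOCAL_THRESHOLDS: Dict[str, int] = {
    "urinary_incontinence": 0,
    "urinary_obstruction": 1,
    "bowel": 1,
    "sexual": 1,
    "hormonal": 0,
}


class ConfigError(ValueError):
    """A run/threshold configuration is invalid."""


class ThresholdConfig(BaseModel):
    """Per-domain Δ thresholds and engine timing parameters.

    Attributes
    ----------
    local : dict
        Strict threshold on the month-over-month change per domain; an
        exceedance is Δ > threshold (ties never trigger).
    baseline : dict
        Strict threshold on the change versus the refreshing baseline.
    refresh_interval_months : int
        Months after which the baseline score is replaced by the current
        score (default 6).
    overdue_grace_days : int
        Days either side of the expected due date within which a survey
        completion is considered on time (default 21, i.e. 3 weeks).
    urgency_cutoff : int
        Minimum category on a scored urgent item that raises its flag.
    reset_after_consecutive_green : int or None
        Optional: treat a domain's exceedance count as zero again after
        this many consecutive green months (default off — exceedance
        history is lifetime, reflecting symptom chronicity).
    """

    model_config = ConfigDict(frozen=True)

    local: Dict[str, int] = Field(
        default_factory=lambda: dict(DEFAULT_LOCAL_THRESHOLDS))
    baseline: Dict[str, int] = Field(
        default_factory=lambda: dict(DEFAULT_LOCAL_THRESHOLDS))
    refresh_interval_months: int = 6
    overdue_grace_days: int = 21
    urgency_cutoff: int = DEFAULT_URGENCY_CUTOFF
    per_tag_cutoffs: Optional[Dict[str, int]] = None
    reset_after_consecutive_green: Optional[int] = None

    @field_validator("local", "baseline")
    @classmethod
    def _nonnegative(cls, v: Dict[str, int]) -> Dict[str, int]:
        for dom, thr in v.items():
            if thr < 0:
                raise ValueError(f"threshold for {dom!r} must be >= 0, got {thr}")
        return v

    @model_validator(mode="after")
    def _positive_timing(self) -> "ThresholdConfig":
        if self.refresh_interval_months < 1:
            raise ValueError("refresh_interval_months must be >= 1")
        if self.overdue_grace_days < 0:
            raise ValueError("overdue_grace_days must be >= 0")
        return self

    def for_domain(self, domain_id: str) -> tuple[int, int]:
        """Return ``(local_threshold, baseline_threshold)`` for a domain."""
        try:
            return self.local[domain_id], self.baseline[domain_id]
        except KeyError:
            raise ConfigError(
                f"no Δ threshold configured for domain {domain_id!r}") from None


def load_thresholds(source=None) -> ThresholdConfig:
    """Load a :class:`ThresholdConfig`, merging partial overrides onto defaults.

    ``source`` may be ``None`` (defaults), a YAML path, or a mapping.
    Partial ``local``/``baseline`` mappings override only the listed
    domains.
    """
    if source is None:
        return ThresholdConfig()
    if isinstance(source, (str, bytes)) or hasattr(source, "read_text"):
        with open(source, "r", encoding="utf-8") as fh:
            source = yaml.safe_load(fh) or {}
    if not isinstance(source, Mapping):
        raise ConfigError("threshold config must be a mapping")
    data = dict(source)
    for key in ("local", "baseline"):
        if key in data:
            merged = dict(DEFAULT_LOCAL_THRESHOLDS)
            merged.update(data[key])
            data[key] = merged
    try:
        return ThresholdConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid threshold config: {exc}") from None
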