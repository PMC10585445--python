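"""Domain-level workflow: dual change scores, thresholds, and state history.

For each scored domain the engine tracks two change scores (Δ):

* **local Δ** — current score minus the most recent prior completed
  survey's score (not necessarily last month: missing months fall back
  to the most recent available data);
* **baseline Δ** — current score minus a *refreshing baseline* that is
  re-seeded with the current score once it is ``refresh_interval_months``
  old, so alerts track the recent trajectory rather than stale history
  (e.g. a high post-treatment score followed by recovery and then a slow
  creep upward should alert on the creep).

An *exceedance* occurs when either Δ is strictly greater than its
per-domain threshold.  Improvement (negative Δ) never triggers.  The
first-ever exceedance in a domain yields a **yellow** state; any repeat
exceedance yields **orange**, as does any clinically urgent symptom
attached to the domain regardless of Δ.  A patient's first survey can
never yield a Δ-driven alert (two surveys are needed for a change
score), but an urgent symptom on it still escalates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

from .config import ThresholdConfig
from .questions import UrgentFlag

GREEN = "green"
YELLOW = "yellow"
ORANGE = "orange"
RED = "red"

#: Severity ordering for domain states and global alerts.
SEVERITY = {GREEN: 0, YELLOW: 1, ORANGE: 2, RED: 3}

# reason codes
REASON_LOCAL = "local_exceeded"
REASON_BASELINE = "baseline_exceeded"
REASON_REPEAT = "repeat_exceedance"
REASON_INSUFFICIENT = "insufficient_history"
REASON_INCOMPLETE = "incomplete_domain"
_EXCEEDANCE_REASONS = frozenset({REASON_LOCAL, REASON_BASELINE})


class InsufficientHistory:
    """Sentinel: deltas are undefined before the second completed survey."""

    _instance: Optional["InsufficientHistory"] = None

    def __new__(cls) -> "InsufficientHistory":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "INSUFFICIENT_HISTORY"


INSUFFICIENT_HISTORY = InsufficientHistory()


@dataclass(frozen=True)
class DeltaPair:
    """The two change scores for one domain at one month."""

    local_delta: int
    baseline_delta: int
    prior_month_used: int


@dataclass(frozen=True)
class DomainHistory:
    """Running per-patient, per-domain state.

    ``exceedance_count`` is the lifetime number of threshold breaches
    (it never decreases; an optional consecutive-green reset rule can
    make it *effectively* zero again without erasing it).
    ``green_run`` counts consecutive green months ending at
    ``last_scored_month`` and exists only to support that reset rule.
    """

    domain_id: str
    baseline_score: int
    baseline_month: int
    exceedance_count: int = 0
    last_state: str = GREEN
    last_score: int = 0
    last_scored_month: int = 0
    green_run: int = 0

    @classmethod
    def initial(cls, domain_id: str, score: int, month: int) -> "DomainHistory":
        """Seed history at a patient's first completed survey."""
        return cls(domain_id=domain_id, baseline_score=score,
                   baseline_month=month, last_score=score,
                   last_scored_month=month)


@dataclass(frozen=True)
class DomainState:
    """Traffic-light state for one domain at one month, with its reasons."""

    domain_id: str
    state: str
    reasons: tuple[str, ...] = ()

    @property
    def has_exceedance(self) -> bool:
        return any(r in _EXCEEDANCE_REASONS for r in self.reasons)


def compute_deltas(
    current_score: int,
    history: Optional[DomainHistory],
    current_month: int,
) -> Union[DeltaPair, InsufficientHistory]:
    """Compute the local and baseline Δ for one domain.

    Returns :data:`INSUFFICIENT_HISTORY` on the first-ever completed
    survey.  The local Δ uses the most recent prior completed survey;
    missing intermediate months are skipped, not imputed.
    """
    if history is None:
        return INSUFFICIENT_HISTORY
    if current_month <= history.last_scored_month:
        raise ValueError(
            f"month {current_month} is not after the last scored month "
            f"{history.last_scored_month} for domain {history.domain_id!r}")
    return DeltaPair(
        local_delta=current_score - history.last_score,
        baseline_delta=current_score - history.baseline_score,
        prior_month_used=history.last_scored_month,
    )


def refresh_baseline(
    history: DomainHistory,
    current_month: int,
    current_score: int,
    interval: int = 6,
) -> DomainHistory:
    """Re-seed the baseline with the current score once it is ``interval``
    months old; otherwise return the history unchanged."""
    if current_month - history.baseline_month >= interval:
        return replace(history, baseline_score=current_score,
                       baseline_month=current_month)
    return history


def _effective_count(history: Optional[DomainHistory],
                     thresholds: ThresholdConfig) -> int:
    if history is None:
        return 0
    reset_n = thresholds.reset_after_consecutive_green
    if reset_n is not None and history.green_run >= reset_n:
        return 0
    return history.exceedance_count


def evaluate_domain_state(
    deltas: Union[DeltaPair, InsufficientHistory],
    thresholds: ThresholdConfig,
    history: Optional[DomainHistory],
    urgent_flags: Sequence[UrgentFlag],
    domain_id: str,
    complete: bool = True,
) -> DomainState:
    """Apply the threshold and escalation rules for one domain-month.

    State logic: green when nothing exceeds and no urgent symptom;
    yellow on the first-ever exceedance; orange on any repeat exceedance
    or whenever an urgent symptom is present (regardless of Δ).
    """
    reasons: list[str] = []
    exceed = False
    if isinstance(deltas, InsufficientHistory):
        reasons.append(REASON_INSUFFICIENT)
    else:
        local_thr, base_thr = thresholds.for_domain(domain_id)
        if deltas.local_delta > local_thr:
            reasons.append(REASON_LOCAL)
            exceed = True
        if deltas.baseline_delta > base_thr:
            reasons.append(REASON_BASELINE)
            exceed = True
    prior_count = _effective_count(history, thresholds)
    if exceed and prior_count >= 1:
        reasons.append(REASON_REPEAT)
    for flag in urgent_flags:
        reasons.append(f"urgent:{flag.tag}")
    if not complete:
        reasons.append(REASON_INCOMPLETE)

    if urgent_flags:
        state = ORANGE
    elif exceed:
        state = YELLOW if prior_count == 0 else ORANGE
    else:
        state = GREEN
    return DomainState(domain_id=domain_id, state=state, reasons=tuple(reasons))


def update_history(
    history: Optional[DomainHistory],
    state: DomainState,
    current_score: int,
    current_month: int,
    thresholds: ThresholdConfig,
    domain_id: Optional[str] = None,
) -> DomainHistory:
    """Fold one month's state into the running history.

    Seeds the history (baseline := first score) when ``history`` is
    ``None``.  The exceedance count increments only on Δ exceedances —
    an urgent-symptom orange does not, by itself, consume the "first
    time" grace.  Baseline refreshing is applied by
    :func:`refresh_baseline`, which the caller invokes after this.
    """
    if history is None:
        hist = DomainHistory.initial(domain_id or state.domain_id,
                                     current_score, current_month)
        return replace(hist, last_state=state.state,
                       green_run=1 if state.state == GREEN else 0)
    new_count = history.exceedance_count
    if state.has_exceedance:
        new_count = _effective_count(history, thresholds) + 1
    return replace(
        history,
        exceedance_count=new_count,
        last_state=state.state,
        last_score=current_score,
        last_scored_month=current_month,
        green_run=history.green_run + 1 if state.state == GREEN else 0,
    )


def step_domain(
    history: Optional[DomainHistory],
    domain_id: str,
    current_score: int,
    current_month: int,
    thresholds: ThresholdConfig,
    urgent_flags: Sequence[UrgentFlag] = (),
    complete: bool = True,
) -> tuple[DomainState, DomainHistory]:
    """One full domain-month transition: deltas → state → history update
    → baseline refresh.  Convenience composition used by the alert engine."""
    deltas = compute_deltas(current_score, history, current_month)
    state = evaluate_domain_state(deltas, thresholds, history, urgent_flags,
                                  domain_id, complete=complete)
    new_hist = update_history(history, state, current_score, current_month,
                              thresholds, domain_id=domain_id)
    new_hist = refresh_baseline(new_hist, current_month, current_score,
                                thresholds.refresh_interval_months)
    return state, new_hist
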