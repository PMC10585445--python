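"""Brute-force reference implementation of the triage rules.

Used only as an independent oracle in tests: for every target month it
rebuilds all state from the raw survey sequence from scratch (no
carried history), using plain loops and the default questionnaire
layout hard-coded below.  Deliberately kept separate from the package's
incremental state machine.
"""

from __future__ import annotations

DOMAIN_ITEMS = {
    "urinary_incontinence": ["ui_leak_frequency", "ui_pad_use", "ui_leak_problem"],
    "urinary_obstruction": ["uo_frequency", "uo_pain_burning", "uo_weak_stream"],
    "bowel": ["bw_urgency", "bw_frequency", "bw_problem"],
    "sexual": ["sx_erection_quality", "sx_erection_ability", "sx_function_problem"],
    "hormonal": ["hr_hot_flashes", "hr_fatigue", "hr_depression"],
}
# (item_id, scored?, domain the urgency escalates)
URGENT_ITEMS = [
    ("uo_pain_burning", True, "urinary_obstruction"),
    ("uo_weak_stream", True, "urinary_obstruction"),
    ("hr_depression", True, "hormonal"),
    ("ns_hematuria", False, "urinary_obstruction"),
    ("ns_bloody_stools", False, "bowel"),
]
LOCAL_THR = {"urinary_incontinence": 0, "urinary_obstruction": 1,
             "bowel": 1, "sexual": 1, "hormonal": 0}
SEV = {"green": 0, "yellow": 1, "orange": 2, "red": 3}


def replay_single_domain(seq, local_thr, base_thr, interval=6):
    """Final state after replaying one domain's (month, score) sequence.

    ``seq`` is an iterable of (month_index, score) for completed
    surveys, in order.  Returns the state string at the last entry.
    """
    state = None
    count = 0
    base = None   # (month, score)
    prior = None  # (month, score)
    for month, score in seq:
        if prior is None:
            state = "green"
        else:
            exceed = (score - prior[1] > local_thr
                      or score - base[1] > base_thr)
            if not exceed:
                state = "green"
            elif count == 0:
                state = "yellow"
            else:
                state = "orange"
            if exceed:
                count += 1
        if base is None:
            base = (month, score)
        elif month - base[0] >= interval:
            base = (month, score)
        prior = (month, score)
    return state


def oracle_domain_states(scores, local_thr, base_thr, interval=6):
    """From-scratch single-domain states for a month-indexed sequence.

    ``scores`` is a list where index = month and value = score or None
    (missing month).  For every completed month the state is recomputed
    from scratch using only the raw scores up to that month.
    """
    out = {}
    for m, s in enumerate(scores):
        if s is None:
            continue
        seq = [(i, scores[i]) for i in range(m + 1) if scores[i] is not None]
        out[m] = replay_single_domain(seq, local_thr, base_thr, interval)
    return out


def _record_values(record):
    return {r.item_id: (r.value if r.answered else 0) for r in record.responses}


def _urgent_domains(record, cutoff):
    values = _record_values(record)
    hit = set()
    for iid, scored, dom in URGENT_ITEMS:
        v = values.get(iid, 0)
        if (scored and v >= cutoff) or (not scored and v >= 1):
            hit.add(dom)
    return hit


def oracle_triage_levels(records, interval=6, cutoff=1, local_thr=None,
                         base_thr=None):
    """From-scratch global alert level per completed month for one patient.

    For each record, everything (scores, urgency, per-domain replay,
    combination, preference escalation) is recomputed from the raw
    records up to and including that month.
    """
    local_thr = local_thr or LOCAL_THR
    base_thr = base_thr or LOCAL_THR
    records = sorted(records, key=lambda r: r.month_index)
    out = {}
    for k, rec in enumerate(records):
        window = records[:k + 1]
        worst = "green"
        urgent_now = _urgent_domains(rec, cutoff)
        for dom, items in DOMAIN_ITEMS.items():
            seq = []
            for r in window:
                vals = _record_values(r)
                seq.append((r.month_index, sum(vals.get(i, 0) for i in items)))
            state = replay_single_domain(seq, local_thr[dom], base_thr[dom],
                                         interval)
            if dom in urgent_now:
                state = "orange"
            if SEV[state] > SEV[worst]:
                worst = state
        if worst == "orange" and rec.preference_response == "accepted":
            worst = "red"
        out[rec.month_index] = worst
    return out
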