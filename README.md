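# nedtriage

A rules-based triage engine for nurse-led prostate-cancer survivorship
care. Patients in remote follow-up complete the **EPIC-CP**
quality-of-life questionnaire monthly (5 symptom domains × 3 ordinal
items scored 0–4; domain score 0–12, total 0–60, higher = worse, plus
two non-scoring items for hematuria and bloody stools). The engine
turns each response set into a four-level traffic-light alert so a
single nurse can safely monitor a large roster and prioritize who needs
follow-up.

For each domain *d* it tracks two change scores,

```
Δ_local(d, t)    = S_d(t) − S_d(t_prev)        (most recent prior survey)
Δ_baseline(d, t) = S_d(t) − B_d(t)             (baseline, refreshed every 6 months)
```

and raises an *exceedance* when either Δ strictly exceeds the domain's
minimal clinically important difference — Δ>0 for urinary incontinence
and hormonal function, Δ>1 for urinary obstruction, bowel, and sexual
function (all tunable). Domain states escalate green → yellow (first
exceedance) → orange (repeat exceedance, or any of the 5 clinically
urgent symptoms: pain/burning urination, weak stream/incomplete
emptying, hematuria, bloody stools, depression). The global alert is
the worst domain state; an orange alert prompts the patient, and
becomes **red** only if they accept a nurse consultation. Surveys
completed more than 3 weeks from their due date (or never) flag the
patient overdue. Tailored self-management feedback is always the first
line of response.

A seeded synthetic-cohort generator (stable / gradually-worsening /
acute-event / improve-then-creep trajectories, missing months, urgent
events, preference responses) with a ground-truth event log makes every
rule and boundary testable without clinical data. See
`docs/methods.md` for the full rule set and design rationale.

## Worked example

Three monthly surveys for one patient whose bowel score climbs
2 → 4 → 6, accepting a consultation when prompted:

```
$ ned score example.csv
{"month_index": 0, "patient_id": "P0001", "scores": {"bowel": 2, ...}, "total": 2}
{"month_index": 1, "patient_id": "P0001", "scores": {"bowel": 4, ...}, "total": 4}
{"month_index": 2, "patient_id": "P0001", "scores": {"bowel": 6, ...}, "total": 6}

$ ned triage example.csv --out out
{"alerts": {"green": 1, "orange": 0, "red": 1, "yellow": 1}, "n_patients": 1, "n_records": 3, "overdue": 0}

$ cat out/dashboard.csv
patient_id,month_index,level,overdue,...,state_bowel,...,contributing_questions,preference_response
P0001,0,green,False,...,green,...,,
P0001,1,yellow,False,...,yellow,...,bw_frequency;bw_problem;bw_urgency,
P0001,2,red,False,...,orange,...,bw_frequency;bw_problem;bw_urgency,accepted
```

Month 0 is green (a change score needs two surveys). Month 1's +2 step
exceeds the bowel Δ>1 threshold for the first time — yellow. Month 2
exceeds again — orange, the patient is prompted, accepts, and the alert
escalates to red: direct nurse interaction required. The dashboard
lists the bowel questions that drove the alert. `ned simulate --seed 3
--out sim/` generates a full synthetic cohort with its ground-truth
log, and `ned validate` checks survey files against the schema.

The same pipeline is available as a library:

```python
from nedtriage import ThresholdConfig, triage_month
res = triage_month(record, histories, schema, ThresholdConfig())
res.alert.level, res.feedback.care_steps, res.histories
```

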