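# Methods

## The triage model

`nedtriage` implements a rules-based expert system for nurse-led
prostate-cancer survivorship care. Patients in remote follow-up complete
the EPIC-CP quality-of-life questionnaire monthly; the engine converts
each response set into a four-level traffic-light alert that tells the
nurse who needs attention, and why.

The pipeline for one patient-month is a deterministic composition:

1. **Scoring.** Each of the 5 symptom domains (urinary incontinence,
   urinary obstruction, bowel, sexual, hormonal) is the sum of its 3
   ordinal items (0 = no problem … 4 = big problem), giving a 0–12
   domain score and a 0–60 total; higher is worse. Two non-scoring
   binary items (hematuria, bloody stools) never enter any sum.
2. **Question-level urgency.** Five items are clinically urgent:
   pain/burning with urination, weak stream/incomplete emptying,
   hematuria, bloody stools, and depression. A scored urgent item at or
   above the urgency cutoff (default 1 — any reported problem), or a
   non-scoring urgent item marked present, raises a flag. Non-scoring
   flags attach to the clinically associated domain (hematuria →
   urinary obstruction as a urinary-tract differential; bloody stools →
   bowel as a radiation-related differential); scored urgent items
   attach to their own domain, so urgency can only ever escalate the
   obstruction, bowel, and hormonal domains under the default layout.
3. **Domain-level change scores.** Two Δs per domain: *local* (versus
   the most recent prior completed survey — missing months are skipped,
   never imputed) and *baseline* (versus a refreshing baseline seeded at
   the first survey and re-seeded with the current score once it is 6
   months old). An exceedance is `Δ > threshold` for **either** Δ
   (strict inequality: a Δ exactly at threshold never triggers;
   improvement, Δ < 0, never triggers). Default thresholds are the
   expert-codefined minimal clinically important differences: Δ>0 for
   urinary incontinence and hormonal function, Δ>1 for urinary
   obstruction, bowel, and sexual function.
4. **Domain state.** Green when nothing exceeds and no urgent flag;
   yellow on a domain's first-ever exceedance; orange on any repeat
   exceedance, or whenever an urgent flag is present regardless of Δ.
   The first survey has no Δ (two surveys are required for a change
   score) and is green unless urgent.
5. **Global alert.** The maximum severity across domains. An orange
   alert prompts the patient for their preference on a nurse
   consultation; **red** occurs only when the patient accepts while an
   orange domain state is present. A declined orange stays orange on
   the dashboard — the nurse may still act at their discretion.
6. **Outputs.** A feedback plan (one care-step content reference per
   non-green domain — self-management education is always the first
   line of response), and a dashboard summary listing the alert, the
   per-domain states, and the contributing questions.

Independently of the alert, a survey completed more than 21 days (3
weeks) from its expected due date — or never completed — flags the
patient overdue. Due dates are `enrollment + round(30.44·month)` days;
the calendar arithmetic for "expected due date" is not prescribed
anywhere authoritative, so the mean Gregorian month is used. When no
enrollment date is supplied, the batch pipeline infers it from the
patient's first completed survey, which is exact when that survey was
on time and shifts all due dates by its delay otherwise.

## Design choices where the rules were open

* **OR over the two Δs.** One threshold pair is co-defined per domain
  for both Δs but no AND/OR rule; OR was chosen for sensitivity — a
  triage system should err toward review.
* **Lifetime exceedance count.** "Second or more time" comes with no
  reset rule, and chronic creeping symptoms are the stated reason for
  keeping history, so the count never resets by default. A
  `reset_after_consecutive_green` option restores first-time (yellow)
  grace after N calm months for clinics that prefer it.
* **Urgency does not consume the first-time grace.** Only Δ exceedances
  increment the count: an isolated hematuria month followed by a first
  score jump yields orange then yellow, not orange then orange.
* **Refresh ordering.** A month's baseline Δ is computed against the
  baseline as it stood before that survey; the refresh applies
  afterwards. At the refresh month itself the (often negative) Δ against
  the old baseline is evaluated, then the baseline snaps to the current
  score.
* **Refresh is time-driven**, measured in month indices, not in number
  of completed surveys — "every 6 months" is calendar language.
* **Partial surveys.** Unanswered scored items contribute 0 and mark the
  domain incomplete; incompleteness is surfaced as a reason annotation
  but never changes the state, because no imputation rule exists and
  inventing one could manufacture or mask alerts.
* **Item layout.** The default schema has 3 scored items per domain
  (15 + 2 non-scoring), the only layout consistent with the 0–12/0–60
  ranges. The loader accepts alternative item counts with per-item
  weights provided each domain still maxes at 12 (e.g. 4 items at
  weight 0.75); weighted domain scores are rounded to the nearest
  integer on the 0–12 scale. Item texts are synthetic placeholders —
  the licensed instrument wording is not reproduced.
* **Preference as data.** The consultation preference is a field on the
  survey record, not interactive I/O, so the engine is batch-testable.
  `triage_month` consults it only when the combined level is orange;
  calling the escalation operation directly with `accepted` on a
  non-orange level raises a contract error.

## The synthetic cohort generator

No open longitudinal EPIC-CP dataset exists, so cohorts are simulated.
Four profiles span the dynamics the dual-Δ design targets: `stable`
(chronic fingerprint, must never alert), `gradual_worsening` (slow creep
— caught by the baseline Δ), `acute_event` (sudden persistent jump —
caught by the local Δ), and `improve_then_creep` (high start, recovery
at the refresh month, slow rise — alerts only against the refreshed
baseline). Domain scores are clamped to 0–12 and decomposed into item
categories by a deterministic greedy fill over the *non-urgent* items
first, so a trajectory never trips an urgency flag by accident; urgent
symptoms enter only as explicit Bernoulli events per tag per month (or
when a score above 4×(non-urgent items) forces spill-over, which the
ground-truth log also records). With nonzero noise, a ±1 ordinal jitter
perturbs domain scores and item decompositions are randomly
redistributed.

Cohort defaults: 100 patients, 12 monthly check-ins, 10% of check-ins
skipped, 5% completed past the 3-week grace, 50% acceptance when
prompted, enrollment staggered over 60 days. These are plausible
remote-monitoring conditions chosen once for the test bed; the
generator emulates response dynamics only — it does not model realistic
population prevalences, treatment-arm structure, correlated domains, or
informative missingness, so passing tests demonstrate the *rules* are
implemented exactly, not that the thresholds are clinically optimal.

Every patient carries a ground-truth log (threshold-crossing months
computed by an inline replay of the Δ definitions over the generated
scores, injected urgent events, missing and overdue months). All
randomness flows from one seeded `numpy` generator with per-patient
spawned streams; identical config + seed reproduces the cohort
byte-for-byte. Consultation preferences are sampled in a second pass on
the months the engine would prompt — preference never feeds back into
domain states, so the pass is exact.

## Verification

The incremental state machine is checked for exact equality against a
brute-force oracle that rebuilds all state from the raw survey sequence
from scratch at every month: exhaustively over all 87,380 sequences of
length ≤ 8 on the grid {missing, 0, 1, 2} for a Δ>1 domain (steps of 1
and 2 probe both threshold boundaries under every missing-data
pattern), all length ≤ 6 sequences for a Δ>0 domain and on a wide-swing
grid {missing, 0, 5, 12} (baseline-refresh behavior), 2,000 random
length ≤ 12 sequences over the full score range, and end-to-end on 200
simulated 24-month noisy trajectories with missing months, urgent
events, and sampled preferences. The 3^5 domain-state × 3 preference
escalation table is enumerated exhaustively. These sizes run in seconds
and were chosen to cover every rule boundary, not to sample it.

## Known limitations

* Chronically high but flat scores (Δ = 0 forever) never alert — the
  algorithm is purely change- and urgency-driven by design; absolute
  score floors would be a clinic-level extension.
* PSA/testosterone recurrence screening, messaging delivery, and the
  patient app are out of scope; the engine is the decision core only.
* Per-patient threshold tailoring is supported only as configuration
  (per-domain overrides), not as an adaptive procedure.
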