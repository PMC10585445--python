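"""Global alert engine: combination, preference, overdue, feedback, triage."""

import itertools
import json
from dataclasses import replace
from datetime import date, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from nedtriage import (
    GREEN, ORANGE, RED, SEVERITY, YELLOW, ConfigError, DomainState,
    PreferenceContractError, ThresholdConfig, apply_patient_preference,
    combine_domain_states, detect_overdue, expected_due_date, select_feedback,
    triage_month,
)
from nedtriage.schema import SCORED_DOMAINS
from conftest import ENROLLMENT, record_from_scores

STATES = (GREEN, YELLOW, ORANGE)
PREFS = ("accepted", "declined", "no_response")


def make_states(levels):
    return {dom: DomainState(domain_id=dom, state=lvl)
            for dom, lvl in zip(SCORED_DOMAINS, levels)}


class TestCombine:
    def test_all_green(self):
        assert combine_domain_states(make_states([GREEN] * 5)) == GREEN

    def test_single_yellow_dominates_greens(self):
        assert combine_domain_states(
            make_states([GREEN, YELLOW, GREEN, GREEN, GREEN])) == YELLOW

    def test_orange_dominates_yellow(self):
        assert combine_domain_states(
            make_states([ORANGE, YELLOW, GREEN, GREEN, GREEN])) == ORANGE

    def test_missing_domain_is_an_error(self):
        states = make_states([GREEN] * 5)
        del states["bowel"]
        with pytest.raises(ValueError, match="bowel"):
            combine_domain_states(states, SCORED_DOMAINS)

    def test_exhaustive_max_severity_over_all_combinations(self):
        for combo in itertools.product(STATES, repeat=5):
            expected = max(combo, key=SEVERITY.__getitem__)
            assert combine_domain_states(make_states(combo)) == expected


class TestPatientPreference:
    def test_orange_accepted_becomes_red(self):
        assert apply_patient_preference(ORANGE, "accepted") == RED

    @pytest.mark.parametrize("pref", ["declined", "no_response", None])
    def test_orange_without_acceptance_stays_orange(self, pref):
        assert apply_patient_preference(ORANGE, pref) == ORANGE

    def test_accepted_without_orange_is_contract_violation(self):
        with pytest.raises(PreferenceContractError):
            apply_patient_preference(YELLOW, "accepted")

    @pytest.mark.parametrize("level", [GREEN, YELLOW])
    @pytest.mark.parametrize("pref", ["declined", "no_response"])
    def test_green_yellow_pass_through(self, level, pref):
        assert apply_patient_preference(level, pref) == level

    def test_exhaustive_escalation_table(self):
        """All 3^5 domain-state combinations x 3 preferences match a
        brute-force table, and exactly 4 distinct levels are reachable."""
        reachable = set()
        for combo in itertools.product(STATES, repeat=5):
            worst = max(combo, key=SEVERITY.__getitem__)
            for pref in PREFS:
                if pref == "accepted" and worst != ORANGE:
                    continue  # the prompt only exists for orange
                expected = RED if (worst == ORANGE and pref == "accepted") \
                    else worst
                got = apply_patient_preference(
                    combine_domain_states(make_states(combo)), pref)
                assert got == expected
                reachable.add(got)
        assert reachable == {GREEN, YELLOW, ORANGE, RED}


class TestOverdue:
    DUE = date(2025, 6, 1)

    @pytest.mark.parametrize("days,expected", [
        (22, True), (21, False), (0, False), (-21, False), (-22, True)])
    def test_three_week_grace_is_strict(self, days, expected):
        done = self.DUE + timedelta(days=days)
        assert detect_overdue(done, self.DUE, grace_days=21) is expected

    def test_missing_completion_is_overdue(self):
        assert detect_overdue(None, self.DUE) is True

    def test_due_date_arithmetic(self):
        assert expected_due_date(ENROLLMENT, 0) == ENROLLMENT
        assert expected_due_date(ENROLLMENT, 2) == ENROLLMENT + timedelta(days=61)


class TestFeedback:
    def test_all_green_yields_empty_plan(self):
        plan = select_feedback(make_states([GREEN] * 5))
        assert not plan.care_steps and plan.first_line is False

    def test_one_care_step_per_non_green_domain(self):
        states = make_states([YELLOW, GREEN, ORANGE, GREEN, GREEN])
        plan = select_feedback(states)
        assert set(plan.care_steps) == {"urinary_incontinence", "bowel"}
        assert plan.first_line is True

    def test_missing_content_key_is_config_error(self):
        states = make_states([GREEN, GREEN, ORANGE, GREEN, GREEN])
        with pytest.raises(ConfigError, match="bowel"):
            select_feedback(states, content_table={})


class TestTriageMonth:
    def _run_months(self, months, thresholds=None):
        """months: list of (scores dict, overrides dict, preference)."""
        thresholds = thresholds or ThresholdConfig()
        histories = {}
        results = []
        from nedtriage import DEFAULT_SCHEMA
        for m, (scores, overrides, pref) in enumerate(months):
            rec = record_from_scores(scores, month=m, overrides=overrides,
                                     preference=pref)
            res = triage_month(rec, histories, DEFAULT_SCHEMA, thresholds,
                               enrollment_date=ENROLLMENT)
            histories = res.histories
            results.append(res)
        return results

    def test_identical_months_stay_green_with_no_feedback(self):
        res = self._run_months([({"bowel": 3}, None, None)] * 3)
        assert [r.alert.level for r in res] == [GREEN] * 3
        assert all(not r.feedback.care_steps for r in res)
        assert all(not r.alert.overdue for r in res)

    def test_first_bowel_jump_is_yellow_overall(self):
        res = self._run_months([({"bowel": 2}, None, None),
                                ({"bowel": 4}, None, None)])
        assert res[1].alert.level == YELLOW
        assert res[1].feedback.care_steps == {"bowel": "care-steps/bowel/yellow"}

    def test_repeat_jump_with_accepted_consult_is_red(self):
        res = self._run_months([({"bowel": 2}, None, None),
                                ({"bowel": 4}, None, None),
                                ({"bowel": 6}, None, "accepted")])
        assert [r.alert.level for r in res] == [GREEN, YELLOW, RED]
        assert res[2].alert.preference_prompted is True

    def test_urgent_item_alone_is_orange_with_contributing_question(self):
        res = self._run_months([({}, None, None),
                                ({}, {"ns_hematuria": 1}, None)])
        assert res[1].alert.level == ORANGE
        assert res[1].dashboard.contributing_questions == ("ns_hematuria",)
        assert res[1].alert.domain_states["urinary_obstruction"].state == ORANGE

    def test_declined_orange_stays_orange_and_is_recorded(self):
        res = self._run_months([({}, None, None),
                                ({}, {"ns_hematuria": 1}, "declined")])
        assert res[1].alert.level == ORANGE
        assert res[1].alert.preference_response == "declined"

    def test_overdue_flag_is_independent_of_scores(self):
        late = ENROLLMENT + timedelta(days=round(30.44) + 30)
        for scores in ({}, {"bowel": 12, "hormonal": 7}):
            rec = record_from_scores(scores, month=1, completion_date=late)
            res = triage_month(rec, {}, __import__("nedtriage").DEFAULT_SCHEMA,
                               ThresholdConfig(), enrollment_date=ENROLLMENT)
            assert res.alert.overdue is True

    def test_deterministic_and_byte_stable(self):
        runs = [self._run_months([({"bowel": 2}, None, None),
                                  ({"bowel": 5}, {"ns_hematuria": 1}, None)])
                for _ in range(2)]
        payloads = [json.dumps([r.alert.to_dict() for r in run], sort_keys=True)
                    for run in runs]
        assert payloads[0] == payloads[1]

    @settings(max_examples=60, deadline=None)
    @given(seq=st.lists(
        st.tuples(st.integers(0, 12), st.booleans(),
                  st.sampled_from(PREFS)), min_size=1, max_size=6))
    def test_red_requires_accepted_preference_on_orange(self, seq):
        """Red is unreachable without an accepted preference, and an
        urgent flag never lowers the month's level (end-to-end)."""
        from nedtriage import DEFAULT_SCHEMA
        histories, histories_u = {}, {}
        for m, (bowel, hematuria, pref) in enumerate(seq):
            rec = record_from_scores(
                {"bowel": bowel}, month=m,
                overrides={"ns_hematuria": int(hematuria)}, preference=pref)
            rec_u = record_from_scores(
                {"bowel": bowel}, month=m, overrides={"ns_hematuria": 1},
                preference=pref)
            res = triage_month(rec, histories, DEFAULT_SCHEMA,
                               ThresholdConfig(), enrollment_date=ENROLLMENT)
            res_u = triage_month(rec_u, histories_u, DEFAULT_SCHEMA,
                                 ThresholdConfig(), enrollment_date=ENROLLMENT)
            histories, histories_u = res.histories, res_u.histories
            if res.alert.level == RED:
                assert pref == "accepted"
                assert any(s.state == ORANGE
                           for s in res.alert.domain_states.values())
            assert SEVERITY[res_u.alert.level] >= SEVERITY[res.alert.level]
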