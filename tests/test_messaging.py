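"""SMS plans, template rendering, log processing and unsubscription."""

import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alkcheck.feedback import estimate_bac_permille
from alkcheck.messaging import (
    CATEGORY_POOLS,
    CONTENT_CATEGORIES,
    DEFAULT_BANK,
    PlanConfig,
    RenderError,
    SmsEvent,
    SmsLog,
    apply_incoming,
    attrition_rate,
    plan_messages,
    plan_to_frame,
    prune_plan,
    read_sms_log_jsonl,
    record_outgoing,
    render_message,
    write_sms_log_jsonl,
)
from alkcheck.risk_engine import RiskGroup
from conftest import make_baseline, make_screening

T0 = datetime.datetime(2012, 9, 3, 9, 0)  # a Monday morning


class TestPlanStructure:
    def test_non_risk_plan_is_12_weekly_messages(self, program_baseline):
        plan = plan_messages(RiskGroup.NON_RISK, program_baseline, T0, rng_seed=1)
        assert len(plan.entries) == 12
        assert all(e.slot == "weekly" for e in plan.entries)
        assert {e.category_id for e in plan.entries} <= {1, 2, 3, 4}

    def test_high_risk_plan_has_18_messages_with_counseling(self, program_baseline):
        plan = plan_messages(RiskGroup.HIGH_RISK, program_baseline, T0, rng_seed=1)
        assert len(plan.entries) == 18
        weekly = [e for e in plan.entries if e.slot == "weekly"]
        assert len(weekly) == 12
        assert any(e.category_id == 10 for e in weekly)

    def test_low_risk_drinking_day_messages_on_stated_weekday(self, program_baseline):
        plan = plan_messages(RiskGroup.LOW_RISK, program_baseline, T0, rng_seed=2)
        dd = [e for e in plan.entries if e.slot == "drinking_day"]
        assert len(dd) == 6  # biweekly over 12 weeks
        assert all(e.send_datetime.weekday() == 4 for e in dd)  # friday
        assert all(e.send_datetime.time() == datetime.time(21, 0) for e in dd)
        gaps = {
            (b.send_datetime - a.send_datetime).days for a, b in zip(dd, dd[1:])
        }
        assert gaps == {14}

    def test_every_pool_category_appears_within_12_weeks(self, program_baseline):
        for group in RiskGroup:
            plan = plan_messages(group, program_baseline, T0, rng_seed=3)
            weekly_cats = {e.category_id for e in plan.entries if e.slot == "weekly"}
            assert weekly_cats == set(CATEGORY_POOLS[group])

    def test_no_immediate_category_repeats_in_weekly_slot(self, program_baseline):
        for seed in range(20):
            plan = plan_messages(RiskGroup.HIGH_RISK, program_baseline, T0, seed)
            cats = [e.category_id for e in plan.entries if e.slot == "weekly"]
            assert all(a != b for a, b in zip(cats, cats[1:]))

    def test_deterministic_given_seed(self, program_baseline):
        a = plan_messages(RiskGroup.LOW_RISK, program_baseline, T0, 7)
        b = plan_messages(RiskGroup.LOW_RISK, program_baseline, T0, 7)
        assert a == b

    def test_all_sends_inside_the_12_week_window(self, program_baseline):
        plan = plan_messages(RiskGroup.HIGH_RISK, program_baseline, T0, 5)
        end = T0 + datetime.timedelta(weeks=12)
        assert all(T0 <= e.send_datetime < end for e in plan.entries)

    def test_biweekly_phase_configurable(self, program_baseline):
        even = PlanConfig(biweekly_phase=1)
        plan = plan_messages(
            RiskGroup.LOW_RISK, program_baseline, T0, 1, config=even
        )
        dd = [e for e in plan.entries if e.slot == "drinking_day"]
        assert len(dd) == 6
        assert min(e.send_datetime for e in dd) >= T0 + datetime.timedelta(weeks=1)

    def test_plan_export_has_one_row_per_entry(self, program_baseline):
        plan = plan_messages(RiskGroup.HIGH_RISK, program_baseline, T0, 1)
        frame = plan_to_frame(plan)
        assert len(frame) == 18
        assert set(frame["slot"]) == {"weekly", "drinking_day"}


class TestRendering:
    def test_simple_substitution(self):
        text = render_message("peer-01", {"name": "Peter"})
        assert "Peter" in text and "{" not in text

    def test_bac_slot_uses_widmark_estimate(self):
        bac = estimate_bac_permille(14, 12, 72, 0.68)
        text = render_message(
            "maxdrinks-01", {"name": "Mike", "max_drinks": 14, "bac_permille": bac}
        )
        assert "14 drinks" in text
        assert f"{bac:.1f} per-mille" in text

    def test_missing_placeholder_is_named(self):
        with pytest.raises(RenderError, match="bac_permille"):
            render_message("maxdrinks-01", {"name": "Mike", "max_drinks": 14})

    def test_overlong_message_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            render_message("peer-01", {"name": "x" * 600})

    def test_every_default_template_renders_under_the_limit(self):
        vars_ = {
            "name": "Alexandra-Christina",
            "max_drinks": 14,
            "bac_permille": 3.43,
            "counseling_contact": "The local counseling centre",
        }
        for tid in DEFAULT_BANK.templates:
            assert len(render_message(tid, vars_)) <= 480


class TestLog:
    def _event(self, text, minute=0, direction="in", pid="s0001"):
        return SmsEvent(T0 + datetime.timedelta(minutes=minute), direction, pid, text)

    def test_stop_keyword_unsubscribes_case_insensitive(self):
        log = apply_incoming(SmsLog(), self._event("  StOp "))
        assert "s0001" in log.unsubscribed_at

    def test_non_stop_message_only_appends(self):
        log = apply_incoming(SmsLog(), self._event("thanks"))
        assert log.unsubscribed_at == {}
        assert len(log.events) == 1

    def test_second_stop_is_idempotent(self):
        log = apply_incoming(SmsLog(), self._event("stop"))
        log = apply_incoming(log, self._event("STOP", minute=5))
        assert len(log.events) == 1
        assert log.unsubscribed_at["s0001"] == T0

    def test_out_of_order_event_rejected(self):
        log = apply_incoming(SmsLog(), self._event("hello", minute=10))
        with pytest.raises(ValueError, match="predates"):
            apply_incoming(log, self._event("late", minute=5))

    def test_manual_override_flag_unsubscribes_free_text(self):
        event = SmsEvent(T0, "in", "s0001", "please no more messages",
                         unsubscribe_override=True)
        log = apply_incoming(SmsLog(), event)
        assert "s0001" in log.unsubscribed_at

    def test_no_outgoing_after_unsubscription(self):
        log = apply_incoming(SmsLog(), self._event("stop"))
        with pytest.raises(ValueError, match="unsubscribed"):
            record_outgoing(log, self._event("hi", minute=60, direction="out"))

    def test_prune_plan_cancels_later_sends(self, program_baseline):
        plan = plan_messages(RiskGroup.LOW_RISK, program_baseline, T0, 1)
        cut = T0 + datetime.timedelta(weeks=4)
        log = apply_incoming(
            SmsLog(), SmsEvent(cut, "in", plan.person_id, "stop")
        )
        pruned = prune_plan(plan, log)
        assert all(e.send_datetime < cut for e in pruned.entries)
        assert len(pruned.entries) < len(plan.entries)

    @pytest.mark.parametrize(
        "n_unsub,n_part,expected",
        [(0, 10, 0.0), (23, 364, 23 / 364), (10, 10, 1.0)],
    )
    def test_attrition_rate(self, n_unsub, n_part, expected):
        log = SmsLog()
        for i in range(n_unsub):
            apply_incoming(log, self._event("stop", pid=f"p{i}"))
        assert attrition_rate(log, n_part) == pytest.approx(expected)
        if (n_unsub, n_part) == (23, 364):
            assert round(100 * attrition_rate(log, n_part), 1) == 6.3

    def test_jsonl_round_trip(self, tmp_path):
        log = SmsLog()
        record_outgoing(log, self._event("hi there", direction="out"))
        apply_incoming(log, self._event("stop", minute=5))
        path = tmp_path / "log.jsonl"
        write_sms_log_jsonl(log, path)
        loaded = read_sms_log_jsonl(path)
        assert loaded.events == log.events
        assert loaded.unsubscribed_at == log.unsubscribed_at


@settings(deadline=None, max_examples=60)
@given(
    group=st.sampled_from(list(RiskGroup)),
    day=st.sampled_from(["monday", "wednesday", "friday", "sunday"]),
    hour=st.integers(17, 22),
    seed=st.integers(0, 10_000),
)
def test_plan_invariants_hold_for_random_participants(group, day, hour, seed):
    """Message dose, pool membership and the counseling-category exclusivity
    hold for arbitrary participants and seeds."""
    baseline = make_baseline(
        typical_drinking_day=day,
        typical_drinking_time=datetime.time(hour, 0),
    )
    plan = plan_messages(group, baseline, T0, seed)
    expected_total = 12 if group is RiskGroup.NON_RISK else 18
    assert len(plan.entries) == expected_total
    weekly = [e for e in plan.entries if e.slot == "weekly"]
    assert len(weekly) == 12
    assert {e.category_id for e in weekly} <= CATEGORY_POOLS[group]
    if group is not RiskGroup.HIGH_RISK:
        assert all(e.category_id != 10 for e in plan.entries)
    assert all(e.category_id in CONTENT_CATEGORIES for e in plan.entries)
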