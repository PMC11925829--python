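"""Session orchestration: counterbalancing, phase structure, criteria."""

import pytest
from pydantic import ValidationError

import rulechoice as rc
from rulechoice.agents import RuleFollowingAgent
from rulechoice.errors import PhaseNotApplicableError

from conftest import (
    audit_cod_safety,
    audit_ext_silent,
    audit_reinforcer_structure,
    make_config,
)


class TestConditionTable:
    def test_table_has_eight_counterbalanced_rows(self):
        rows = rc.build_condition_table(1)
        assert len(rows) == 8
        assert sum(r.rich_side == "left" for r in rows) == 4
        # rich is always the VI-10, lean the VI-60 alternative
        assert all(r.rich.left.mean_s == 10 or r.rich.right.mean_s == 10
                   for r in rows)
        assert all(r.lean.left.mean_s == 60 or r.lean.right.mean_s == 60
                   for r in rows)

    def test_specific_rows(self):
        gp101 = rc.condition_by_id("GP101")
        assert gp101.rich_color == "red" and gp101.rich_side == "left"
        gp301 = rc.condition_by_id("GP301")
        assert gp301.rich_color == "red" and gp301.rich_side == "right"
        assert gp101.rule_map == {"red": "left", "blue": "right"}

    def test_experiment2_ids(self):
        rows = rc.build_condition_table(2)
        assert [r.participant_id for r in rows][:2] == ["CP111", "CP211"]
        with pytest.raises(rc.ConfigError):
            rc.condition_by_id("GP999")


class TestConfigValidation:
    def test_forced_ext_count_bounded_by_lean_components(self):
        with pytest.raises(ValidationError):
            make_config(n_forced_ext_lean=19)

    def test_criterion_defaults_by_experiment(self):
        assert make_config().effective_criterion_pct == 95.0
        assert make_config("CP111", experiment=2,
                           agent_type="rate_learning").effective_criterion_pct == 80.0


class TestTrainingPhase:
    def test_cycle_spans_140_seconds(self, exp1_result):
        """Two 60 s components and two 10 s inter-component intervals."""
        log = exp1_result.log
        onsets = {}
        for e in log.select(phase="training", event="component_on"):
            onsets.setdefault((e.block, e.cycle), []).append(e.t_s)
        for (block, cycle), ts in onsets.items():
            first = min(ts)
            rest_off = [e for e in log.events
                        if e.event == "rest_off" and e.payload["kind"] == "ici"
                        and e.t_s > first]
            second_ici_end = rest_off[1].t_s
            assert second_ici_end - first == pytest.approx(140.0, abs=1e-6)

    def test_structure_36_periods_random_order(self, exp1_result):
        log = exp1_result.log
        ons = log.select(phase="training", event="component_on")
        assert len(ons) == 36
        labels = [e.component_label for e in ons]
        assert labels.count("Rich") == labels.count("Lean") == 18
        # both components exactly once per cycle, order varies across cycles
        orders = set()
        for i in range(0, 36, 2):
            pair = (labels[i], labels[i + 1])
            assert set(pair) == {"Rich", "Lean"}
            orders.add(pair)
        assert len(orders) == 2  # both orderings occur over 18 cycles

    def test_exactly_six_forced_ext_lean_components(self, exp1_result):
        ons = exp1_result.log.select(phase="training", event="component_on",
                                     component_label="Lean")
        forced = [e for e in ons if e.payload["forced_ext"]]
        assert len(forced) == 6
        audit_ext_silent(exp1_result.log)

    def test_compliant_agent_passes_at_95(self, exp1_result):
        assert exp1_result.training_passed
        series = rc.percent_instructed_series(exp1_result.log, "Rich")
        assert (series.dropna() == 100.0).all()

    def test_silent_agent_fails_criterion_without_exception(self):
        class Mute(RuleFollowingAgent):
            def response_times(self, duration_s):
                return []

        cfg = make_config(seed=3)
        agent = Mute(rule_map={"red": "left", "blue": "right"},
                     rich_color="red", seed=4)
        result = rc.Session(cfg, agent=agent).run()
        assert result.training_passed is False
        assert not result.choice_test_run

    def test_rest_periods_between_blocks(self, exp1_result):
        rests = [e for e in exp1_result.log.events
                 if e.event == "rest_on" and e.payload["kind"] == "block_rest"]
        assert len(rests) == 2
        assert all(e.payload["duration_s"] == 30.0 for e in rests)


class TestRuleTestPhase:
    def test_perfect_agent_passes(self, exp1_result):
        assert exp1_result.rule_test_passed
        assert len(exp1_result.rule_answers) == 4
        assert {r.kind for r in exp1_result.rule_answers} == {"color_blank",
                                                             "side_blank"}

    def test_uppercase_answer_scored_incorrect(self):
        class Shouty(RuleFollowingAgent):
            def answer(self, kind, given):
                return super().answer(kind, given).upper()

        cfg = make_config(seed=5)
        agent = Shouty(rule_map={"red": "left", "blue": "right"},
                       rich_color="red", seed=6)
        result = rc.Session(cfg, agent=agent).run()
        assert result.rule_test_passed is False
        assert not result.choice_test_run  # experiment ends on failure

    def test_one_wrong_answer_fails_and_terminates(self):
        cfg = make_config(seed=6, agent_params={"rule_recall": 0.0})
        result = rc.Session(cfg).run()
        assert result.rule_test_passed is False
        assert not result.choice_test_run

    def test_phase_not_applicable_in_experiment2(self):
        cfg = make_config("CP111", experiment=2, agent_type="rate_learning")
        session = rc.Session(cfg)
        with pytest.raises(PhaseNotApplicableError):
            session.run_rule_test()

    def test_experiment2_session_skips_rule_test(self, exp2_result):
        assert exp2_result.rule_test_passed is None
        assert not exp2_result.log.select(phase="rule_test")
        assert exp2_result.choice_test_run


class TestChoiceTestPhase:
    def test_eight_components_two_cycles(self, exp1_result):
        ons = exp1_result.log.select(phase="choice_test", event="component_on")
        assert len(ons) == 8
        labels = [e.component_label for e in ons]
        for lab in ("Rich", "Lean", "BS", "NS"):
            assert labels.count(lab) == 2

    def test_bs_ns_deliver_zero_reinforcers(self, exp1_result, exp2_result):
        for result in (exp1_result, exp2_result):
            for e in result.log.select(phase="choice_test"):
                if e.component_label in ("BS", "NS"):
                    assert not e.event.startswith("reinforcer_")

    def test_bs_alternation_metadata(self, exp1_result):
        bs_on = [e for e in exp1_result.log.select(phase="choice_test",
                                                   event="component_on")
                 if e.component_label == "BS"]
        for e in bs_on:
            assert e.payload["alternation_ms"] == 400
            assert e.payload["initial_color"] in ("red", "blue")
            assert e.payload["flash_ms"] == 235

    def test_bs_displayed_color_alternates_every_400ms(self):
        """Agents conditioned on the displayed color see it flip each 400 ms."""
        seen = {}

        class Spy(RuleFollowingAgent):
            def choose(self, ctx):
                if ctx.label == "BS":
                    seen.setdefault(len(seen), ctx.displayed_color)
                return super().choose(ctx)

        cfg = make_config(seed=8, agent_params={"response_rate_hz": 2.0})
        agent = Spy(rule_map={"red": "left", "blue": "right"}, rich_color="red",
                    response_rate_hz=2.0, seed=9)
        result = rc.Session(cfg, agent=agent).run()
        assert result.choice_test_run
        assert set(seen.values()) == {"red", "blue"}


class TestDeterminismAndAudits:
    def test_event_log_replay_bit_for_bit(self):
        cfg = make_config("GP202", seed=13)
        a, b = rc.Session(cfg).run(), rc.Session(cfg).run()
        assert a.log == b.log
        assert a.log.to_frame().equals(b.log.to_frame())

    def test_structural_audits_on_full_sessions(self, exp1_result, exp2_result):
        for result in (exp1_result, exp2_result):
            result.log.validate()
            audit_cod_safety(result.log)
            audit_reinforcer_structure(result.log)
            audit_ext_silent(result.log)

    def test_earnings_track_reinforcers(self, exp1_result):
        assert exp1_result.earnings == pytest.approx(
            0.7 * exp1_result.total_reinforcers
        )
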