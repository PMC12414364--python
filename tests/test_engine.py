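"""Tests for the daily time-step engine: step composition, weaning logic, KPIs."""

import pytest

from calfsim import intake as intk
from calfsim import requirements as req
from calfsim import starter_energy as se
from calfsim.engine import (
    CalfState,
    Scenario,
    compare,
    kpis,
    simulate,
    step,
    trajectory_frame,
    bw_at_age,
)
from calfsim.intake import MilkPlan, StarterIntakeInputs
from calfsim.requirements import FeedingStage

from conftest import make_scenario


class TestStep:
    def test_single_step_matches_hand_composition(self, scenario):
        """One engine step equals the explicit composition of the module operations."""
        state = CalfState(day=9, bw=46.0, cum_nfc=0.4)
        new_state, rec = step(state, scenario)

        day = 10
        offered = scenario.plan.offered(day)
        consumed = intk.liquid_consumed(offered)
        liquid_dm, me_liquid = intk.liquid_dm_and_me(consumed, scenario.liquid)
        fp = (day - scenario.plan.first_starter_offer_day) / 7.0
        si = intk.starter_intake_temperate(
            StarterIntakeInputs(bw=46.0, me_i_ld=me_liquid, fp_starter=fp)
        )
        starter_dm = si / 1000.0
        dig = se.digestibilities(se.ln_ccs_nfci(0.4), scenario.starter.form)
        me_density = se.starter_me_density(scenario.starter, dig)
        me_total = me_liquid + starter_dm * me_density
        ebw = req.empty_body_weight(46.0, FeedingStage.PREWEANING)
        mem_value = req.mem(req.nem(ebw, FeedingStage.PREWEANING), req.km_preweaning())
        ne_gain = (me_total - mem_value) * scenario.k_g
        ebw_gain = req.ebw_gain_from_ne(ne_gain, ebw)

        assert rec.liquid_consumed == consumed
        assert rec.starter_dm == pytest.approx(starter_dm, rel=1e-12)
        assert rec.me_total == pytest.approx(me_total, rel=1e-12)
        assert rec.ne_gain == pytest.approx(ne_gain, rel=1e-12)
        assert rec.bw_gain == pytest.approx(ebw_gain / 0.91, rel=1e-12)
        assert new_state.bw == pytest.approx(46.0 + ebw_gain / 0.91, rel=1e-12)
        assert new_state.cum_nfc == pytest.approx(
            0.4 + starter_dm * scenario.starter.nfc_fraction, rel=1e-12
        )

    def test_offered_above_cap_is_capped(self):
        sc = make_scenario(plan_kwargs={"allowance_by_day": [(1, 20.0)]})
        _, rec = step(CalfState(day=0, bw=40.0), sc)
        assert rec.liquid_offered == 20.0
        assert rec.liquid_consumed == 14.0

    def test_starvation_sets_negative_balance_and_bw_drops(self):
        sc = make_scenario(plan_kwargs={"allowance_by_day": [(1, 0.0)]})
        state, rec = step(CalfState(day=0, bw=40.0), sc)
        assert rec.negative_balance
        assert state.bw < 40.0

    def test_total_dmi_is_sum_of_components(self, scenario):
        for rec in simulate(scenario):
            assert rec.total_dmi == pytest.approx(rec.liquid_dm + rec.starter_dm)


class TestSimulate:
    def test_deterministic(self, scenario):
        assert simulate(scenario) == simulate(scenario)

    def test_energy_conservation_each_day(self, scenario):
        for rec in simulate(scenario):
            if rec.ne_gain >= 0:
                assert rec.me_total - rec.mem == pytest.approx(
                    rec.ne_gain / scenario.k_g, abs=1e-9
                )

    def test_weaning_day_switches_equation_set(self, scenario):
        traj = simulate(scenario)
        wa = scenario.plan.weaning_age
        before, after = traj[wa - 2], traj[wa - 1]
        assert not before.weaned and after.weaned
        # preweaning day obeys NEM/0.69; weaned day uses the cubic k_m
        assert before.mem == pytest.approx(before.nem / 0.69)
        assert after.mem > after.nem  # k_m <= 1
        assert after.mem != pytest.approx(after.nem / 0.69)
        # NEM coefficient and EBW factor switch: recompute both readings
        bw_start = before.bw  # start-of-day BW on weaning day
        assert after.nem == pytest.approx(97.0 * (0.85 * bw_start) ** 0.75 / 1000.0)

    def test_more_milk_never_hurts_weaning_bw(self):
        """Doubling the allowance (below the cap) never decreases BW at weaning."""
        for base in (2.0, 4.0, 6.0):
            low = make_scenario(plan_kwargs={"allowance_by_day": [(1, base)]})
            high = make_scenario(plan_kwargs={"allowance_by_day": [(1, 2 * base)]})
            wa = low.plan.weaning_age
            assert simulate(high)[wa - 1].bw >= simulate(low)[wa - 1].bw

    def test_bw_changes_bounded_and_nfc_monotone(self, scenario):
        traj = simulate(scenario)
        prev_bw, prev_nfc = scenario.initial_bw, 0.0
        for rec in traj:
            assert abs(rec.bw - prev_bw) < 3.0
            assert rec.cum_nfc >= prev_nfc
            prev_bw, prev_nfc = rec.bw, rec.cum_nfc

    def test_lower_milk_promotes_starter_intake_at_equal_state(self):
        """At the same body weight and starter-exposure clock, a calf offered
        less milk eats more starter (milk-substitution effect)."""
        low = make_scenario(plan_kwargs={"allowance_by_day": [(1, 3.0)]})
        high = make_scenario(plan_kwargs={"allowance_by_day": [(1, 9.0)]})
        state = CalfState(day=20, bw=50.0, cum_nfc=2.0)
        _, rec_low = step(state, low)
        state = CalfState(day=20, bw=50.0, cum_nfc=2.0)
        _, rec_high = step(state, high)
        assert rec_low.starter_dm > rec_high.starter_dm

    def test_scenario_bounds_rejected_before_stepping(self):
        with pytest.raises(ValueError):
            make_scenario(initial_bw=19.0)
        with pytest.raises(ValueError):
            make_scenario(temperature=60.0)
        with pytest.raises(ValueError):
            make_scenario(horizon=101)


class TestKpis:
    def test_handmade_linear_trajectory_adg(self, scenario):
        traj = simulate(scenario)
        k = kpis(traj, scenario, window="full")
        assert k.adg == pytest.approx((traj[-1].bw - scenario.initial_bw) / traj[-1].day)

    def test_age_at_15kg_is_first_crossing(self, scenario):
        traj = simulate(scenario)
        k = kpis(traj, scenario, window="full")
        if k.age_at_15kg_nfc is not None:
            d = k.age_at_15kg_nfc
            assert traj[d - 1].cum_nfc >= 15.0
            assert all(r.cum_nfc < 15.0 for r in traj[: d - 1])

    def test_never_reaching_15kg_is_none(self):
        sc = make_scenario(horizon=10)
        assert kpis(simulate(sc), sc, window="full").age_at_15kg_nfc is None

    def test_cost_per_kg_undefined_without_gain(self):
        sc = make_scenario(plan_kwargs={"allowance_by_day": [(1, 0.0)]}, horizon=10)
        k = kpis(simulate(sc), sc, window="full")
        assert k.cost_per_kg_gain is None

    def test_weaning_window_truncates(self, scenario):
        kw = kpis(simulate(scenario), scenario, window="weaning")
        assert kw.final_bw < kpis(simulate(scenario), scenario, window="full").final_bw


class TestCompare:
    def test_five_scenarios_rejected(self):
        scs = [make_scenario(label=f"s{i}") for i in range(5)]
        with pytest.raises(ValueError):
            compare(scs)

    def test_single_scenario_table(self, scenario):
        out = compare([scenario])
        assert list(out["kpis"].columns) == ["base"]
        assert "weaning_final_bw_kg" in out["kpis"].index

    def test_order_permutes_columns_only(self):
        a = make_scenario(label="a", plan_kwargs={"allowance_by_day": [(1, 4.0)]})
        b = make_scenario(label="b", plan_kwargs={"allowance_by_day": [(1, 8.0)]})
        t1 = compare([a, b])["kpis"]
        t2 = compare([b, a])["kpis"]
        assert list(t1.columns) == ["a", "b"] and list(t2.columns) == ["b", "a"]
        assert t1["a"].equals(t2["a"]) and t1["b"].equals(t2["b"])


class TestTrajectoryAccess:
    def test_bw_at_age_zero_is_initial(self, scenario):
        traj = simulate(scenario)
        assert bw_at_age(traj, scenario, 0) == scenario.initial_bw
        assert bw_at_age(traj, scenario, 5) == traj[4].bw

    def test_frame_has_every_record_field_once(self, scenario):
        df = trajectory_frame(simulate(scenario), label="base")
        from dataclasses import fields
        from calfsim.engine import DailyRecord

        expected = ["scenario"] + [f.name for f in fields(DailyRecord)]
        assert list(df.columns) == expected
        assert len(df) == scenario.horizon
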