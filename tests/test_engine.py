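"""Cohort engine: transition semantics, accounting identities, conservation.

The hand-enumeration oracle re-implements the documented cycle semantics
(screening, background detection, progression, incidence, mortality, tunnel
increments) over an explicit dictionary of paths, independently of the
vectorised engine.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pytest

from darescreen.engine import CohortModel, discount, run_cohort, validation_summary
from darescreen.parameters import (
    AgeSchedule,
    ModelSettings,
    ParameterSet,
    Schedules,
    StrategySpec,
    standard_strategies,
)
from darescreen.survival import WeibullParams

STAGES = ("local", "regional", "distal")
NO_SCREEN = StrategySpec(label="No screening", screening=False)


def make_schedules(settings, inc=0.0, mort=0.0, shape=1.0, scale=10.0):
    n = settings.max_age - settings.start_age + 1
    return Schedules(
        incidence=AgeSchedule.from_array("incidence", settings.start_age, [inc] * n),
        other_cause_mortality=AgeSchedule.from_array(
            "other_cause_mortality", settings.start_age, [mort] * n
        ),
        survival={s: WeibullParams(stage=s, shape=shape, scale=scale) for s in STAGES},
    )


class TestDiscount:
    def test_zero_rate_identity(self):
        assert discount(123.4, 0.0, 7) == 123.4

    def test_half_cycle_closed_form(self):
        assert discount(100.0, 0.03, 1) == pytest.approx(100 * 1.03**-0.5, rel=1e-12)
        assert discount(100.0, 0.03, 1) == pytest.approx(98.533, abs=5e-4)

    def test_constant_stream_value_decreases_with_rate(self):
        values = [
            sum(discount(1.0, r, k) for k in range(1, 31))
            for r in (0.0, 0.01, 0.03, 0.05, 0.10)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestStepSemantics:
    def test_null_dynamics(self):
        settings = ModelSettings()
        model = CohortModel(ParameterSet(), settings, make_schedules(settings))
        occ = model.initial_occupancy()
        nxt, ev = model.step(occ, 40, NO_SCREEN)
        assert np.array_equal(nxt, occ)
        assert ev["incident"] == 0.0 and ev["deaths_other"] == 0.0

    def test_progression_ladder_local_to_death_in_three_cycles(self):
        """Undetected cancer progresses local -> regional -> distal over
        one-year periods and dies of cancer a year after undetected distal."""
        settings = ModelSettings()
        params = ParameterSet(
            p_background_detect_local=0.0,
            p_background_detect_regional=0.0,
            p_background_detect_distal=0.0,
        )
        model = CohortModel(params, settings, make_schedules(settings))
        occ = np.zeros(model.n_states)
        occ[model.undet["local"][0]] = 1.0
        occ, _ = model.step(occ, 40, NO_SCREEN)
        assert occ[model.undet["regional"][0]] == 1.0
        occ, _ = model.step(occ, 41, NO_SCREEN)
        assert occ[model.undet["distal"][0]] == 1.0
        occ, _ = model.step(occ, 42, NO_SCREEN)
        assert occ[model.i_dead_cancer] == 1.0

    def test_dwell_years_respected_for_slower_progression(self):
        settings = ModelSettings()
        params = ParameterSet(
            progression_interval_years=2,
            p_background_detect_local=0.0,
            p_background_detect_regional=0.0,
            p_background_detect_distal=0.0,
        )
        model = CohortModel(params, settings, make_schedules(settings))
        occ = np.zeros(model.n_states)
        occ[model.undet["local"][0]] = 1.0
        occ, _ = model.step(occ, 40, NO_SCREEN)
        assert occ[model.undet["local"][1]] == 1.0  # still local, year 2
        occ, _ = model.step(occ, 41, NO_SCREEN)
        assert occ[model.undet["regional"][0]] == 1.0

    def test_hand_path_enumeration_oracle(self):
        """Three cycles with incidence, background detection, other-cause and
        excess mortality agree with an independent path enumeration."""
        inc, q, shape, scale = 0.01, 0.05, 1.0, 10.0
        pbg = {"local": 0.2, "regional": 0.15, "distal": 0.1}
        settings = ModelSettings()
        params = ParameterSet()
        model = CohortModel(params, settings,
                            make_schedules(settings, inc=inc, mort=q,
                                           shape=shape, scale=scale))
        w = WeibullParams(stage="local", shape=shape, scale=scale)

        # independent enumeration over labelled states
        nxt_stage = {"local": "regional", "regional": "distal"}
        dist = {"well": 1.0}
        for _ in range(3):
            new: dict = defaultdict(float)

            def alive_or_dead(key, mass):
                new[key] += mass * (1 - q)
                new["do"] += mass * q

            for state, mass in dist.items():
                if state == "well":
                    newc = mass * inc
                    alive_or_dead(("u", "local"), newc)
                    alive_or_dead("well", mass - newc)
                elif state in ("dc", "do"):
                    new[state] += mass
                elif state[0] == "u":
                    stage = state[1]
                    det = mass * pbg[stage]
                    alive_or_dead(("d", stage, 0), det)
                    rem = mass - det
                    if stage == "distal":
                        new["dc"] += rem
                    else:
                        alive_or_dead(("u", nxt_stage[stage]), rem)
                else:  # detected tunnel state
                    _, stage, t = state
                    surv = mass * (1 - q)
                    new["do"] += mass * q
                    ex = surv * w.annual_death_prob(t)
                    new["dc"] += ex
                    new[("d", stage, t + 1)] += surv - ex
            dist = dict(new)

        occ = model.initial_occupancy()
        for age in (35, 36, 37):
            occ, _ = model.step(occ, age, NO_SCREEN)

        def engine_mass(key):
            if key == "well":
                return occ[model.i_well]
            if key == "dc":
                return occ[model.i_dead_cancer]
            if key == "do":
                return occ[model.i_dead_other]
            if key[0] == "u":
                return occ[model.undet[key[1]]].sum()
            return occ[model.det[key[1]][key[2]]]

        for key, mass in dist.items():
            assert engine_mass(key) == pytest.approx(mass, abs=1e-12), key
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


class TestRunCohort:
    def test_no_screening_has_zero_screening_cost(self, base_case, reference):
        params, settings = base_case
        trace, summary = run_cohort(NO_SCREEN, params, settings, reference)
        assert trace.events["screens"].sum() == 0.0
        assert trace.events["fp_referrals"].sum() == 0.0
        assert summary.screens == 0.0

    def test_immortal_cohort_closed_form(self):
        """No incidence, no mortality, r = 0: 65 life-years, 0.76 x 65 QALYs."""
        settings = ModelSettings(discount_rate=0.0)
        model = CohortModel(ParameterSet(), settings, make_schedules(settings))
        _, summary = model.run(NO_SCREEN)
        assert summary.life_years_undiscounted == pytest.approx(65.0, abs=1e-12)
        assert summary.qalys_undiscounted == pytest.approx(0.76 * 65, abs=1e-9)
        assert summary.cost_undiscounted == 0.0

    def test_probability_conservation_every_cycle(self, reference_model, menu):
        for strat in menu:
            trace, _ = reference_model.run(strat)
            sums = trace.occupancy.sum(axis=1)
            assert np.all(np.abs(sums - 1.0) < 1e-9)

    def test_deterministic_bit_identical_reruns(self, base_case, reference, menu):
        params, settings = base_case
        strat = menu[-1]
        t1, s1 = run_cohort(strat, params, settings, reference)
        t2, s2 = run_cohort(strat, params, settings, reference)
        assert np.array_equal(t1.occupancy, t2.occupancy)
        assert s1 == s2

    def test_discounted_below_undiscounted_and_qalys_below_lys(
        self, reference_summaries
    ):
        for s in reference_summaries.values():
            assert s.cost_discounted <= s.cost_undiscounted
            assert s.life_years_discounted <= s.life_years_undiscounted
            assert s.qalys_discounted <= s.qalys_undiscounted
            assert s.qalys_undiscounted < s.life_years_undiscounted

    def test_more_frequent_screening_costs_more_and_shifts_stage(
        self, reference_summaries
    ):
        """Within the age >= 50 band, shortening the interval never lowers
        lifetime cost and never lowers the localized share of detections."""
        labels = [
            "No screening",
            "Age >=50 every 5 years",
            "Age >=50 every 4 years",
            "Age >=50 every 3 years",
            "Age >=50 every 2 years",
            "Age >=50 every year",
        ]
        costs = [reference_summaries[l].cost_undiscounted for l in labels]
        locfrac = [reference_summaries[l].localized_fraction for l in labels]
        assert all(a <= b for a, b in zip(costs, costs[1:]))
        assert all(a <= b for a, b in zip(locfrac, locfrac[1:]))


class TestValidationSummary:
    def test_stage_fractions_sum_to_one(self, reference_model):
        trace, _ = reference_model.run(NO_SCREEN)
        vs = validation_summary(trace)
        assert vs.defined
        assert sum(vs.stage_distribution.values()) == pytest.approx(1.0, rel=1e-12)
        assert sum(vs.age_band_distribution.values()) == pytest.approx(1.0, rel=1e-9)

    def test_forced_early_detection_makes_diagnoses_localized(self):
        settings = ModelSettings()
        params = ParameterSet(
            dare_sensitivity=1.0,
            p_background_detect_local=1.0,
        )
        sched = make_schedules(settings, inc=0.002, mort=0.01)
        annual = StrategySpec(label="annual", screening=True, screen_start_age=35,
                              screen_end_age=99, interval_years=1)
        trace, _ = CohortModel(params, settings, sched).run(annual)
        vs = validation_summary(trace)
        assert vs.stage_distribution["local"] > 0.999

    def test_no_diagnoses_flagged_not_thrown(self):
        settings = ModelSettings()
        model = CohortModel(ParameterSet(), settings,
                            make_schedules(settings, inc=0.0, mort=0.01))
        trace, _ = model.run(NO_SCREEN)
        vs = validation_summary(trace)
        assert not vs.defined
        assert vs.lifetime_risk == 0.0
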