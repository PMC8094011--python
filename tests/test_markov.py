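import math

import numpy as np
import pytest

from helpers import exponential_curve, microsimulate, truncated_geometric_life_months
from lungcea.markov import (
    CohortTrace,
    HealthState,
    ScheduleError,
    TransitionSchedule,
    build_schedule,
    discount_factor,
    run_cohort,
    trace_overall_survival,
)
from lungcea.parameters import RunConfig, standard_strategies
from lungcea.survival import SurvivalCurve

S = HealthState


def zero_values(**overrides):
    """A complete parameter-value map, all zeros unless overridden."""
    values = {
        "nivo_ipi_per_cycle": 0.0,
        "chemo_total_per_cycle": 0.0,
        "second_line_nivo_ipi_per_cycle": 0.0,
        "second_line_chemo_per_cycle": 0.0,
        "toxicity_cost_nivo_ipi": 0.0,
        "toxicity_cost_chemo": 0.0,
        "toxicity_disutility_nivo_ipi": 0.0,
        "toxicity_disutility_chemo": 0.0,
        "stable_care_per_cycle": 0.0,
        "progressed_care_per_cycle": 0.0,
        "death_cost": 0.0,
        "utility_stable": 0.0,
        "utility_progression_decrement": 0.0,
        "patient_time_per_cycle": 0.0,
        "transport_nivo_ipi_per_cycle": 0.0,
        "transport_chemo_per_cycle": 0.0,
        "caregiver_per_cycle": 0.0,
        "productivity_loss_per_cycle": 0.0,
        "pemetrexed_per_cycle": 0.0,
    }
    values.update(overrides)
    return values


def run_config(horizon, rate=0.0, **kw):
    kw.setdefault("trial_followup_cycles", min(42, horizon))
    return RunConfig(horizon_cycles=horizon, annual_discount_rate=rate, **kw)


def nivo_strategy(**overrides):
    strat = standard_strategies()["nivo_ipi"]
    for k, v in overrides.items():
        setattr(strat, k, v)
    return strat


class TestDiscountFactor:
    def test_cycle_zero(self):
        assert discount_factor(0, 0.03) == 1.0

    def test_one_year(self):
        assert discount_factor(12, 0.03) == pytest.approx(1 / 1.03)

    def test_ten_years(self):
        assert discount_factor(120, 0.03) == pytest.approx(1.03**-10)

    def test_zero_rate(self):
        assert discount_factor(57, 0.0) == 1.0

    def test_negative_inputs(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)
        with pytest.raises(ValueError):
            discount_factor(1, -0.03)


class TestBuildSchedule:
    def test_zero_hazard_identity_except_routing(self):
        flat = SurvivalCurve(np.ones(13))
        strat = nivo_strategy(max_treatment_cycles=3, second_line_uptake=0.5)
        sched = build_schedule(flat, flat, strat, run_config(12))
        for t in range(12):
            m = sched.matrices[t]
            if t == 2:
                assert m[S.STABLE_FIRST_LINE] == pytest.approx([0.5, 0.5, 0, 0])
            else:
                assert m[S.STABLE_FIRST_LINE] == pytest.approx([1, 0, 0, 0])
            assert m[S.PROGRESSED, S.PROGRESSED] == 1.0

    def test_routing_mass_arrives_at_stop_cycle(self):
        flat = SurvivalCurve(np.ones(13))
        strat = nivo_strategy(max_treatment_cycles=3, second_line_uptake=0.4)
        sched = build_schedule(flat, flat, strat, run_config(12))
        res = run_cohort(sched, zero_values(), strat, run_config(12))
        occ = res.trace.occupancy[:, S.STABLE_SECOND_LINE]
        assert occ[2] == 0.0
        assert occ[3] == pytest.approx(0.4)
        assert np.all(occ[3:] == pytest.approx(0.4))

    def test_exponential_death_no_progression(self):
        curve = SurvivalCurve(exponential_curve(0.05, 24))
        sched = build_schedule(curve, curve, nivo_strategy(), run_config(24))
        for t in range(24):
            row = sched.matrices[t][S.STABLE_FIRST_LINE]
            assert row[S.DEAD] == pytest.approx(0.05)
            assert row[S.PROGRESSED] == pytest.approx(0.0)

    def test_rows_stochastic(self, inputs):
        from lungcea import model

        curves = model.extend_curves(inputs)
        strat = inputs.params.strategies["nivo_ipi"]
        sched = build_schedule(
            curves["os_nivo_ipi"], curves["pfs_nivo_ipi"], strat, inputs.params.run
        )
        assert np.allclose(sched.matrices.sum(axis=2), 1.0, atol=1e-12)

    def test_short_curve_rejected(self):
        curve = SurvivalCurve(exponential_curve(0.05, 10))
        with pytest.raises(ScheduleError):
            build_schedule(curve, curve, nivo_strategy(), run_config(24))

    def test_invalid_schedule_rejected(self):
        bad = np.tile(np.eye(4), (5, 1, 1))
        bad[0, 0, 0] = 0.5  # row no longer sums to 1
        with pytest.raises(ScheduleError):
            TransitionSchedule(bad)


class TestRunCohort:
    def test_no_event_utility_accrual(self):
        flat = SurvivalCurve(np.ones(13))
        strat = nivo_strategy()
        values = zero_values(utility_stable=0.754, toxicity_disutility_nivo_ipi=0.017)
        sched = build_schedule(flat, flat, strat, run_config(12))
        res = run_cohort(sched, values, strat, run_config(12))
        assert res.discounted_qalys == pytest.approx(0.754 - 0.017 / 12)
        assert res.discounted_cost == 0.0
        assert res.undiscounted_life_months == pytest.approx(12)

    def test_all_dead_at_cycle_one(self):
        curve = SurvivalCurve(np.concatenate([[1.0], np.zeros(12)]))
        strat = nivo_strategy()
        values = zero_values(
            nivo_ipi_per_cycle=26425,
            stable_care_per_cycle=2166,
            toxicity_cost_nivo_ipi=1185,
            death_cost=15957,
        )
        sched = build_schedule(curve, curve, strat, run_config(12))
        res = run_cohort(sched, values, strat, run_config(12))
        assert res.discounted_cost == pytest.approx(26425 + 2166 + 1185 + 15957)
        assert res.undiscounted_life_months == pytest.approx(1)

    def test_exponential_life_months_matches_geometric_sum(self):
        p = 0.05
        curve = SurvivalCurve(exponential_curve(p, 120))
        strat = nivo_strategy()
        sched = build_schedule(curve, curve, strat, run_config(120))
        res = run_cohort(sched, zero_values(), strat, run_config(120))
        assert res.undiscounted_life_months == pytest.approx(
            truncated_geometric_life_months(p, 120), rel=1e-12
        )

    def test_death_cost_discounted_at_cycle_of_death(self):
        curve = SurvivalCurve(np.concatenate([[1.0], np.zeros(12)]))
        strat = nivo_strategy()
        values = zero_values(death_cost=10_000)
        sched = build_schedule(curve, curve, strat, run_config(12, rate=0.03))
        res = run_cohort(sched, values, strat, run_config(12, rate=0.03))
        assert res.discounted_cost == pytest.approx(10_000 * 1.03 ** (-1 / 12))

    def test_societal_perspective_adds_components(self):
        curve = SurvivalCurve(exponential_curve(0.05, 24))
        strat = nivo_strategy()
        values = zero_values(
            patient_time_per_cycle=534,
            transport_nivo_ipi_per_cycle=91,
            caregiver_per_cycle=619,
            productivity_loss_per_cycle=854,
        )
        cfg = run_config(24)
        sched = build_schedule(curve, curve, strat, cfg)
        health = run_cohort(sched, values, strat, cfg, perspective="healthcare")
        societal = run_cohort(sched, values, strat, cfg, perspective="societal")
        alive_months = health.undiscounted_life_months
        assert health.discounted_cost == 0.0
        assert societal.discounted_cost == pytest.approx(
            (534 + 91 + 619 + 854) * alive_months
        )
        assert societal.discounted_qalys == health.discounted_qalys

    def test_fractional_cap_prorates_final_cycle(self):
        flat = SurvivalCurve(np.ones(13))
        values = zero_values(nivo_ipi_per_cycle=1000)
        full = nivo_strategy(max_treatment_cycles=2, second_line_uptake=0.0)
        frac = nivo_strategy(max_treatment_cycles=1.4, second_line_uptake=0.0)
        cfg = run_config(12)
        cost_full = run_cohort(
            build_schedule(flat, flat, full, cfg), values, full, cfg
        ).discounted_cost
        cost_frac = run_cohort(
            build_schedule(flat, flat, frac, cfg), values, frac, cfg
        ).discounted_cost
        assert cost_full == pytest.approx(2000)
        assert cost_frac == pytest.approx(1400)

    def test_continue_past_progression_accrues_drug_in_progressed(self):
        # OS flat, PFS falling: mass moves to PROGRESSED but nobody dies
        os_curve = SurvivalCurve(np.ones(25))
        pfs_curve = SurvivalCurve(exponential_curve(0.2, 24))
        cfg = run_config(24)
        base = nivo_strategy(second_line_uptake=0.0)
        cont = nivo_strategy(second_line_uptake=0.0, continue_past_progression=True)
        values = zero_values(nivo_ipi_per_cycle=1000)
        sched = build_schedule(os_curve, pfs_curve, base, cfg)
        res_base = run_cohort(sched, values, base, cfg)
        res_cont = run_cohort(sched, values, cont, cfg)
        prog_months = float(np.sum(res_cont.trace.occupancy[:-1, S.PROGRESSED]))
        assert res_cont.discounted_cost - res_base.discounted_cost == pytest.approx(
            1000 * prog_months
        )

    def test_maintenance_pemetrexed_added_after_cap(self):
        flat = SurvivalCurve(np.ones(13))
        cfg = run_config(12)
        strat = standard_strategies()["chemo"]
        strat.second_line_uptake = 0.0
        strat.maintenance_pemetrexed = True
        strat.nonsquamous_proportion = 0.5
        values = zero_values(pemetrexed_per_cycle=7990)
        sched = build_schedule(flat, flat, strat, cfg)
        res = run_cohort(sched, values, strat, cfg)
        # 9 post-cap cycles (3..11), all occupants stable, half nonsquamous
        assert res.discounted_cost == pytest.approx(7990 * 0.5 * 9)


class TestTraceInvariants:
    def test_conservation_and_dead_monotone(self, inputs):
        from lungcea import model

        results = model.run_pair(inputs)
        for res in results.values():
            occ = res.trace.occupancy
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(np.diff(occ[:, S.DEAD]) >= -1e-12)

    def test_round_trip_overall_survival(self, inputs):
        from lungcea import model

        curves = model.extend_curves(inputs)
        for name in ("nivo_ipi", "chemo"):
            strat = inputs.params.strategies[name]
            sched = build_schedule(
                curves[f"os_{name}"], curves[f"pfs_{name}"], strat, inputs.params.run
            )
            res = run_cohort(sched, zero_values(), strat, inputs.params.run)
            recovered = trace_overall_survival(res.trace)
            assert np.max(
                np.abs(recovered.probabilities - curves[f"os_{name}"].probabilities)
            ) < 1e-9

    def test_trace_rejects_nonconserved(self):
        occ = np.zeros((3, 4))
        occ[:, 0] = [1.0, 0.9, 0.8]  # mass leaks
        with pytest.raises(ScheduleError):
            CohortTrace(occ)

    def test_all_dead_trace_survival(self):
        curve = SurvivalCurve(np.concatenate([[1.0], np.zeros(12)]))
        strat = nivo_strategy()
        sched = build_schedule(curve, curve, strat, run_config(12))
        res = run_cohort(sched, zero_values(), strat, run_config(12))
        assert trace_overall_survival(res.trace).survival(1) == 0.0

    def test_flat_trace_survival(self):
        flat = SurvivalCurve(np.ones(13))
        strat = nivo_strategy()
        sched = build_schedule(flat, flat, strat, run_config(12))
        res = run_cohort(sched, zero_values(), strat, run_config(12))
        assert np.all(trace_overall_survival(res.trace).probabilities == 1.0)


class TestAccrualProperties:
    def test_discounting_strictly_reduces_totals(self, inputs):
        from lungcea import model

        res0 = model.run_pair(inputs)  # config rate is 3%
        values = inputs.params.means()
        curves = model.extend_curves(inputs)
        strat = inputs.params.strategies["nivo_ipi"]
        run3 = inputs.params.run
        sched = build_schedule(curves["os_nivo_ipi"], curves["pfs_nivo_ipi"], strat, run3)
        res = run_cohort(sched, values, strat, run3)
        assert res.discounted_cost < res.undiscounted_cost
        assert res.discounted_qalys < res.undiscounted_qalys
        assert res0["nivo_ipi"].discounted_cost == pytest.approx(res.discounted_cost)

    def test_zero_costs_give_zero_cost(self, inputs):
        from lungcea import model

        curves = model.extend_curves(inputs)
        strat = inputs.params.strategies["chemo"]
        sched = build_schedule(curves["os_chemo"], curves["pfs_chemo"], strat, inputs.params.run)
        res = run_cohort(
            sched, zero_values(utility_stable=0.754), strat, inputs.params.run
        )
        assert res.discounted_cost == 0.0
        assert res.discounted_qalys > 0

    def test_zero_utilities_give_zero_qalys(self, inputs):
        from lungcea import model

        curves = model.extend_curves(inputs)
        strat = inputs.params.strategies["chemo"]
        sched = build_schedule(curves["os_chemo"], curves["pfs_chemo"], strat, inputs.params.run)
        res = run_cohort(sched, zero_values(death_cost=15957), strat, inputs.params.run)
        assert res.discounted_qalys == 0.0
        assert res.discounted_cost > 0

    def test_half_cycle_correction_between_bounds(self, inputs):
        from lungcea import model

        curves = model.extend_curves(inputs)
        strat = inputs.params.strategies["nivo_ipi"]
        base_run = inputs.params.run
        hcc_run = RunConfig(
            horizon_cycles=base_run.horizon_cycles,
            annual_discount_rate=base_run.annual_discount_rate,
            trial_followup_cycles=base_run.trial_followup_cycles,
            half_cycle_correction=True,
        )
        values = inputs.params.means()
        sched = build_schedule(curves["os_nivo_ipi"], curves["pfs_nivo_ipi"], strat, base_run)
        plain = run_cohort(sched, values, strat, base_run)
        hcc = run_cohort(sched, values, strat, hcc_run)
        # mortality shifts mass out of alive states, so mid-cycle occupancy is lower
        assert hcc.discounted_qalys < plain.discounted_qalys
        assert hcc.discounted_qalys > 0.5 * plain.discounted_qalys


class TestMicrosimOracle:
    def test_cohort_matches_microsimulation(self, inputs):
        from lungcea import model

        curves = model.extend_curves(inputs)
        strat = inputs.params.strategies["nivo_ipi"]
        run = inputs.params.run
        values = inputs.params.means()
        sched = build_schedule(curves["os_nivo_ipi"], curves["pfs_nivo_ipi"], strat, run)
        cohort = run_cohort(sched, values, strat, run)
        n = 20_000
        cost, qalys = microsimulate(sched, values, strat, run, n, seed=7)
        for label, cohort_val, draws in (
            ("cost", cohort.discounted_cost, cost),
            ("qalys", cohort.discounted_qalys, qalys),
        ):
            se = draws.std() / math.sqrt(n)
            assert abs(cohort_val - draws.mean()) < 3 * se, label
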