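"""Four-state monthly cohort engine: transition schedules, traces, discounted accrual.

States: stable disease on first-line treatment, stable disease on second-line
treatment, progressed disease, death (absorbing).  The cohort enters entirely
in the first state; each cycle applies a 4x4 row-stochastic matrix built from
the arm's OS/PFS curves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping

import numpy as np

log = logging.getLogger(__name__)

from .parameters import ParameterSet, RunConfig, StrategyConfig
from .survival import SurvivalCurve, split_progression_death

__all__ = [
    "HealthState",
    "ScheduleError",
    "TransitionSchedule",
    "CohortTrace",
    "StrategyResult",
    "discount_factor",
    "build_schedule",
    "run_cohort",
    "trace_overall_survival",
]

_ROW_TOL = 1e-12
_TRACE_TOL = 1e-9


class HealthState(IntEnum):
    STABLE_FIRST_LINE = 0
    STABLE_SECOND_LINE = 1
    PROGRESSED = 2
    DEAD = 3


class ScheduleError(ValueError):
    """Raised when transition probabilities cannot form a stochastic matrix."""


@dataclass
class TransitionSchedule:
    """Per-cycle 4x4 transition matrices, indexed by cycle 0..horizon-1."""

    matrices: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1:] != (4, 4):
            raise ScheduleError(f"expected (n, 4, 4) matrices, got shape {m.shape}")
        if np.any(m < -_ROW_TOL) or np.any(m > 1 + _ROW_TOL):
            raise ScheduleError("transition probabilities must lie in [0, 1]")
        rowsums = m.sum(axis=2)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            t, s = np.unravel_index(np.argmax(np.abs(rowsums - 1.0)), rowsums.shape)
            raise ScheduleError(
                f"cycle {t}, state {HealthState(s).name}: row sums to {rowsums[t, s]}"
            )
        dead = m[:, HealthState.DEAD, :]
        expected = np.zeros(4)
        expected[HealthState.DEAD] = 1.0
        if np.any(np.abs(dead - expected) > _ROW_TOL):
            raise ScheduleError("DEAD must be absorbing")
        self.matrices = m

    @property
    def n_cycles(self) -> int:
        return self.matrices.shape[0]


@dataclass
class CohortTrace:
    """State-occupancy fractions per cycle; row 0 is the entry distribution."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 4:
            raise ScheduleError(f"expected (n+1, 4) occupancy, got shape {occ.shape}")
        sums = occ.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _TRACE_TOL):
            t = int(np.argmax(np.abs(sums - 1.0)))
            raise ScheduleError(f"cycle {t}: occupancies sum to {sums[t]}")
        dead = occ[:, HealthState.DEAD]
        if np.any(np.diff(dead) < -_ROW_TOL):
            t = int(np.argmax(np.diff(dead) < -_ROW_TOL))
            raise ScheduleError(f"cycle {t}: DEAD occupancy decreases")
        self.occupancy = occ

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


@dataclass
class StrategyResult:
    """Discounted totals, undiscounted diagnostics, and the cohort trace."""

    strategy: str
    discounted_cost: float
    discounted_qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float
    undiscounted_life_months: float
    trace: CohortTrace
    cost_breakdown: dict[str, float] = field(default_factory=dict)
    qaly_breakdown: dict[str, float] = field(default_factory=dict)


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Discount factor (1 + rate)**(-cycle/12) for a monthly cycle index."""
    if cycle < 0:
        raise ValueError(f"cycle index must be nonnegative, got {cycle}")
    if annual_rate < 0:
        raise ValueError(f"annual rate must be nonnegative, got {annual_rate}")
    return float((1.0 + annual_rate) ** (-cycle / 12.0))


def build_schedule(
    os_curve: SurvivalCurve,
    pfs_curve: SurvivalCurve,
    strategy: StrategyConfig,
    run: RunConfig,
    *,
    uptake: float | None = None,
    post_progression_hazard_multiplier: float = 1.0,
) -> TransitionSchedule:
    """Build the per-cycle transition matrices for one arm.

    Stable states face the marginal OS death probability plus the excess-PFS
    progression probability each cycle.  Progressed patients die at the OS
    hazard scaled by ``post_progression_hazard_multiplier`` (default 1, which
    makes the cohort trace reproduce the input OS curve exactly).  At the end
    of the last treatment cycle, non-progressing survivors route to the
    second-line state with probability ``uptake``.
    """
    n = run.horizon_cycles
    if os_curve.last_month < n or pfs_curve.last_month < n:
        raise ScheduleError(
            f"curves must cover the horizon ({n} cycles); OS ends at "
            f"{os_curve.last_month}, PFS at {pfs_curve.last_month}"
        )
    if uptake is None:
        uptake = strategy.second_line_uptake
    if not 0 <= uptake <= 1:
        raise ScheduleError(f"second-line uptake must be a probability, got {uptake}")
    stop_cycle = math.ceil(strategy.max_treatment_cycles)
    S = HealthState

    matrices = np.zeros((n, 4, 4))
    for t in range(n):
        so0 = os_curve.probabilities[t]
        so1 = os_curve.probabilities[t + 1]
        if so0 <= 0:
            p_progress, p_die, p_die_pp = 0.0, 1.0, 1.0
        else:
            p_progress, p_die = split_progression_death(pfs_curve, os_curve, t)
            r = so1 / so0
            p_die_pp = 1.0 - r**post_progression_hazard_multiplier
        if p_progress + p_die > 1.0 + _ROW_TOL:
            raise ScheduleError(
                f"cycle {t}: p_progress + p_die = {p_progress + p_die} exceeds 1"
            )
        stay = max(0.0, 1.0 - p_progress - p_die)
        route = uptake if t == stop_cycle - 1 else 0.0
        m = matrices[t]
        m[S.STABLE_FIRST_LINE] = (
            stay * (1.0 - route),
            stay * route,
            p_progress,
            p_die,
        )
        m[S.STABLE_SECOND_LINE] = (0.0, stay, p_progress, p_die)
        m[S.PROGRESSED] = (0.0, 0.0, 1.0 - p_die_pp, p_die_pp)
        m[S.DEAD] = (0.0, 0.0, 0.0, 1.0)
    return TransitionSchedule(matrices)


def _resolve_values(params) -> Mapping[str, float]:
    if isinstance(params, ParameterSet):
        return params.means()
    return dict(params)


def run_cohort(
    schedule: TransitionSchedule,
    params: "ParameterSet | Mapping[str, float]",
    strategy: StrategyConfig,
    run: RunConfig,
    *,
    perspective: str | None = None,
) -> StrategyResult:
    """Run the cohort through the schedule and accrue discounted costs and QALYs.

    Accrual rules per cycle ``t`` (state occupancy at the start of the cycle):

    - first-line drug cost in STABLE_FIRST_LINE while ``t < max_treatment_cycles``
      (a fractional cap prorates the final cycle);
    - second-line drug cost in STABLE_SECOND_LINE;
    - stable-state management cost in both stable states, progressed-state cost
      in PROGRESSED;
    - societal components in all alive states under the societal perspective;
    - one-time death cost on each cycle's new DEAD entrants, discounted at the
      cycle of death;
    - one-time toxicity cost and a 1-month toxicity disutility at entry;
    - utilities accrue at annual value / 12 per cycle.
    """
    values = _resolve_values(params)
    persp = perspective or run.perspective
    n = schedule.n_cycles
    rate = run.annual_discount_rate

    occ = np.zeros((n + 1, 4))
    occ[0, HealthState.STABLE_FIRST_LINE] = 1.0
    for t in range(n):
        occ[t + 1] = occ[t] @ schedule.matrices[t]
    trace = CohortTrace(occ)

    first_line = values[strategy.first_line_cost_param]
    second_line = values[strategy.second_line_cost_param]
    tox_cost = values[strategy.toxicity_cost_param]
    tox_disutility = values[strategy.toxicity_disutility_param]
    stable_cost = values["stable_care_per_cycle"]
    progressed_cost = values["progressed_care_per_cycle"]
    death_cost = values["death_cost"]
    u_stable = values["utility_stable"]
    u_progressed = u_stable - values["utility_progression_decrement"]
    societal_rate = (
        values["patient_time_per_cycle"]
        + values[strategy.transport_cost_param]
        + values["caregiver_per_cycle"]
        + values["productivity_loss_per_cycle"]
    )
    pemetrexed = values.get("pemetrexed_per_cycle", 0.0)

    cap = strategy.max_treatment_cycles
    stop_cycle = math.ceil(cap)
    cycles = np.arange(n)
    drug_fraction = np.clip(cap - cycles, 0.0, 1.0)  # prorates a fractional cap

    if run.half_cycle_correction:
        s1 = 0.5 * (occ[:-1, 0] + occ[1:, 0])
        s2 = 0.5 * (occ[:-1, 1] + occ[1:, 1])
        prog = 0.5 * (occ[:-1, 2] + occ[1:, 2])
    else:
        s1, s2, prog = occ[:-1, 0], occ[:-1, 1], occ[:-1, 2]
    stable = s1 + s2
    alive = stable + prog
    dead = occ[:, HealthState.DEAD]
    new_dead = np.diff(dead)

    def accrue(df: np.ndarray, df_next: np.ndarray):
        costs = {
            "first_line_drug": first_line * float(np.sum(s1 * drug_fraction * df)),
            "second_line_drug": second_line * float(np.sum(s2 * df)),
            "stable_care": stable_cost * float(np.sum(stable * df)),
            "progressed_care": progressed_cost * float(np.sum(prog * df)),
            "death": death_cost * float(np.sum(new_dead * df_next)),
            "toxicity": tox_cost * float(df[0]),
        }
        if strategy.continue_past_progression:
            costs["first_line_drug_post_progression"] = first_line * float(
                np.sum(prog * drug_fraction * df)
            )
        if strategy.maintenance_pemetrexed:
            mask = cycles >= stop_cycle
            costs["maintenance_pemetrexed"] = (
                pemetrexed
                * strategy.nonsquamous_proportion
                * float(np.sum(stable[mask] * df[mask]))
            )
        if persp == "societal":
            costs["societal"] = societal_rate * float(np.sum(alive * df))
        qalys = {
            "stable": u_stable / 12.0 * float(np.sum(stable * df)),
            "progressed": u_progressed / 12.0 * float(np.sum(prog * df)),
            "toxicity": -tox_disutility / 12.0 * float(df[0]),
        }
        return costs, qalys

    df = np.power(1.0 + rate, -cycles / 12.0)
    df_next = np.power(1.0 + rate, -(cycles + 1) / 12.0)
    ones = np.ones(n)
    cost_breakdown, qaly_breakdown = accrue(df, df_next)
    cost_undisc, qaly_undisc = accrue(ones, ones)

    log.info(
        "%s: one-time toxicity cost %.2f at cycle 0; expected death cost %.2f "
        "(discounted) over %d cycles",
        strategy.name, cost_breakdown["toxicity"], cost_breakdown["death"], n,
    )
    result = StrategyResult(
        strategy=strategy.name,
        discounted_cost=sum(cost_breakdown.values()),
        discounted_qalys=sum(qaly_breakdown.values()),
        undiscounted_cost=sum(cost_undisc.values()),
        undiscounted_qalys=sum(qaly_undisc.values()),
        undiscounted_life_months=float(np.sum(1.0 - dead[:-1])),
        trace=trace,
        cost_breakdown=cost_breakdown,
        qaly_breakdown=qaly_breakdown,
    )
    if result.discounted_cost > result.undiscounted_cost + 1e-6:
        raise ScheduleError("discounted cost exceeds undiscounted cost")
    if result.discounted_qalys > result.undiscounted_qalys + 1e-9:
        raise ScheduleError("discounted QALYs exceed undiscounted QALYs")
    if result.discounted_qalys > n / 12.0 + 1e-9:
        raise ScheduleError("QALYs exceed the horizon in years")
    return result


def trace_overall_survival(trace: CohortTrace) -> SurvivalCurve:
    """Model-implied overall survival: 1 - DEAD occupancy per cycle."""
    return SurvivalCurve(1.0 - trace.occupancy[:, HealthState.DEAD])
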