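"""Independent oracles used by the test suite.

The microsimulation below deliberately re-derives the accrual rules patient by
patient instead of reusing the cohort engine's vectorized accrual, so it can
serve as an independent check of the expected-value computation.
"""

import math

import numpy as np

from lungcea.markov import HealthState


def microsimulate(
    schedule,
    values,
    strategy,
    run,
    n_patients,
    seed,
    perspective="healthcare",
):
    """Individual-level simulation through a transition schedule.

    Returns per-patient arrays ``(discounted_cost, discounted_qalys)``.
    """
    rng = np.random.default_rng(seed)
    n = schedule.n_cycles
    rate = run.annual_discount_rate
    cum = schedule.matrices.cumsum(axis=2)

    first_line = values[strategy.first_line_cost_param]
    second_line = values[strategy.second_line_cost_param]
    stable_cost = values["stable_care_per_cycle"]
    progressed_cost = values["progressed_care_per_cycle"]
    death_cost = values["death_cost"]
    u_stable = values["utility_stable"]
    u_prog = u_stable - values["utility_progression_decrement"]
    societal = (
        values["patient_time_per_cycle"]
        + values[strategy.transport_cost_param]
        + values["caregiver_per_cycle"]
        + values["productivity_loss_per_cycle"]
    )
    cap = strategy.max_treatment_cycles

    states = np.full(n_patients, int(HealthState.STABLE_FIRST_LINE), dtype=np.int64)
    cost = np.full(n_patients, float(values[strategy.toxicity_cost_param]))
    qalys = np.full(
        n_patients, -values[strategy.toxicity_disutility_param] / 12.0
    )

    for t in range(n):
        df = (1.0 + rate) ** (-t / 12.0)
        s1 = states == HealthState.STABLE_FIRST_LINE
        s2 = states == HealthState.STABLE_SECOND_LINE
        prog = states == HealthState.PROGRESSED
        frac = min(1.0, max(0.0, cap - t))
        cost[s1] += (first_line * frac + stable_cost) * df
        cost[s2] += (second_line + stable_cost) * df
        cost[prog] += progressed_cost * df
        if perspective == "societal":
            cost[s1 | s2 | prog] += societal * df
        qalys[s1 | s2] += u_stable / 12.0 * df
        qalys[prog] += u_prog / 12.0 * df

        u = rng.random(n_patients)
        rows = cum[t][states]
        new_states = (u[:, None] > rows).sum(axis=1)
        died = (new_states == HealthState.DEAD) & (states != HealthState.DEAD)
        cost[died] += death_cost * (1.0 + rate) ** (-(t + 1) / 12.0)
        states = new_states
    return cost, qalys


def truncated_geometric_life_months(p_monthly, horizon):
    """Closed-form expected life-months under a constant monthly death probability."""
    q = 1.0 - p_monthly
    return (1.0 - q**horizon) / p_monthly


def exponential_curve(monthly_event_probability, horizon):
    """Survival curve with constant per-cycle event probability."""
    t = np.arange(horizon + 1)
    return (1.0 - monthly_event_probability) ** t


def brute_force_threshold(evaluate, target, low, high, step):
    """Grid-scan oracle: largest value in [low, high] whose ICER <= target."""
    best = None
    v = low
    while v <= high + 1e-12:
        if evaluate(v) <= target:
            best = v
        v += step
    return best


def gamma_moments(shape, scale):
    return shape * scale, math.sqrt(shape) * scale


def beta_moments(alpha, beta):
    mean = alpha / (alpha + beta)
    var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1.0))
    return mean, math.sqrt(var)
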