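"""Cost-effectiveness arithmetic, deterministic sensitivity analyses, thresholds, scenarios."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from . import model
from .markov import StrategyResult
from .parameters import ParameterError, ParameterSet

log = logging.getLogger(__name__)

__all__ = [
    "BracketError",
    "CEAResult",
    "TornadoEntry",
    "Scenario",
    "icer",
    "round_icer",
    "nmb",
    "percent_reduction",
    "compare_totals",
    "compare",
    "evaluate",
    "numeric_icer",
    "dsa_ranges",
    "one_way_dsa",
    "threshold_search",
    "price_threshold",
    "duration_threshold",
    "standard_scenarios",
    "run_scenarios",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
INDIFFERENT = "indifferent"


class BracketError(ValueError):
    """Raised when a threshold-search bracket does not straddle the target."""


def icer(delta_cost: float, delta_qalys: float) -> float | str:
    """Incremental cost-effectiveness ratio, or a dominance label.

    Sign convention: deltas are intervention minus comparator.  A ratio is
    returned whenever it is informative (both deltas share a sign and the
    QALY delta is nonzero); otherwise a dominance label.
    """
    if delta_cost == 0 and delta_qalys == 0:
        return INDIFFERENT
    if delta_qalys < 0:
        if delta_cost >= 0:
            return DOMINATED
        return delta_cost / delta_qalys  # southwest quadrant: savings per QALY forgone
    if delta_cost <= 0:
        return DOMINANT
    if delta_qalys == 0:
        return DOMINATED  # positive cost, no gain
    return delta_cost / delta_qalys


def round_icer(value: float) -> float:
    """Round a finite ICER to the nearest $100, half-up."""
    if not math.isfinite(value):
        raise ValueError(f"cannot round non-finite ICER {value}")
    return math.floor(value / 100.0 + 0.5) * 100.0


def nmb(cost: float, qalys: float, wtp: float) -> float:
    """Net monetary benefit wtp * qalys - cost."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be nonnegative, got {wtp}")
    return wtp * qalys - cost


def percent_reduction(base: float, reduced: float) -> float:
    """Percentage reduction 100 * (1 - reduced/base)."""
    if base <= 0:
        raise ValueError(f"base value must be positive, got {base}")
    return 100.0 * (1.0 - reduced / base)


@dataclass(frozen=True)
class CEAResult:
    """Two-strategy comparison: per-arm totals, increments, ICER, and NMBs."""

    intervention: str
    comparator: str
    costs: dict[str, float]
    qalys: dict[str, float]
    delta_cost: float
    delta_qalys: float
    icer: float | str
    icer_rounded: float | str
    wtp: float
    nmbs: dict[str, float]

    @property
    def cost_effective(self) -> bool:
        return self.nmbs[self.intervention] > self.nmbs[self.comparator]


def compare_totals(
    intervention_cost: float,
    intervention_qalys: float,
    comparator_cost: float,
    comparator_qalys: float,
    *,
    intervention: str = "nivo_ipi",
    comparator: str = "chemo",
    wtp: float = 100_000.0,
) -> CEAResult:
    """Build a :class:`CEAResult` from per-arm cost/QALY totals."""
    delta_cost = intervention_cost - comparator_cost
    delta_qalys = intervention_qalys - comparator_qalys
    ratio = icer(delta_cost, delta_qalys)
    rounded = round_icer(ratio) if isinstance(ratio, float) else ratio
    return CEAResult(
        intervention=intervention,
        comparator=comparator,
        costs={intervention: intervention_cost, comparator: comparator_cost},
        qalys={intervention: intervention_qalys, comparator: comparator_qalys},
        delta_cost=delta_cost,
        delta_qalys=delta_qalys,
        icer=ratio,
        icer_rounded=rounded,
        wtp=wtp,
        nmbs={
            intervention: nmb(intervention_cost, intervention_qalys, wtp),
            comparator: nmb(comparator_cost, comparator_qalys, wtp),
        },
    )


def compare(
    results: Mapping[str, StrategyResult],
    intervention: str,
    comparator: str,
    wtp: float = 100_000.0,
) -> CEAResult:
    """Compare two strategy results (intervention minus comparator)."""
    return compare_totals(
        results[intervention].discounted_cost,
        results[intervention].discounted_qalys,
        results[comparator].discounted_cost,
        results[comparator].discounted_qalys,
        intervention=intervention,
        comparator=comparator,
        wtp=wtp,
    )


def evaluate(inputs: model.ModelInputs, **run_kwargs) -> CEAResult:
    """Run both strategies and compare them; forwards kwargs to model.run_pair."""
    params = inputs.params
    results = model.run_pair(inputs, **run_kwargs)
    return compare(
        results, params.intervention, params.comparator, wtp=params.run.wtp_per_qaly
    )


def numeric_icer(result: CEAResult) -> float:
    """Map an ICER-or-label to the extended real line (for searches and sorting)."""
    if isinstance(result.icer, str):
        return {DOMINANT: -math.inf, DOMINATED: math.inf, INDIFFERENT: 0.0}[result.icer]
    return result.icer


@dataclass
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    parameter: str
    low: float
    high: float
    icer_low: float | str | None = None
    icer_high: float | str | None = None
    error: str | None = None

    @property
    def spread(self) -> float:
        if self.error is not None or self.icer_low is None or self.icer_high is None:
            return math.nan
        lo = self.icer_low if isinstance(self.icer_low, float) else math.nan
        hi = self.icer_high if isinstance(self.icer_high, float) else math.nan
        return abs(hi - lo)


OS_HAZARD_RATIO_KEY = "os_hazard_ratio"


def dsa_ranges(
    params: ParameterSet,
    *,
    fraction: float = 0.2,
    include: Sequence[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Default one-way ranges: the printed 95% CI when present, else mean +/- 20%."""
    names = include if include is not None else list(params.specs)
    ranges: dict[str, tuple[float, float]] = {}
    for name in names:
        spec = params.specs[name]
        if spec.ci95 is not None:
            ranges[name] = spec.ci95
        elif spec.mean > 0:
            ranges[name] = ((1 - fraction) * spec.mean, (1 + fraction) * spec.mean)
    return ranges


def one_way_dsa(
    inputs: model.ModelInputs,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    runner: Callable[..., CEAResult] | None = None,
) -> list[TornadoEntry]:
    """Re-run the model with each parameter at its low/high value, all else at base.

    The reserved range key ``os_hazard_ratio`` varies the OS hazard ratio by
    regenerating the intervention OS curve from the comparator curve.  Model
    failures at an extreme are recorded on the entry, not dropped.  Entries are
    sorted by spread descending (ties broken by name, so the tornado is
    invariant to input ordering).
    """
    if ranges is None:
        ranges = dsa_ranges(inputs.params)
    runner = runner or evaluate
    entries: list[TornadoEntry] = []
    for name, (low, high) in ranges.items():
        entry = TornadoEntry(parameter=name, low=float(low), high=float(high))
        try:
            if name == OS_HAZARD_RATIO_KEY:
                res_low = runner(inputs, os_hazard_ratio=low)
                res_high = runner(inputs, os_hazard_ratio=high)
            else:
                base = inputs.params.mean(name)
                if not low <= base <= high:
                    raise ParameterError(
                        f"range ({low}, {high}) does not bracket the base value {base}"
                    )
                res_low = runner(inputs, value_overrides={name: low})
                res_high = runner(inputs, value_overrides={name: high})
            entry.icer_low = res_low.icer
            entry.icer_high = res_high.icer
        except Exception as exc:  # noqa: BLE001 - flagged, never dropped
            entry.error = str(exc)
            log.warning("DSA for %s failed: %s", name, exc)
        entries.append(entry)
    entries.sort(key=lambda e: (-(e.spread if e.spread == e.spread else -math.inf), e.parameter))
    return entries


def threshold_search(
    target_wtp: float,
    variable_evaluator: Callable[[float], float],
    bracket: tuple[float, float],
    tol: float,
) -> float:
    """Bisection on a monotone variable -> ICER map until the bracket is below tol.

    Requires the target ICER to lie between the bracket endpoints' ICERs
    (either orientation).  Returns the variable value whose ICER meets the
    target within the resolution implied by ``tol``.
    """
    low, high = float(bracket[0]), float(bracket[1])
    if low >= high:
        raise BracketError(f"invalid bracket ({low}, {high})")
    f_low = variable_evaluator(low)
    f_high = variable_evaluator(high)
    increasing = f_low <= f_high
    lo_val, hi_val = (f_low, f_high) if increasing else (f_high, f_low)
    if not lo_val <= target_wtp <= hi_val:
        raise BracketError(
            f"bracket does not straddle the target: ICER({low}) = {f_low}, "
            f"ICER({high}) = {f_high}, target = {target_wtp}"
        )
    while high - low > tol:
        mid = 0.5 * (low + high)
        f_mid = variable_evaluator(mid)
        below = f_mid <= target_wtp if increasing else f_mid >= target_wtp
        if below:
            low = mid
        else:
            high = mid
    return 0.5 * (low + high)


def price_threshold(
    inputs: model.ModelInputs,
    *,
    target_wtp: float | None = None,
    bracket: tuple[float, float] | None = None,
    tol: float = 1.0,
) -> float:
    """Monthly intervention drug price at which the ICER meets the WTP target."""
    params = inputs.params
    target = target_wtp if target_wtp is not None else params.run.wtp_per_qaly
    price_param = params.strategies[params.intervention].first_line_cost_param
    if bracket is None:
        bracket = (0.0, params.mean(price_param))

    def at_price(price: float) -> float:
        return numeric_icer(evaluate(inputs, value_overrides={price_param: price}))

    return threshold_search(target, at_price, bracket, tol)


def duration_threshold(
    inputs: model.ModelInputs,
    *,
    target_wtp: float | None = None,
    bracket: tuple[float, float] | None = None,
    tol: float = 0.1,
) -> float:
    """Maximum intervention treatment duration (months, fractional) meeting the WTP.

    Fractional durations prorate the final cycle's drug cost.
    """
    params = inputs.params
    target = target_wtp if target_wtp is not None else params.run.wtp_per_qaly
    name = params.intervention
    if bracket is None:
        bracket = (0.05, params.strategies[name].max_treatment_cycles)

    def at_duration(months: float) -> float:
        return numeric_icer(
            evaluate(
                inputs,
                strategy_overrides={name: {"max_treatment_cycles": months}},
            )
        )

    return threshold_search(target, at_duration, bracket, tol)


@dataclass(frozen=True)
class Scenario:
    """A named configuration change relative to the base case."""

    name: str
    perspective: str | None = None
    extrapolation_mode: str | None = None
    continue_past_progression: bool = False
    maintenance_pemetrexed: bool = False
    nonsquamous_proportion: float | None = None
    curves_key: str | None = None
    os_hazard_ratio: float | None = None


def standard_scenarios() -> list[Scenario]:
    """The named main analyses: base case plus the four headline variations."""
    return [
        Scenario(name="base"),
        Scenario(name="societal", perspective="societal"),
        Scenario(name="cure", extrapolation_mode="cure_life_table"),
        Scenario(name="continue_past_progression", continue_past_progression=True),
        Scenario(name="maintenance_pemetrexed", maintenance_pemetrexed=True),
    ]


def run_scenarios(
    scenarios: Sequence[Scenario], inputs: model.ModelInputs
) -> dict[str, CEAResult]:
    """Run each scenario; each result reflects only that scenario's change."""
    params = inputs.params
    out: dict[str, CEAResult] = {}
    for sc in scenarios:
        strategy_overrides: dict[str, dict] = {}
        if sc.continue_past_progression:
            strategy_overrides[params.intervention] = {
                "continue_past_progression": True
            }
        if sc.maintenance_pemetrexed:
            block: dict = {"maintenance_pemetrexed": True}
            if sc.nonsquamous_proportion is not None:
                block["nonsquamous_proportion"] = sc.nonsquamous_proportion
            strategy_overrides[params.comparator] = block
        curves = None
        if sc.curves_key is not None:
            if sc.curves_key not in inputs.subgroup_curves:
                raise ParameterError(
                    f"scenario {sc.name!r}: no curve set named {sc.curves_key!r}"
                )
            curves = inputs.subgroup_curves[sc.curves_key]
        out[sc.name] = evaluate(
            inputs,
            perspective=sc.perspective,
            extrapolation_mode=sc.extrapolation_mode,
            strategy_overrides=strategy_overrides or None,
            curves=curves,
            os_hazard_ratio=sc.os_hazard_ratio,
        )
    return out
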