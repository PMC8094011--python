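"""Model inputs: distribution specifications, cost/utility tables, strategy and run configuration.

Every model quantity is represented as a :class:`DistributionSpec` carrying a
point estimate (the mean), a standard deviation for probabilistic analyses,
and optionally a printed 95% CI used for deterministic ranges.  Costs are in
2020 USD; utilities are on the 0-1 scale; transition-scale parameters are
probabilities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "ParameterError",
    "DistributionSpec",
    "CostInputs",
    "UtilityInputs",
    "StrategyConfig",
    "RunConfig",
    "ParameterSet",
    "default_sd",
    "gamma_from_mean_sd",
    "beta_from_mean_sd",
    "weighted_event_average",
    "load_parameters",
    "standard_strategies",
    "REQUIRED_PARAMETERS",
]


class ParameterError(ValueError):
    """Raised when a model input violates its contract."""


DEFAULT_SD_FRACTION = 0.2  # SD assumed to be 20% of the mean when not reported

PERSPECTIVES = ("healthcare", "societal")
EXTRAPOLATION_MODES = ("conditional_survival", "cure_life_table")


def default_sd(mean: float, fraction: float = DEFAULT_SD_FRACTION) -> float:
    """Standard deviation imputed for a parameter with no reported SD.

    The default rule is 20% of the mean; ``fraction`` widens or narrows the
    rule (the tested range is 10%-40%).
    """
    if mean < 0:
        raise ParameterError(f"default_sd requires a nonnegative mean, got {mean}")
    if not 0 < fraction <= 1:
        raise ParameterError(f"sd fraction must be in (0, 1], got {fraction}")
    return fraction * mean


def gamma_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments gamma parameters ``(shape, scale)`` for a cost variable."""
    if mean <= 0 or sd <= 0:
        raise ParameterError(
            f"gamma distribution requires positive mean and sd, got mean={mean}, sd={sd}"
        )
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def beta_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta parameters ``(alpha, beta)`` for a utility/probability."""
    if not 0 < mean < 1:
        raise ParameterError(f"beta distribution requires 0 < mean < 1, got {mean}")
    if sd <= 0:
        raise ParameterError(f"beta distribution requires positive sd, got {sd}")
    bound = mean * (1.0 - mean)
    if sd * sd >= bound:
        raise ParameterError(
            f"sd {sd} too large for beta with mean {mean}: "
            f"requires sd < sqrt(mean*(1-mean)) = {math.sqrt(bound):.6g}"
        )
    nu = bound / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def weighted_event_average(
    frequencies: Sequence[float], values: Sequence[float]
) -> float:
    """Expected one-time per-patient burden: sum of frequency x per-event value.

    Used to collapse per-event toxicity costs/disutilities into a single
    strategy-level value weighted by trial event frequencies.
    """
    if len(frequencies) != len(values):
        raise ParameterError(
            f"length mismatch: {len(frequencies)} frequencies vs {len(values)} values"
        )
    f = np.asarray(frequencies, dtype=float)
    v = np.asarray(values, dtype=float)
    if f.size == 0:
        return 0.0
    if np.any((f < 0) | (f > 1)):
        raise ParameterError("event frequencies must lie in [0, 1]")
    if np.any(v < 0):
        raise ParameterError("event values must be nonnegative")
    return float(f @ v)


@dataclass(frozen=True)
class DistributionSpec:
    """Point estimate plus sampling distribution for one model parameter.

    kind
        ``"gamma"`` for costs, ``"beta"`` for utilities and probabilities,
        ``"fixed"`` for quantities excluded from probabilistic analysis.
    """

    kind: str
    mean: float
    sd: float = 0.0
    ci95: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gamma", "beta", "fixed"):
            raise ParameterError(f"unknown distribution kind {self.kind!r}")
        if self.ci95 is not None:
            lo, hi = self.ci95
            object.__setattr__(self, "ci95", (float(lo), float(hi)))
            if not lo < self.mean < hi:
                raise ParameterError(
                    f"ci95 ({lo}, {hi}) does not bracket the mean {self.mean}"
                )
        if self.kind == "gamma":
            gamma_from_mean_sd(self.mean, self.sd)  # validates
        elif self.kind == "beta":
            beta_from_mean_sd(self.mean, self.sd)  # validates

    def sample(self, rng: np.random.Generator) -> float:
        """One random draw (the mean itself for ``kind='fixed'``)."""
        if self.kind == "fixed":
            return self.mean
        if self.kind == "gamma":
            shape, scale = gamma_from_mean_sd(self.mean, self.sd)
            return float(rng.gamma(shape, scale))
        alpha, beta = beta_from_mean_sd(self.mean, self.sd)
        return float(rng.beta(alpha, beta))


@dataclass(frozen=True)
class CostInputs:
    """Typed view of the cost parameters (all per-cycle unless noted; 2020 USD)."""

    first_line_drug_per_cycle: dict[str, float]
    second_line_drug_per_cycle: dict[str, float]
    stable_state_per_cycle: float
    progressed_state_per_cycle: float
    death_one_time: float
    toxicity_one_time: dict[str, float]
    patient_time_per_cycle: float
    transport_per_cycle: dict[str, float]
    caregiver_per_cycle: float
    productivity_loss_per_cycle: float

    def __post_init__(self) -> None:
        scalars = [
            self.stable_state_per_cycle,
            self.progressed_state_per_cycle,
            self.death_one_time,
            self.patient_time_per_cycle,
            self.caregiver_per_cycle,
            self.productivity_loss_per_cycle,
        ]
        for mapping in (
            self.first_line_drug_per_cycle,
            self.second_line_drug_per_cycle,
            self.toxicity_one_time,
            self.transport_per_cycle,
        ):
            scalars.extend(mapping.values())
        if any(v < 0 for v in scalars):
            raise ParameterError("all cost inputs must be nonnegative")


@dataclass(frozen=True)
class UtilityInputs:
    """Typed view of the utility parameters (annual scale; death fixed at 0)."""

    stable_utility_per_year: float
    progression_decrement_per_year: float
    toxicity_disutility: dict[str, float]
    death_utility: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.stable_utility_per_year, self.progression_decrement_per_year]
        vals.extend(self.toxicity_disutility.values())
        if any(not 0 <= v <= 1 for v in vals):
            raise ParameterError("utilities and decrements must lie in [0, 1]")
        if self.stable_utility_per_year < self.progression_decrement_per_year:
            raise ParameterError(
                "progression decrement exceeds the stable-disease utility"
            )
        if self.death_utility != 0:
            raise ParameterError("death utility is fixed at 0")


@dataclass
class StrategyConfig:
    """Treatment-arm configuration.

    ``max_treatment_cycles`` may be fractional: the final cycle's drug cost is
    prorated, which is what the treatment-duration threshold search varies.
    """

    name: str
    max_treatment_cycles: float
    second_line_uptake: float
    first_line_cost_param: str
    second_line_cost_param: str
    toxicity_cost_param: str
    toxicity_disutility_param: str
    transport_cost_param: str
    uptake_param: str | None = None
    maintenance_pemetrexed: bool = False
    nonsquamous_proportion: float = 1.0
    continue_past_progression: bool = False

    def __post_init__(self) -> None:
        if self.max_treatment_cycles < 1 and self.max_treatment_cycles <= 0:
            raise ParameterError(
                f"max_treatment_cycles must be positive, got {self.max_treatment_cycles}"
            )
        for label, p in (
            ("second_line_uptake", self.second_line_uptake),
            ("nonsquamous_proportion", self.nonsquamous_proportion),
        ):
            if not 0 <= p <= 1:
                raise ParameterError(f"{label} must be a probability, got {p}")


@dataclass
class RunConfig:
    """Global run configuration (cycle grid, discounting, perspective, horizon)."""

    horizon_cycles: int = 120
    cycle_length_months: float = 1.0
    annual_discount_rate: float = 0.03
    perspective: str = "healthcare"
    wtp_per_qaly: float = 100_000.0
    extrapolation_mode: str = "conditional_survival"
    trial_followup_cycles: int = 42
    half_cycle_correction: bool = False
    start_age_years: float = 64.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon_cycles < self.trial_followup_cycles:
            raise ParameterError(
                "horizon_cycles must be at least trial_followup_cycles "
                f"({self.horizon_cycles} < {self.trial_followup_cycles})"
            )
        if not 0 <= self.annual_discount_rate <= 0.2:
            raise ParameterError(
                f"annual_discount_rate must lie in [0, 0.2], got {self.annual_discount_rate}"
            )
        if self.perspective not in PERSPECTIVES:
            raise ParameterError(f"unknown perspective {self.perspective!r}")
        if self.extrapolation_mode not in EXTRAPOLATION_MODES:
            raise ParameterError(
                f"unknown extrapolation_mode {self.extrapolation_mode!r}"
            )
        if self.cycle_length_months != 1:
            raise ParameterError("cycle length is fixed at 1 month")


#: Canonical parameter names required for a full model run.
REQUIRED_PARAMETERS = (
    "nivolumab_per_cycle",
    "ipilimumab_per_cycle",
    "nivo_ipi_per_cycle",
    "pemetrexed_per_cycle",
    "gemcitabine_per_cycle",
    "cisplatin_per_cycle",
    "carboplatin_per_cycle",
    "chemo_total_per_cycle",
    "second_line_nivo_ipi_per_cycle",
    "second_line_chemo_per_cycle",
    "toxicity_cost_nivo_ipi",
    "toxicity_cost_chemo",
    "stable_care_per_cycle",
    "progressed_care_per_cycle",
    "death_cost",
    "patient_time_per_cycle",
    "transport_nivo_ipi_per_cycle",
    "transport_chemo_per_cycle",
    "caregiver_per_cycle",
    "productivity_loss_per_cycle",
    "utility_stable",
    "utility_progression_decrement",
    "toxicity_disutility_nivo_ipi",
    "toxicity_disutility_chemo",
    "second_line_uptake_nivo_ipi",
    "second_line_uptake_chemo",
)

_STRATEGY_PARAM_DEFAULTS: dict[str, dict[str, str]] = {
    "nivo_ipi": dict(
        first_line_cost_param="nivo_ipi_per_cycle",
        second_line_cost_param="second_line_nivo_ipi_per_cycle",
        toxicity_cost_param="toxicity_cost_nivo_ipi",
        toxicity_disutility_param="toxicity_disutility_nivo_ipi",
        transport_cost_param="transport_nivo_ipi_per_cycle",
        uptake_param="second_line_uptake_nivo_ipi",
    ),
    "chemo": dict(
        first_line_cost_param="chemo_total_per_cycle",
        second_line_cost_param="second_line_chemo_per_cycle",
        toxicity_cost_param="toxicity_cost_chemo",
        toxicity_disutility_param="toxicity_disutility_chemo",
        transport_cost_param="transport_chemo_per_cycle",
        uptake_param="second_line_uptake_chemo",
    ),
}


def standard_strategies(
    uptake_nivo_ipi: float = 0.377, uptake_chemo: float = 0.537
) -> dict[str, StrategyConfig]:
    """The two base-case arms: 24-cycle immunotherapy cap, 3-cycle chemotherapy cap."""
    return {
        "nivo_ipi": StrategyConfig(
            name="nivo_ipi",
            max_treatment_cycles=24,
            second_line_uptake=uptake_nivo_ipi,
            **_STRATEGY_PARAM_DEFAULTS["nivo_ipi"],
        ),
        "chemo": StrategyConfig(
            name="chemo",
            max_treatment_cycles=3,
            second_line_uptake=uptake_chemo,
            **_STRATEGY_PARAM_DEFAULTS["chemo"],
        ),
    }


@dataclass
class ParameterSet:
    """All model inputs: distribution specs plus strategy and run configuration."""

    specs: dict[str, DistributionSpec]
    run: RunConfig = field(default_factory=RunConfig)
    strategies: dict[str, StrategyConfig] = field(default_factory=standard_strategies)
    intervention: str = "nivo_ipi"
    comparator: str = "chemo"

    def mean(self, name: str) -> float:
        try:
            return self.specs[name].mean
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r}") from None

    def means(self) -> dict[str, float]:
        return {name: spec.mean for name, spec in self.specs.items()}

    def with_means(self, overrides: Mapping[str, float]) -> dict[str, float]:
        values = self.means()
        for name, value in overrides.items():
            if name not in values:
                raise ParameterError(f"unknown parameter {name!r}")
            values[name] = float(value)
        return values

    def as_fixed(self) -> "ParameterSet":
        """Copy with every distribution degenerate (for deterministic PSA checks)."""
        fixed = {
            name: DistributionSpec(kind="fixed", mean=s.mean, sd=0.0, ci95=s.ci95)
            for name, s in self.specs.items()
        }
        return replace(self, specs=fixed)

    def cost_inputs(self) -> CostInputs:
        m = self.means()
        return CostInputs(
            first_line_drug_per_cycle={
                "nivo_ipi": m["nivo_ipi_per_cycle"],
                "chemo": m["chemo_total_per_cycle"],
            },
            second_line_drug_per_cycle={
                "nivo_ipi": m["second_line_nivo_ipi_per_cycle"],
                "chemo": m["second_line_chemo_per_cycle"],
            },
            stable_state_per_cycle=m["stable_care_per_cycle"],
            progressed_state_per_cycle=m["progressed_care_per_cycle"],
            death_one_time=m["death_cost"],
            toxicity_one_time={
                "nivo_ipi": m["toxicity_cost_nivo_ipi"],
                "chemo": m["toxicity_cost_chemo"],
            },
            patient_time_per_cycle=m["patient_time_per_cycle"],
            transport_per_cycle={
                "nivo_ipi": m["transport_nivo_ipi_per_cycle"],
                "chemo": m["transport_chemo_per_cycle"],
            },
            caregiver_per_cycle=m["caregiver_per_cycle"],
            productivity_loss_per_cycle=m["productivity_loss_per_cycle"],
        )

    def utility_inputs(self) -> UtilityInputs:
        m = self.means()
        return UtilityInputs(
            stable_utility_per_year=m["utility_stable"],
            progression_decrement_per_year=m["utility_progression_decrement"],
            toxicity_disutility={
                "nivo_ipi": m["toxicity_disutility_nivo_ipi"],
                "chemo": m["toxicity_disutility_chemo"],
            },
        )


def _normalize_number(value) -> float:
    # tolerate thin-space / space / comma thousands separators in hand-edited files
    if isinstance(value, str):
        value = value.replace(" ", "").replace(" ", "").replace(" ", "")
        value = value.replace(",", "")
    return float(value)


def _parse_spec(entry: Mapping, sd_fraction: float) -> tuple[str, DistributionSpec]:
    name = entry.get("name")
    if not name:
        raise ParameterError(f"parameter entry missing a name: {entry!r}")
    try:
        mean = _normalize_number(entry["mean"])
    except KeyError:
        raise ParameterError(f"parameter {name!r}: missing mean") from None
    kind = entry.get("kind", "fixed")
    sd = entry.get("sd")
    if sd is None and kind != "fixed":
        sd = default_sd(mean, sd_fraction)
        log.debug("parameter %s: sd imputed as %g (%.0f%% of mean)", name, sd, 100 * sd_fraction)
    ci95 = entry.get("ci95")
    if ci95 is not None:
        ci95 = (_normalize_number(ci95[0]), _normalize_number(ci95[1]))
    try:
        spec = DistributionSpec(
            kind=kind,
            mean=mean,
            sd=0.0 if sd is None else _normalize_number(sd),
            ci95=ci95,
        )
    except ParameterError as exc:
        raise ParameterError(f"parameter {name!r}: {exc}") from None
    return str(name), spec


def _strategy_from_block(block: Mapping) -> StrategyConfig:
    name = block.get("name")
    if not name:
        raise ParameterError(f"strategy block missing a name: {block!r}")
    defaults = dict(_STRATEGY_PARAM_DEFAULTS.get(name, {}))
    fields = dict(defaults)
    for key in (
        "max_treatment_cycles",
        "second_line_uptake",
        "first_line_cost_param",
        "second_line_cost_param",
        "toxicity_cost_param",
        "toxicity_disutility_param",
        "transport_cost_param",
        "uptake_param",
        "maintenance_pemetrexed",
        "nonsquamous_proportion",
        "continue_past_progression",
    ):
        if key in block:
            fields[key] = block[key]
    missing = [
        k
        for k in (
            "max_treatment_cycles",
            "second_line_uptake",
            "first_line_cost_param",
            "second_line_cost_param",
            "toxicity_cost_param",
            "toxicity_disutility_param",
            "transport_cost_param",
        )
        if k not in fields
    ]
    if missing:
        raise ParameterError(f"strategy {name!r}: missing fields {missing}")
    return StrategyConfig(name=str(name), **fields)


def _validate_parameter_set(pset: ParameterSet) -> None:
    missing = [n for n in REQUIRED_PARAMETERS if n not in pset.specs]
    if missing:
        raise ParameterError(f"missing required parameters: {missing}")
    m = pset.means()
    combo = m["nivo_ipi_per_cycle"]
    parts = m["nivolumab_per_cycle"] + m["ipilimumab_per_cycle"]
    if abs(combo - parts) > 0.5:
        raise ParameterError(
            "combination drug cost must equal the sum of its components "
            f"({combo} != {m['nivolumab_per_cycle']} + {m['ipilimumab_per_cycle']})"
        )
    # typed views run their own invariant checks
    pset.cost_inputs()
    pset.utility_inputs()
    for name in ("utility_stable", "utility_progression_decrement"):
        if not 0 <= m[name] <= 1:
            raise ParameterError(f"parameter {name!r}: value {m[name]} outside [0, 1]")
    log.info("loaded %d parameters; validation passed", len(pset.specs))


def load_parameters(
    parameter_file: str | Path,
    config_file: str | Path | None = None,
    sd_fraction: float = DEFAULT_SD_FRACTION,
) -> ParameterSet:
    """Load and validate the parameter table (plus optional run/strategy config).

    The parameter file is YAML/JSON with one entry per table row:
    ``{name, mean, sd (optional), ci95 (optional), kind}``.  Missing SDs are
    imputed as ``sd_fraction`` of the mean.
    """
    parameter_file = Path(parameter_file)
    if not parameter_file.exists():
        raise ParameterError(f"parameter file not found: {parameter_file}")
    data = yaml.safe_load(parameter_file.read_text())
    entries = data.get("parameters", data) if isinstance(data, Mapping) else data
    if not isinstance(entries, list):
        raise ParameterError(f"{parameter_file}: expected a list of parameter entries")
    specs: dict[str, DistributionSpec] = {}
    for entry in entries:
        name, spec = _parse_spec(entry, sd_fraction)
        if name in specs:
            raise ParameterError(f"duplicate parameter {name!r}")
        specs[name] = spec

    run = RunConfig()
    strategies = standard_strategies()
    intervention, comparator = "nivo_ipi", "chemo"
    if config_file is not None:
        config_file = Path(config_file)
        if not config_file.exists():
            raise ParameterError(f"config file not found: {config_file}")
        cfg = yaml.safe_load(config_file.read_text()) or {}
        if "run" in cfg:
            run = RunConfig(**cfg["run"])
        if "strategies" in cfg:
            strategies = {}
            for block in cfg["strategies"]:
                strat = _strategy_from_block(block)
                strategies[strat.name] = strat
        intervention = cfg.get("intervention", intervention)
        comparator = cfg.get("comparator", comparator)

    pset = ParameterSet(
        specs=specs,
        run=run,
        strategies=strategies,
        intervention=intervention,
        comparator=comparator,
    )
    _validate_parameter_set(pset)
    return pset
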