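"""Wiring: load all inputs from a config file and run the two-arm model once.

This module owns the plumbing shared by the deterministic analyses, the
sensitivity analyses, and the probabilistic analysis: curve extension to the
horizon, optional hazard-ratio regeneration of the intervention OS curve,
per-replicate hazard multipliers, and strategy/parameter overrides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

from . import markov, survival
from .parameters import ParameterError, ParameterSet, load_parameters

log = logging.getLogger(__name__)

__all__ = ["ModelInputs", "load_inputs", "extend_curves", "run_pair"]

CURVE_KINDS = ("os", "pfs")


@dataclass
class ModelInputs:
    """Everything a model run needs: parameters, curves, extrapolation tables."""

    params: ParameterSet
    curves: dict[str, survival.SurvivalCurve]
    cs_table: survival.ConditionalSurvivalTable
    life_table: survival.LifeTable
    subgroup_curves: dict[str, dict[str, survival.SurvivalCurve]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for name in self.params.strategies:
            for kind in CURVE_KINDS:
                key = f"{kind}_{name}"
                if key not in self.curves:
                    raise ParameterError(f"missing survival curve {key!r}")


def _load_curve_set(block: Mapping, base: Path) -> dict[str, survival.SurvivalCurve]:
    curves: dict[str, survival.SurvivalCurve] = {}
    for arm, files in block.items():
        for kind in CURVE_KINDS:
            if kind not in files:
                raise ParameterError(f"curve block for {arm!r} missing {kind!r}")
            curves[f"{kind}_{arm}"] = survival.read_survival_points(base / files[kind])
    return curves


def load_inputs(config_path: str | Path) -> ModelInputs:
    """Load a run configuration plus every file it references.

    File paths inside the config are resolved relative to the config file.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise ParameterError(f"config file not found: {config_path}")
    cfg = yaml.safe_load(config_path.read_text()) or {}
    base = config_path.parent
    for key in ("parameters", "curves", "life_table", "conditional_survival"):
        if key not in cfg:
            raise ParameterError(f"{config_path}: missing {key!r} entry")
    params = load_parameters(base / cfg["parameters"], config_path)
    curves = _load_curve_set(cfg["curves"], base)
    cs_table = survival.read_conditional_survival(base / cfg["conditional_survival"])
    life_table = survival.read_life_table(base / cfg["life_table"])
    subgroups = {
        name: _load_curve_set(block, base)
        for name, block in cfg.get("subgroups", {}).items()
    }
    return ModelInputs(
        params=params,
        curves=curves,
        cs_table=cs_table,
        life_table=life_table,
        subgroup_curves=subgroups,
    )


def extend_curves(
    inputs: ModelInputs,
    mode: str | None = None,
    curves: Mapping[str, survival.SurvivalCurve] | None = None,
) -> dict[str, survival.SurvivalCurve]:
    """Extend every curve from the trial boundary through the horizon.

    Both OS and PFS are extended by the same mechanism; because the extension
    applies one shared hazard beyond the boundary, no excess progression
    hazard remains there.
    """
    run = inputs.params.run
    mode = mode or run.extrapolation_mode
    source = curves if curves is not None else inputs.curves
    out: dict[str, survival.SurvivalCurve] = {}
    boundary = run.trial_followup_cycles
    for key, curve in source.items():
        if mode == "conditional_survival":
            out[key] = survival.extend_conditional(
                curve, inputs.cs_table, boundary=boundary, horizon=run.horizon_cycles
            )
        else:
            out[key] = survival.extend_life_table(
                curve,
                inputs.life_table,
                start_age=run.start_age_years,
                boundary=boundary,
                horizon=run.horizon_cycles,
            )
    return out


def run_pair(
    inputs: ModelInputs,
    *,
    value_overrides: Mapping[str, float] | None = None,
    values: Mapping[str, float] | None = None,
    perspective: str | None = None,
    extrapolation_mode: str | None = None,
    curves: Mapping[str, survival.SurvivalCurve] | None = None,
    extended_curves: Mapping[str, survival.SurvivalCurve] | None = None,
    curve_multipliers: Mapping[str, float] | None = None,
    os_hazard_ratio: float | None = None,
    strategy_overrides: Mapping[str, Mapping] | None = None,
) -> dict[str, markov.StrategyResult]:
    """Run both strategies once and return results keyed by strategy name.

    ``values`` supplies a fully sampled parameter vector (PSA); otherwise the
    parameter means with ``value_overrides`` applied are used.  An
    ``os_hazard_ratio`` regenerates the intervention OS curve from the
    comparator curve via proportional hazards before extension.
    ``curve_multipliers`` raise each extended curve to a per-curve power
    (a hazard multiplier applied to every cycle).
    """
    params = inputs.params
    run = params.run
    if values is None:
        values = params.with_means(value_overrides or {})
    elif value_overrides:
        raise ParameterError("pass either values or value_overrides, not both")

    if extended_curves is None:
        raw = dict(curves if curves is not None else inputs.curves)
        if os_hazard_ratio is not None:
            anchor = raw[f"os_{params.comparator}"]
            raw[f"os_{params.intervention}"] = survival.apply_hazard_ratio(
                anchor, os_hazard_ratio
            )
        extended = extend_curves(inputs, mode=extrapolation_mode, curves=raw)
    else:
        extended = dict(extended_curves)
    if curve_multipliers:
        for key, mult in curve_multipliers.items():
            extended[key] = survival.apply_hazard_ratio(extended[key], mult)

    results: dict[str, markov.StrategyResult] = {}
    for name, strategy in params.strategies.items():
        overrides = dict((strategy_overrides or {}).get(name, {}))
        if overrides:
            strategy = replace(strategy, **overrides)
        uptake = strategy.second_line_uptake
        if strategy.uptake_param and strategy.uptake_param in values:
            uptake = values[strategy.uptake_param]
        schedule = markov.build_schedule(
            extended[f"os_{name}"],
            extended[f"pfs_{name}"],
            strategy,
            run,
            uptake=uptake,
        )
        results[name] = markov.run_cohort(
            schedule, values, strategy, run, perspective=perspective
        )
    return results
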