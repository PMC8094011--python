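"""Synthetic trial inputs: two-arm OS/PFS curves, extrapolation tables, parameter fixture.

The generated curves are piecewise exponential (the downstream engine only
consumes monthly hazards): the comparator OS curve hits its target median
exactly, the intervention OS curve follows by proportional hazards, and each
PFS curve adds a nonnegative progression hazard on top of its arm's OS hazard
so PFS never exceeds OS.  Default medians are placeholders for exercising the
pipeline, not estimates of any trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .parameters import ParameterError
from .survival import ConditionalSurvivalTable, LifeTable, SurvivalCurve

__all__ = [
    "SyntheticTrialSpec",
    "make_trial_curves",
    "make_life_table",
    "make_conditional_survival",
    "make_parameter_fixture",
    "write_parameter_fixture",
    "make_bundle",
]

DEFAULT_CONDITIONAL_SURVIVAL = (0.70, 0.78, 0.84, 0.88, 0.90, 0.92, 0.92)
DEFAULT_SUBGROUP_HRS = {
    # placeholder subgroup effect sizes for exercising the scenario machinery
    "pdl1_lt1": (0.64, 0.75),
    "pdl1_ge1": (0.78, 0.82),
    "pdl1_ge50": (0.68, 0.78),
}


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Shape parameters for the generated two-arm trial curves."""

    chemo_median_os: float = 12.0
    chemo_median_pfs: float = 5.0
    os_hazard_ratio: float = 0.73
    pfs_hazard_ratio: float = 0.79
    followup_months: int = 42
    knots: tuple[tuple[float, float], ...] = ((24.0, 1.35),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chemo_median_os <= 0 or self.chemo_median_pfs <= 0:
            raise ParameterError("medians must be positive")
        if self.chemo_median_pfs > self.chemo_median_os:
            raise ParameterError("PFS median cannot exceed OS median")
        if self.os_hazard_ratio <= 0 or self.pfs_hazard_ratio <= 0:
            raise ParameterError("hazard ratios must be positive")
        if self.followup_months < 1:
            raise ParameterError("followup_months must be at least 1")
        months = [k[0] for k in self.knots]
        if any(m <= 0 for m in months) or sorted(months) != list(months):
            raise ParameterError("knot months must be positive and increasing")
        if any(mult <= 0 for _, mult in self.knots):
            raise ParameterError("knot hazard multipliers must be positive")


def _hazard_weight(t: float, knots: tuple[tuple[float, float], ...]) -> float:
    """Effective exposure time w(t) such that cumulative hazard = base_hazard * w(t)."""
    weight = 0.0
    prev_month, mult = 0.0, 1.0
    for month, next_mult in knots:
        if t <= month:
            return weight + mult * (t - prev_month)
        weight += mult * (month - prev_month)
        prev_month, mult = month, next_mult
    return weight + mult * (t - prev_month)


def make_trial_curves(spec: SyntheticTrialSpec) -> dict[str, SurvivalCurve]:
    """Generate the four monthly curves keyed os_/pfs_ x chemo/nivo_ipi."""
    grid = np.arange(spec.followup_months + 1, dtype=float)
    weights = np.array([_hazard_weight(t, spec.knots) for t in grid])

    h_os = math.log(2.0) / _hazard_weight(spec.chemo_median_os, spec.knots)
    h_pfs_total = math.log(2.0) / _hazard_weight(spec.chemo_median_pfs, spec.knots)
    excess = h_pfs_total - h_os
    if excess < 0:
        raise ParameterError("PFS hazard below OS hazard: curves would cross")

    H_os_chemo = h_os * weights
    E_chemo = excess * weights
    curves = {
        "os_chemo": SurvivalCurve(np.exp(-H_os_chemo)),
        "pfs_chemo": SurvivalCurve(np.exp(-(H_os_chemo + E_chemo))),
        "os_nivo_ipi": SurvivalCurve(np.exp(-spec.os_hazard_ratio * H_os_chemo)),
        "pfs_nivo_ipi": SurvivalCurve(
            np.exp(
                -(spec.os_hazard_ratio * H_os_chemo + spec.pfs_hazard_ratio * E_chemo)
            )
        ),
    }
    return curves


def make_life_table(
    start_age: int, annual_q: list[float] | tuple[float, ...] | np.ndarray
) -> LifeTable:
    """Life table over contiguous ages starting at ``start_age``."""
    q = np.asarray(annual_q, dtype=float)
    ages = np.arange(int(start_age), int(start_age) + q.size)
    return LifeTable(ages=ages, annual_death_probability=q)


def default_life_table(start_age: float, horizon_cycles: int) -> LifeTable:
    """Age-increasing placeholder mortality covering the model horizon."""
    n_ages = int(math.floor(start_age + horizon_cycles / 12.0)) - int(start_age) + 2
    base = int(start_age)
    q = np.minimum(0.02 * 1.09 ** np.arange(n_ages), 0.95)
    return make_life_table(base, q)


def make_conditional_survival(
    annual_cs: list[float] | tuple[float, ...] | np.ndarray,
) -> ConditionalSurvivalTable:
    """Conditional-survival table for years 0..n-1 past the extrapolation boundary."""
    v = np.asarray(annual_cs, dtype=float)
    return ConditionalSurvivalTable(
        years=np.arange(v.size), annual_conditional_survival=v
    )


def make_parameter_fixture() -> list[dict]:
    """The bundled base-case parameter table (2020 USD; utilities annual scale).

    Infusion ($143) and follow-up/monitoring ($433) costs are already included
    in the per-cycle drug costs and are recorded here for reference only.
    """
    gamma = "gamma"
    beta = "beta"
    rows = [
        ("nivolumab_per_cycle", 14975, (9703, 21417), gamma),
        ("ipilimumab_per_cycle", 11450, (7413, 16296), gamma),
        ("nivo_ipi_per_cycle", 26425, (17089, 37662), gamma),
        ("pemetrexed_per_cycle", 7990, (5182, 11395), gamma),
        ("gemcitabine_per_cycle", 118, (76, 169), gamma),
        ("cisplatin_per_cycle", 94, (61, 134), gamma),
        ("carboplatin_per_cycle", 163, (105, 233), gamma),
        ("chemo_total_per_cycle", 7929, (5151, 11331), gamma),
        ("second_line_nivo_ipi_per_cycle", 8908, (5764, 12735), gamma),
        ("second_line_chemo_per_cycle", 12093, (7824, 17255), gamma),
        ("toxicity_cost_nivo_ipi", 1185, (767, 1695), gamma),
        ("toxicity_cost_chemo", 6384, (4139, 9127), gamma),
        ("stable_care_per_cycle", 2166, (1397, 3098), gamma),
        ("progressed_care_per_cycle", 4000, (2575, 5712), gamma),
        ("death_cost", 15957, (10335, 22818), gamma),
        ("patient_time_per_cycle", 534, (345, 763), gamma),
        ("transport_nivo_ipi_per_cycle", 91, (59, 130), gamma),
        ("transport_chemo_per_cycle", 61, (39, 87), gamma),
        ("caregiver_per_cycle", 619, (401, 882), gamma),
        ("productivity_loss_per_cycle", 854, (553, 1219), gamma),
        ("utility_stable", 0.754, (0.407, 0.970), beta),
        ("utility_progression_decrement", 0.180, (0.115, 0.367), beta),
        ("toxicity_disutility_nivo_ipi", 0.017, (0.011, 0.024), beta),
        ("toxicity_disutility_chemo", 0.019, (0.012, 0.027), beta),
        ("second_line_uptake_nivo_ipi", 0.377, None, beta),
        ("second_line_uptake_chemo", 0.537, None, beta),
    ]
    entries = []
    for name, mean, ci95, kind in rows:
        entry: dict = {"name": name, "mean": mean, "kind": kind}
        if ci95 is not None:
            entry["ci95"] = list(ci95)
        entries.append(entry)
    entries.append(
        {
            "name": "infusion_per_cycle",
            "mean": 143,
            "kind": "fixed",
            "note": "already included in per-cycle drug costs",
        }
    )
    entries.append(
        {
            "name": "followup_monitoring_per_cycle",
            "mean": 433,
            "kind": "fixed",
            "note": "already included in per-cycle drug costs",
        }
    )
    return entries


def write_parameter_fixture(path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump({"parameters": make_parameter_fixture()}, sort_keys=False))
    return path


def make_bundle(
    out_dir: str | Path,
    trial: SyntheticTrialSpec | None = None,
    *,
    seed: int = 0,
    start_age: float = 64.0,
    horizon_cycles: int = 120,
    annual_discount_rate: float = 0.03,
    conditional_survival: tuple[float, ...] = DEFAULT_CONDITIONAL_SURVIVAL,
    subgroup_hrs: dict[str, tuple[float, float]] | None = None,
) -> Path:
    """Write a complete, self-consistent input bundle and return the config path.

    Emits the four curve files, life table, conditional-survival table,
    parameter fixture, and a run config wired to them (paths relative to the
    bundle directory).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trial = trial or SyntheticTrialSpec(seed=seed)

    curves = make_trial_curves(trial)
    for key, curve in curves.items():
        curve.write(out_dir / f"{key}.tsv")

    n_years = (horizon_cycles - trial.followup_months) // 12 + 2
    cs = conditional_survival
    if len(cs) < n_years:
        cs = tuple(cs) + (cs[-1],) * (n_years - len(cs))
    make_conditional_survival(cs).write(out_dir / "conditional_survival.tsv")
    default_life_table(start_age, horizon_cycles).write(out_dir / "life_table.tsv")
    write_parameter_fixture(out_dir / "parameters.yaml")

    config: dict = {
        "parameters": "parameters.yaml",
        "curves": {
            "nivo_ipi": {"os": "os_nivo_ipi.tsv", "pfs": "pfs_nivo_ipi.tsv"},
            "chemo": {"os": "os_chemo.tsv", "pfs": "pfs_chemo.tsv"},
        },
        "life_table": "life_table.tsv",
        "conditional_survival": "conditional_survival.tsv",
        "intervention": "nivo_ipi",
        "comparator": "chemo",
        "run": {
            "horizon_cycles": horizon_cycles,
            "annual_discount_rate": annual_discount_rate,
            "trial_followup_cycles": trial.followup_months,
            "start_age_years": start_age,
            "seed": seed,
        },
        "strategies": [
            {"name": "nivo_ipi", "max_treatment_cycles": 24, "second_line_uptake": 0.377},
            {"name": "chemo", "max_treatment_cycles": 3, "second_line_uptake": 0.537},
        ],
    }
    if subgroup_hrs:
        config["subgroups"] = {}
        for name, (os_hr, pfs_hr) in subgroup_hrs.items():
            sub_spec = SyntheticTrialSpec(
                chemo_median_os=trial.chemo_median_os,
                chemo_median_pfs=trial.chemo_median_pfs,
                os_hazard_ratio=os_hr,
                pfs_hazard_ratio=pfs_hr,
                followup_months=trial.followup_months,
                knots=trial.knots,
                seed=seed,
            )
            sub_curves = make_trial_curves(sub_spec)
            block: dict = {"nivo_ipi": {}, "chemo": {}}
            for key, curve in sub_curves.items():
                kind, arm = key.split("_", 1)
                fname = f"{name}_{key}.tsv"
                curve.write(out_dir / fname)
                block[arm][kind] = fname
            config["subgroups"][name] = block

    config_path = out_dir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
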