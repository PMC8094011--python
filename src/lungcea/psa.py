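"""Probabilistic sensitivity analysis and cost-effectiveness acceptability curves.

Each replicate draws every parameter from its distribution (gamma for costs,
beta for utilities and probabilities) plus one hazard multiplier per survival
curve, reruns both strategies, and records the per-arm (cost, QALY) pair.

Curve uncertainty is parameterized as a beta draw on the curve's mean monthly
event probability; the ratio draw/mean becomes a hazard multiplier applied to
every cycle, which preserves curve monotonicity.  The draw order is fixed:
parameters in sorted-name order, then curve multipliers in sorted-key order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import cea, model
from .parameters import DistributionSpec, ParameterSet
from .survival import SurvivalCurve, monthly_event_probability

log = logging.getLogger(__name__)

__all__ = [
    "PSASample",
    "CEACPoint",
    "curve_event_probability_mean",
    "curve_uncertainty_specs",
    "sample_parameters",
    "run_psa",
    "ceac",
    "summarize",
]


@dataclass(frozen=True)
class PSASample:
    """One Monte Carlo replicate: per-strategy discounted cost and QALYs."""

    replicate: int
    costs: dict[str, float]
    qalys: dict[str, float]
    draws: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.costs.values()):
            raise ValueError("replicate costs must be nonnegative")
        if any(q < -1e-9 for q in self.qalys.values()):
            raise ValueError("replicate QALYs must be nonnegative")


@dataclass(frozen=True)
class CEACPoint:
    """Probability each strategy is cost-effective at one WTP value."""

    wtp: float
    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, expected 1")
        if any(not 0 <= p <= 1 for p in self.probabilities.values()):
            raise ValueError("probabilities must lie in [0, 1]")


def curve_event_probability_mean(curve: SurvivalCurve) -> float:
    """Mean monthly event probability over the cycles where the curve is positive."""
    probs = [
        monthly_event_probability(curve, t)
        for t in range(curve.last_month)
        if curve.probabilities[t] > 0
    ]
    if not probs:
        raise ValueError("curve has no positive-survival cycles")
    return float(np.mean(probs))


def curve_uncertainty_specs(
    curves: dict[str, SurvivalCurve],
    sd_fraction: float = 0.2,
    kind: str = "beta",
) -> dict[str, DistributionSpec]:
    """One beta spec per curve, centred on its mean monthly event probability."""
    specs: dict[str, DistributionSpec] = {}
    for key, curve in curves.items():
        mean = curve_event_probability_mean(curve)
        if kind == "fixed" or mean <= 0:
            specs[key] = DistributionSpec(kind="fixed", mean=max(mean, 0.0))
        else:
            specs[key] = DistributionSpec(kind=kind, mean=mean, sd=sd_fraction * mean)
    return specs


def sample_parameters(
    params: ParameterSet,
    rng: np.random.Generator,
    curve_specs: dict[str, DistributionSpec] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """One joint draw: parameter values plus per-curve hazard multipliers.

    With every spec ``kind='fixed'`` the draw equals the means exactly and all
    multipliers are 1.
    """
    values = {name: params.specs[name].sample(rng) for name in sorted(params.specs)}
    multipliers: dict[str, float] = {}
    for key in sorted(curve_specs or {}):
        spec = curve_specs[key]
        if spec.kind == "fixed" or spec.mean <= 0:
            multipliers[key] = 1.0
        else:
            multipliers[key] = spec.sample(rng) / spec.mean
    return values, multipliers


def run_psa(
    inputs: model.ModelInputs,
    n_reps: int,
    seed: int,
    *,
    vary_curves: bool = True,
    perspective: str | None = None,
    extrapolation_mode: str | None = None,
    keep_draws: bool = False,
    max_failure_fraction: float = 0.01,
) -> list[PSASample]:
    """Run ``n_reps`` independent replicates under one seeded RNG stream.

    Failed replicates are recorded and excluded; more than
    ``max_failure_fraction`` of failures aborts the analysis.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be at least 1, got {n_reps}")
    params = inputs.params
    rng = np.random.default_rng(seed)
    extended = model.extend_curves(inputs, mode=extrapolation_mode)
    curve_specs = curve_uncertainty_specs(
        inputs.curves, kind="beta" if vary_curves else "fixed"
    )
    samples: list[PSASample] = []
    failures = 0
    for rep in range(n_reps):
        values, multipliers = sample_parameters(params, rng, curve_specs)
        try:
            results = model.run_pair(
                inputs,
                values=values,
                perspective=perspective,
                extended_curves=extended,
                curve_multipliers=multipliers if vary_curves else None,
            )
        except Exception as exc:  # noqa: BLE001 - counted and bounded below
            failures += 1
            log.warning("replicate %d failed: %s", rep, exc)
            if failures > max_failure_fraction * n_reps:
                raise RuntimeError(
                    f"{failures} of {rep + 1} PSA replicates failed"
                ) from exc
            continue
        samples.append(
            PSASample(
                replicate=rep,
                costs={k: r.discounted_cost for k, r in results.items()},
                qalys={k: r.discounted_qalys for k, r in results.items()},
                draws=dict(values) if keep_draws else None,
            )
        )
    summary = summarize(samples, params.intervention, params.comparator)
    log.info("PSA summary: %s", summary)
    return samples


def summarize(
    samples: list[PSASample], intervention: str, comparator: str
) -> dict[str, float]:
    """Mean cost/QALYs per strategy and the ICER of the means."""
    out: dict[str, float] = {}
    for name in (intervention, comparator):
        out[f"mean_cost_{name}"] = float(np.mean([s.costs[name] for s in samples]))
        out[f"mean_qalys_{name}"] = float(np.mean([s.qalys[name] for s in samples]))
    ratio = cea.icer(
        out[f"mean_cost_{intervention}"] - out[f"mean_cost_{comparator}"],
        out[f"mean_qalys_{intervention}"] - out[f"mean_qalys_{comparator}"],
    )
    out["icer_of_means"] = ratio if isinstance(ratio, float) else float("nan")
    return out


def ceac(
    samples: list[PSASample],
    wtp_grid: np.ndarray | list[float],
    comparator: str = "chemo",
) -> list[CEACPoint]:
    """Fraction of replicates in which each strategy has the strictly highest NMB.

    Exact NMB ties are credited to the comparator (conservative for the
    intervention).
    """
    if not samples:
        raise ValueError("ceac requires at least one PSA sample")
    wtps = np.asarray(wtp_grid, dtype=float)
    if wtps.size == 0:
        raise ValueError("ceac requires a nonempty WTP grid")
    strategies = sorted(samples[0].costs)
    if comparator not in strategies:
        raise ValueError(f"comparator {comparator!r} not among strategies {strategies}")
    costs = np.array([[s.costs[k] for k in strategies] for s in samples])
    qalys = np.array([[s.qalys[k] for k in strategies] for s in samples])
    comp_idx = strategies.index(comparator)
    points: list[CEACPoint] = []
    for wtp in wtps:
        benefit = wtp * qalys - costs  # (reps, strategies)
        best = benefit.max(axis=1, keepdims=True)
        is_best = benefit >= best - 0.0  # exact comparison; ties handled next
        tie = is_best.sum(axis=1) > 1
        winner = benefit.argmax(axis=1)
        winner[tie] = comp_idx
        probs = {
            k: float(np.mean(winner == i)) for i, k in enumerate(strategies)
        }
        points.append(CEACPoint(wtp=float(wtp), probabilities=probs))
    return points
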