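"""Survival curves on a monthly grid, transition probabilities, and extrapolation.

All transition probabilities in the cohort model derive from two curves per
arm (overall survival and progression-free survival).  Within the trial
follow-up window the curves are consumed as digitized monthly points; beyond
it they are extended either by disease-specific annual conditional survival
or by general-population life-table mortality (the cure assumption).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CurveError",
    "CoverageError",
    "SurvivalCurve",
    "ConditionalSurvivalTable",
    "LifeTable",
    "read_survival_points",
    "read_conditional_survival",
    "read_life_table",
    "monthly_event_probability",
    "split_progression_death",
    "extend_conditional",
    "extend_life_table",
    "apply_hazard_ratio",
]

_MONOTONE_TOL = 1e-9


class CurveError(ValueError):
    """Raised for malformed or degenerate survival inputs."""


class CoverageError(CurveError):
    """Raised when an extrapolation table does not cover the needed range."""


@dataclass
class SurvivalCurve:
    """Monotone nonincreasing survival function sampled at integer months.

    ``probabilities[t]`` is S(t) for month ``t``; S(0) must be 1.
    """

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise CurveError("survival curve must be a nonempty 1-D array")
        if abs(p[0] - 1.0) > _MONOTONE_TOL:
            raise CurveError(f"S(0) must equal 1, got {p[0]}")
        if np.any(p < -_MONOTONE_TOL) or np.any(p > 1 + _MONOTONE_TOL):
            raise CurveError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(p) > _MONOTONE_TOL):
            t = int(np.argmax(np.diff(p) > _MONOTONE_TOL))
            raise CurveError(f"survival increases between months {t} and {t + 1}")
        self.probabilities = np.clip(p, 0.0, 1.0)
        self.probabilities[0] = 1.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.probabilities.size)

    @property
    def last_month(self) -> int:
        return self.probabilities.size - 1

    def survival(self, t: int) -> float:
        return float(self.probabilities[t])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.times, "survival": self.probabilities})

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


@dataclass
class ConditionalSurvivalTable:
    """Annual conditional survival by year since the extrapolation boundary."""

    years: np.ndarray
    annual_conditional_survival: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.years, dtype=int)
        v = np.asarray(self.annual_conditional_survival, dtype=float)
        if y.size != v.size or y.size == 0:
            raise CurveError("conditional-survival table must be nonempty and aligned")
        if np.any(np.diff(y) != 1):
            raise CurveError("conditional-survival years must be contiguous")
        if np.any((v <= 0) | (v > 1)):
            raise CurveError("annual conditional survival must lie in (0, 1]")
        self.years, self.annual_conditional_survival = y, v

    def annual(self, year: int) -> float:
        idx = year - int(self.years[0])
        if idx < 0 or idx >= self.years.size:
            raise CoverageError(
                f"conditional-survival table does not cover year {year} "
                f"(covers {self.years[0]}..{self.years[-1]})"
            )
        return float(self.annual_conditional_survival[idx])

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"year": self.years, "annual_conditional_survival": self.annual_conditional_survival}
        ).to_csv(path, sep="\t", index=False)
        return path


@dataclass
class LifeTable:
    """Annual death probability q(x) by integer age."""

    ages: np.ndarray
    annual_death_probability: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.annual_death_probability, dtype=float)
        if a.size != q.size or a.size == 0:
            raise CurveError("life table must be nonempty and aligned")
        if np.any(np.diff(a) != 1):
            raise CurveError("life-table ages must be contiguous")
        if np.any((q <= 0) | (q >= 1)):
            raise CurveError("annual death probabilities must lie in (0, 1)")
        self.ages, self.annual_death_probability = a, q

    def q(self, age: int) -> float:
        idx = age - int(self.ages[0])
        if idx < 0 or idx >= self.ages.size:
            raise CoverageError(
                f"life table does not cover age {age} "
                f"(covers {self.ages[0]}..{self.ages[-1]})"
            )
        return float(self.annual_death_probability[idx])

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"age": self.ages, "annual_death_probability": self.annual_death_probability}
        ).to_csv(path, sep="\t", index=False)
        return path


def _read_two_columns(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CurveError(f"file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise CurveError(f"{path}: expected at least two columns")
    return df


def read_survival_points(path: str | Path) -> SurvivalCurve:
    """Read a (month, survival) file and return a curve on the integer-month grid.

    Points at non-integer months are interpolated log-linearly (exponentially),
    which preserves positive hazards between digitized points.
    """
    df = _read_two_columns(path)
    months = df.iloc[:, 0].to_numpy(dtype=float)
    surv = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(months)
    months, surv = months[order], surv[order]
    if np.any(np.diff(months) <= 0):
        raise CurveError(f"{path}: duplicate month values")
    if abs(months[0]) > 1e-9:
        raise CurveError(f"{path}: a month-0 row is required")
    for i, s in enumerate(surv):
        if not 0 <= s <= 1:
            raise CurveError(f"{path}: row {i}: survival {s} outside [0, 1]")
    if np.any(np.diff(surv) > _MONOTONE_TOL):
        i = int(np.argmax(np.diff(surv) > _MONOTONE_TOL))
        raise CurveError(f"{path}: row {i + 1}: survival increases")
    if abs(surv[0] - 1.0) > _MONOTONE_TOL:
        raise CurveError(f"{path}: row 0: S(0) must equal 1, got {surv[0]}")

    horizon = int(math.floor(months[-1] + 1e-9))
    grid = np.arange(horizon + 1, dtype=float)
    positive = surv > 0
    if positive.all():
        probs = np.exp(np.interp(grid, months, np.log(surv)))
    else:
        # zeros only allowed at the tail; grid points at/after the first zero get 0
        first_zero = int(np.argmax(~positive))
        if positive[first_zero:].any():
            raise CurveError(f"{path}: zero survival followed by positive values")
        zero_from = months[first_zero]
        probs = np.zeros_like(grid)
        head = grid < zero_from
        probs[head] = np.exp(
            np.interp(grid[head], months[:first_zero], np.log(surv[:first_zero]))
        )
    return SurvivalCurve(probs)


def read_conditional_survival(path: str | Path) -> ConditionalSurvivalTable:
    df = _read_two_columns(path)
    return ConditionalSurvivalTable(
        years=df.iloc[:, 0].to_numpy(), annual_conditional_survival=df.iloc[:, 1].to_numpy()
    )


def read_life_table(path: str | Path) -> LifeTable:
    df = _read_two_columns(path)
    return LifeTable(
        ages=df.iloc[:, 0].to_numpy(), annual_death_probability=df.iloc[:, 1].to_numpy()
    )


def monthly_event_probability(curve: SurvivalCurve, t: int) -> float:
    """Per-cycle event probability 1 - S(t+1)/S(t)."""
    s0 = curve.probabilities[t]
    s1 = curve.probabilities[t + 1]
    if s0 <= 0:
        raise CurveError(f"degenerate curve: S({t}) = 0")
    return float(1.0 - s1 / s0)


def split_progression_death(
    s_pfs: SurvivalCurve, s_os: SurvivalCurve, t: int
) -> tuple[float, float]:
    """Split the cycle-t PFS event probability into progression and death.

    Death takes the marginal OS probability; progression takes the excess of
    the PFS hazard over the OS hazard (cause-specific decomposition), floored
    at zero when digitized curves cross.  Returns ``(p_progress, p_die)``.
    """
    so0, so1 = s_os.probabilities[t], s_os.probabilities[t + 1]
    sp0, sp1 = s_pfs.probabilities[t], s_pfs.probabilities[t + 1]
    if so0 <= 0 or sp0 <= 0:
        raise CurveError(f"degenerate curve: zero survival at month {t}")
    p_die = 1.0 - so1 / so0
    if so1 <= 0:
        return 0.0, 1.0
    if sp1 <= 0:
        # PFS extinct this cycle: every non-dying stable patient progresses
        return 1.0 - p_die, p_die
    h_os = -math.log(so1 / so0)
    h_pfs = -math.log(sp1 / sp0)
    p_progress = 1.0 - math.exp(-max(0.0, h_pfs - h_os))
    return p_progress, p_die


def extend_conditional(
    curve: SurvivalCurve,
    table: ConditionalSurvivalTable,
    boundary: int = 42,
    horizon: int = 120,
) -> SurvivalCurve:
    """Extend a curve beyond ``boundary`` by compounding annual conditional survival.

    Year ``k`` of the table applies to months ``boundary + 12k .. boundary + 12k + 11``;
    each month multiplies survival by ``cs ** (1/12)``.
    """
    if curve.last_month < boundary:
        raise CurveError(
            f"curve ends at month {curve.last_month}, before boundary {boundary}"
        )
    probs = list(curve.probabilities[: boundary + 1])
    year0 = int(table.years[0])
    for t in range(boundary, horizon):
        cs = table.annual(year0 + (t - boundary) // 12)
        probs.append(probs[-1] * cs ** (1.0 / 12.0))
    return SurvivalCurve(np.asarray(probs))


def extend_life_table(
    curve: SurvivalCurve,
    lt: LifeTable,
    start_age: float,
    boundary: int = 42,
    horizon: int = 120,
) -> SurvivalCurve:
    """Extend a curve beyond ``boundary`` with general-population mortality.

    Implements the cure assumption: survivors at the boundary face only the
    age-specific annual death probability q(x), converted to a monthly
    probability ``1 - (1 - q)**(1/12)``.  Age advances deterministically from
    ``start_age`` at model entry.
    """
    if curve.last_month < boundary:
        raise CurveError(
            f"curve ends at month {curve.last_month}, before boundary {boundary}"
        )
    probs = list(curve.probabilities[: boundary + 1])
    for t in range(boundary, horizon):
        age = int(math.floor(start_age + t / 12.0))
        q = lt.q(age)
        probs.append(probs[-1] * (1.0 - q) ** (1.0 / 12.0))
    return SurvivalCurve(np.asarray(probs))


def apply_hazard_ratio(reference: SurvivalCurve, hr: float) -> SurvivalCurve:
    """Proportional-hazards transform S'(t) = S(t)**hr on the monthly grid."""
    if hr <= 0:
        raise CurveError(f"hazard ratio must be positive, got {hr}")
    return SurvivalCurve(reference.probabilities**hr)
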