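"""Percentile-based action levels at target failure rates, and the combined
GPR/ΔD tabulation.

An action level for GPR is one-sided (a plan fails when GPR < threshold); an
action level for the mean target dose difference is two-sided on |ΔD| (a plan
fails when |ΔD| > threshold). Raw percentile thresholds are rounded to a
granularity step — 5 for GPR, 0.5 for ΔD — under a configurable convention:

``nearest``
    the multiple of the step closest to the raw quantile; ties broken toward
    the lenient side (down for GPR, up for |ΔD|).
``up``
    always round toward the lenient side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, EmptyStatisticsError, ParameterError
from .gamma_engine import GammaCriterion
from .plan_metrics import PlanQAResult

__all__ = [
    "DEFAULT_Q_MENU",
    "ActionLevel",
    "CombinedTable",
    "percentile",
    "gpr_action_level",
    "dd_action_level",
    "observed_failure_rate",
    "combined_table",
]

DEFAULT_Q_MENU: tuple[float, ...] = (0.02, 0.05, 0.1, 0.2)

Rounding = Literal["nearest", "up"]
Sidedness = Literal["one_sided_lower", "two_sided_abs"]


@dataclass(frozen=True)
class ActionLevel:
    """A pass/fail threshold for one QA metric tied to a target failure rate.

    ``metric`` is either ``"dd"`` (two-sided |ΔD| in %) or a GPR criterion;
    ``raw_threshold`` keeps the unrounded quantile for diagnostics.
    """

    metric: str
    threshold: float
    q: float
    sidedness: Sidedness
    criterion: GammaCriterion | None = None
    raw_threshold: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ParameterError(f"q must be in (0, 1), got {self.q}")
        if self.sidedness == "one_sided_lower":
            if not 0 < self.threshold <= 100:
                raise ParameterError(f"GPR threshold {self.threshold} outside (0, 100]")
        elif self.threshold <= 0:
            raise ParameterError(f"|ΔD| threshold must be > 0, got {self.threshold}")

    def fails(self, result: PlanQAResult) -> bool:
        if self.sidedness == "two_sided_abs":
            return abs(result.delta_d) > self.threshold
        if self.criterion is None or self.criterion not in result.gpr:
            raise DataError(f"plan {result.plan_id} lacks GPR for {self.metric}")
        return result.gpr[self.criterion] < self.threshold


@dataclass(frozen=True)
class CombinedTable:
    """2x2 pass/fail tabulation of a cohort, in percent of plans.

    Marginals include the joint cell, so
    ``passed_both = 100 - failed_gamma - failed_dd + failed_both``.
    """

    passed_both: float
    failed_both: float
    failed_gamma: float
    failed_dd: float
    n: int

    def identity_residual(self) -> float:
        return self.passed_both - (
            100.0 - self.failed_gamma - self.failed_dd + self.failed_both
        )


def percentile(values: Sequence[float], p: float) -> float:
    """Linear-interpolation quantile with inclusive endpoints (numpy 'linear')."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise EmptyStatisticsError("cannot take a percentile of an empty list")
    if not 0 <= p <= 1:
        raise ParameterError(f"p must be in [0, 1], got {p}")
    return float(np.quantile(values, p, method="linear"))


def _round_to_step(value: float, step: float, rounding: Rounding, lenient_up: bool) -> float:
    """Round to a multiple of ``step``; 'up' means toward the lenient side."""
    ratio = value / step
    if rounding == "up":
        k = math.floor(ratio) if not lenient_up else math.ceil(ratio)
        return k * step
    lo, hi = math.floor(ratio) * step, math.ceil(ratio) * step
    d_lo, d_hi = value - lo, hi - value
    if abs(d_lo - d_hi) < 1e-12:  # tie -> lenient side
        return hi if lenient_up else lo
    return lo if d_lo < d_hi else hi


def gpr_action_level(
    gprs: Sequence[float],
    q: float,
    granularity: float = 5.0,
    rounding: Rounding = "nearest",
    criterion: GammaCriterion | None = None,
) -> ActionLevel:
    """Action level on GPR: threshold near the q-quantile, fails when below.

    Lower thresholds are lenient, so the 'up' convention rounds *down*.
    """
    if not 0 < q < 1:
        raise ParameterError(f"q must be in (0, 1), got {q}")
    raw = percentile(gprs, q)
    threshold = _round_to_step(raw, granularity, rounding, lenient_up=False)
    threshold = min(threshold, 100.0)
    if threshold <= 0:
        threshold = granularity
    metric = f"gpr({criterion.dd:g},{criterion.dta:g})" if criterion else "gpr"
    return ActionLevel(
        metric=metric,
        threshold=threshold,
        q=q,
        sidedness="one_sided_lower",
        criterion=criterion,
        raw_threshold=raw,
    )


def dd_action_level(
    dds: Sequence[float],
    q: float,
    granularity: float = 0.5,
    rounding: Rounding = "nearest",
) -> ActionLevel:
    """Action level on |ΔD|: threshold near the (1-q)-quantile of |ΔD|,
    fails when above. Higher thresholds are lenient."""
    if not 0 < q < 1:
        raise ParameterError(f"q must be in (0, 1), got {q}")
    raw = percentile(np.abs(np.asarray(dds, dtype=np.float64)), 1.0 - q)
    threshold = _round_to_step(raw, granularity, rounding, lenient_up=True)
    if threshold <= 0:
        threshold = granularity  # degenerate all-zero cohort
    return ActionLevel(
        metric="dd",
        threshold=threshold,
        q=q,
        sidedness="two_sided_abs",
        raw_threshold=raw,
    )


def observed_failure_rate(cohort: Sequence[PlanQAResult], al: ActionLevel) -> float:
    """Percentage of cohort plans failing one action level."""
    if len(cohort) == 0:
        raise EmptyStatisticsError("empty cohort")
    fails = sum(al.fails(r) for r in cohort)
    return 100.0 * fails / len(cohort)


def combined_table(
    cohort: Sequence[PlanQAResult], al_gamma: ActionLevel, al_dd: ActionLevel
) -> CombinedTable:
    """Tabulate pass/fail of the gamma and |ΔD| action levels jointly."""
    if len(cohort) == 0:
        raise EmptyStatisticsError("empty cohort")
    fg = np.array([al_gamma.fails(r) for r in cohort])
    fd = np.array([al_dd.fails(r) for r in cohort])
    n = len(cohort)
    to_pct = lambda k: 100.0 * k / n  # noqa: E731
    return CombinedTable(
        passed_both=to_pct(int((~fg & ~fd).sum())),
        failed_both=to_pct(int((fg & fd).sum())),
        failed_gamma=to_pct(int(fg.sum())),
        failed_dd=to_pct(int(fd.sum())),
        n=n,
    )


def action_level_frame(levels: Iterable[ActionLevel]) -> pd.DataFrame:
    """Action-level report table (metric, q, threshold, raw quantile)."""
    rows = [
        {
            "metric": al.metric,
            "q": al.q,
            "threshold": al.threshold,
            "raw_quantile": al.raw_threshold,
            "sidedness": al.sidedness,
        }
        for al in levels
    ]
    if not rows:
        raise DataError("no action levels to tabulate")
    return pd.DataFrame(rows)
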