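"""Per-plan QA metrics: mean target dose difference and the GPR bundle."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dose_model import DoseGrid, StructureMask, resample_onto
from .errors import DataError, DegenerateTargetError, GeometryError
from .gamma_engine import GammaCriterion, gamma_map, gamma_pass_rate

__all__ = [
    "DEFAULT_CRITERIA",
    "PlanQAResult",
    "mean_target_dose_diff",
    "evaluate_plan",
    "results_to_frame",
    "frame_to_results",
    "write_results_csv",
    "read_results_csv",
]

#: the four study criteria, ordered lenient -> strict
DEFAULT_CRITERIA: tuple[GammaCriterion, ...] = (
    GammaCriterion(5, 3),
    GammaCriterion(3, 3),
    GammaCriterion(2, 2),
    GammaCriterion(2, 1),
)


@dataclass(frozen=True)
class PlanQAResult:
    """One plan's QA outcome: GPR per criterion plus the signed ΔD in %."""

    plan_id: str
    gpr: dict[GammaCriterion, float]
    delta_d: float
    case_class: str = ""
    technique: str = ""

    def __post_init__(self) -> None:
        for crit, value in self.gpr.items():
            if not 0 <= value <= 100:
                raise DataError(f"GPR {value} for {crit} outside [0, 100]")
        if not np.isfinite(self.delta_d):
            raise DataError(f"delta_d must be finite, got {self.delta_d}")


def mean_target_dose_diff(
    ref: DoseGrid, eval_grid: DoseGrid, target: StructureMask
) -> float:
    """Signed relative difference (%) of mean target dose, eval vs reference.

    Positive values mean the evaluated dose is higher. Both grids must be on
    the target's geometry; resample first if they are not.
    """
    if target.geometry != ref.geometry or target.geometry != eval_grid.geometry:
        raise GeometryError("grids and target mask must share one geometry")
    if target.count() == 0:
        raise DegenerateTargetError("target mask is empty")
    mean_ref = float(ref.values[target.values].mean())
    mean_eval = float(eval_grid.values[target.values].mean())
    if mean_ref <= 0:
        raise DegenerateTargetError("reference mean target dose is non-positive")
    return 100.0 * (mean_eval - mean_ref) / mean_ref


def evaluate_plan(
    ref: DoseGrid,
    eval_grid: DoseGrid,
    target: StructureMask,
    criteria: Sequence[GammaCriterion] = DEFAULT_CRITERIA,
    *,
    plan_id: str = "plan",
    case_class: str = "",
    technique: str = "",
    interpolate: bool = True,
) -> PlanQAResult:
    """Bundle GPR at each criterion with ΔD for one plan.

    The gamma engine interpolates the evaluated grid on its native geometry;
    for ΔD the evaluated grid is resampled onto the reference geometry (where
    the target mask lives) first.
    """
    if target.geometry != ref.geometry:
        raise GeometryError("target mask must live on the reference geometry")
    if eval_grid.geometry == ref.geometry:
        eval_on_ref = eval_grid
    else:
        eval_on_ref, oos = resample_onto(eval_grid, ref.geometry)
        if np.any(oos[target.values]):
            raise GeometryError("target extends outside the evaluated grid support")
    gpr = {
        crit: gamma_pass_rate(gamma_map(ref, eval_grid, crit, interpolate=interpolate))
        for crit in criteria
    }
    delta_d = mean_target_dose_diff(ref, eval_on_ref, target)
    return PlanQAResult(
        plan_id=plan_id,
        gpr=gpr,
        delta_d=delta_d,
        case_class=case_class,
        technique=technique,
    )


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def _column(crit: GammaCriterion) -> str:
    return f"gpr_{crit.dd:g}_{crit.dta:g}"


def _criterion_from_column(name: str) -> GammaCriterion:
    _, dd, dta = name.split("_")
    return GammaCriterion(float(dd), float(dta))


def results_to_frame(results: Iterable[PlanQAResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict[str, object] = {
            "plan_id": r.plan_id,
            "case_class": r.case_class,
            "technique": r.technique,
            "delta_d": r.delta_d,
        }
        for crit, value in r.gpr.items():
            row[_column(crit)] = value
        rows.append(row)
    if not rows:
        raise DataError("no plan results to tabulate")
    return pd.DataFrame(rows)


def frame_to_results(frame: pd.DataFrame) -> list[PlanQAResult]:
    gpr_cols = [c for c in frame.columns if c.startswith("gpr_")]
    if "delta_d" not in frame.columns or not gpr_cols:
        raise DataError("results frame needs delta_d and gpr_* columns")
    criteria = {c: _criterion_from_column(c) for c in gpr_cols}
    out = []
    for _, row in frame.iterrows():
        out.append(
            PlanQAResult(
                plan_id=str(row["plan_id"]),
                case_class=str(row.get("case_class", "")),
                technique=str(row.get("technique", "")),
                delta_d=float(row["delta_d"]),
                gpr={criteria[c]: float(row[c]) for c in gpr_cols},
            )
        )
    return out


def write_results_csv(results: Iterable[PlanQAResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False, float_format="%.6f")


def read_results_csv(path: str | Path) -> list[PlanQAResult]:
    return frame_to_results(pd.read_csv(path))
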