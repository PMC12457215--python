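"""End-to-end study orchestration: cohort -> metrics -> action levels ->
combined tables -> TG-218 comparison."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .action_levels import (
    DEFAULT_Q_MENU,
    ActionLevel,
    Rounding,
    action_level_frame,
    combined_table,
    dd_action_level,
    gpr_action_level,
    observed_failure_rate,
)
from .dose_model import read_mask_nrrd, read_nrrd
from .errors import ConfigurationError
from .gamma_engine import GammaCriterion
from .plan_metrics import (
    DEFAULT_CRITERIA,
    PlanQAResult,
    evaluate_plan,
    read_results_csv,
    results_to_frame,
)
from .synthetic_cohort import CohortSimConfig, sample_result_cohort
from .tg218_stats import beta_half_from_q, binomial_se, expected_fail_rate

logger = logging.getLogger("doseqa")

__all__ = ["StudyConfig", "StudyReport", "run_study", "evaluate_plan_directory"]


class FixedActionLevel(BaseModel):
    """A user-imposed action level, e.g. GPR(3,3) >= 90 or |ΔD| <= 4.5."""

    metric: str  # "dd" or "gpr"
    threshold: float
    dd: Optional[float] = None
    dta: Optional[float] = None


class StudyConfig(BaseModel):
    """Declarative study description consumed by :func:`run_study`.

    Exactly one of ``cohort`` (result-level simulation), ``results_csv``
    (precomputed per-plan metrics) or ``plan_dir`` (directory of voxel-level
    plan folders with ref.nrrd / eval.nrrd / mask.nrrd) must be given.
    """

    cohort: Optional[CohortSimConfig] = None
    results_csv: Optional[str] = None
    plan_dir: Optional[str] = None
    criteria: list[tuple[float, float]] = Field(
        default_factory=lambda: [(c.dd, c.dta) for c in DEFAULT_CRITERIA]
    )
    q_menu: list[float] = Field(default_factory=lambda: list(DEFAULT_Q_MENU))
    rounding: Rounding = "nearest"
    fixed_levels: list[FixedActionLevel] = Field(default_factory=list)
    seed: int = 0

    def criterion_objects(self) -> list[GammaCriterion]:
        return [GammaCriterion(dd, dta) for dd, dta in self.criteria]


@dataclass
class StudyReport:
    """All study outputs plus provenance; writable as a CSV bundle."""

    results: pd.DataFrame
    action_levels: pd.DataFrame
    combined: pd.DataFrame
    tg218: pd.DataFrame
    provenance: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(outdir / "plan_results.csv", index=False, float_format="%.6f")
        self.action_levels.to_csv(outdir / "action_levels.csv", index=False, float_format="%.6f")
        self.combined.to_csv(outdir / "combined_tables.csv", index=False, float_format="%.6f")
        self.tg218.to_csv(outdir / "tg218_report.csv", index=False, float_format="%.6f")
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)


def evaluate_plan_directory(
    plan_dir: str | Path,
    criteria: Sequence[GammaCriterion],
    interpolate: bool = True,
) -> list[PlanQAResult]:
    """Evaluate every plan folder (ref.nrrd, eval.nrrd, mask.nrrd) found
    directly under ``plan_dir``, sorted by folder name."""
    plan_dir = Path(plan_dir)
    folders = sorted(p for p in plan_dir.iterdir() if p.is_dir())
    if not folders:
        raise ConfigurationError(f"no plan folders under {plan_dir}")
    results = []
    for folder in folders:
        t0 = time.perf_counter()
        ref = read_nrrd(folder / "ref.nrrd")
        eval_grid = read_nrrd(folder / "eval.nrrd")
        mask = read_mask_nrrd(folder / "mask.nrrd")
        result = evaluate_plan(
            ref, eval_grid, mask, criteria, plan_id=folder.name, interpolate=interpolate
        )
        logger.info(
            "plan %s: delta_d=%.3f%% gpr=%s (%.2fs)",
            folder.name,
            result.delta_d,
            {str(k): round(v, 2) for k, v in result.gpr.items()},
            time.perf_counter() - t0,
        )
        results.append(result)
    return results


def _load_cohort(config: StudyConfig) -> list[PlanQAResult]:
    sources = [config.cohort, config.results_csv, config.plan_dir]
    if sum(s is not None for s in sources) != 1:
        raise ConfigurationError(
            "exactly one of cohort, results_csv or plan_dir must be configured"
        )
    if config.cohort is not None:
        return sample_result_cohort(config.cohort, seed=config.seed)
    if config.results_csv is not None:
        return read_results_csv(config.results_csv)
    return evaluate_plan_directory(config.plan_dir, config.criterion_objects())


def _tg218_row(metric: str, q: float | None, threshold: float, values: np.ndarray,
               sidedness: str, n: int) -> dict:
    mean, sd = float(values.mean()), float(values.std(ddof=1))
    expected = expected_fail_rate(mean, sd, threshold, sidedness)
    return {
        "metric": metric,
        "q": q,
        "threshold": threshold,
        "cohort_mean": mean,
        "cohort_sd": sd,
        "beta_half": beta_half_from_q(q, sidedness) if q is not None else None,
        "expected_fail_pct": expected,
        "binomial_se_pct": binomial_se(expected / 100.0, n),
        "sidedness": sidedness,
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full analysis on one cohort; deterministic given (config, seed)."""
    cohort = _load_cohort(config)
    n = len(cohort)
    criteria = config.criterion_objects()
    results_frame = results_to_frame(cohort)
    dds = np.array([r.delta_d for r in cohort])

    # --- percentile action levels at every q, per metric -------------------
    levels: list[ActionLevel] = []
    for q in config.q_menu:
        for crit in criteria:
            gprs = [r.gpr[crit] for r in cohort]
            levels.append(
                gpr_action_level(gprs, q, rounding=config.rounding, criterion=crit)
            )
        levels.append(dd_action_level(dds, q, rounding=config.rounding))
    al_frame = action_level_frame(levels)
    al_frame["observed_fail_pct"] = [
        observed_failure_rate(cohort, al) for al in levels
    ]

    # --- combined tables: derived pairs per q plus any fixed levels --------
    combined_rows = []
    tg218_rows = []
    for q in config.q_menu:
        al_dd = next(l for l in levels if l.metric == "dd" and l.q == q)
        for crit in criteria:
            al_g = next(
                l for l in levels if l.criterion == crit and l.q == q
            )
            table = combined_table(cohort, al_g, al_dd)
            combined_rows.append(
                {
                    "source": "derived",
                    "q": q,
                    "gamma_metric": al_g.metric,
                    "gamma_threshold": al_g.threshold,
                    "dd_threshold": al_dd.threshold,
                    "passed_both": table.passed_both,
                    "failed_both": table.failed_both,
                    "failed_gamma": table.failed_gamma,
                    "failed_dd": table.failed_dd,
                }
            )
        gpr_values = {crit: np.array([r.gpr[crit] for r in cohort]) for crit in criteria}
        for crit in criteria:
            al_g = next(l for l in levels if l.criterion == crit and l.q == q)
            tg218_rows.append(
                _tg218_row(al_g.metric, q, al_g.threshold, gpr_values[crit], "one_sided", n)
            )
        tg218_rows.append(_tg218_row("dd", q, al_dd.threshold, dds, "two_sided", n))

    fixed_gamma = [f for f in config.fixed_levels if f.metric == "gpr"]
    fixed_dd = [f for f in config.fixed_levels if f.metric == "dd"]
    for fg in fixed_gamma:
        crit = GammaCriterion(fg.dd, fg.dta)
        al_g = ActionLevel(
            metric=f"gpr({crit.dd:g},{crit.dta:g})",
            threshold=fg.threshold,
            q=0.5,  # placeholder; fixed levels carry no target q
            sidedness="one_sided_lower",
            criterion=crit,
        )
        gpr_values = np.array([r.gpr[crit] for r in cohort])
        tg218_rows.append(_tg218_row(al_g.metric, None, fg.threshold, gpr_values, "one_sided", n))
        for fd in fixed_dd:
            al_d = ActionLevel(
                metric="dd", threshold=fd.threshold, q=0.5, sidedness="two_sided_abs"
            )
            table = combined_table(cohort, al_g, al_d)
            combined_rows.append(
                {
                    "source": "fixed",
                    "q": None,
                    "gamma_metric": al_g.metric,
                    "gamma_threshold": fg.threshold,
                    "dd_threshold": fd.threshold,
                    "passed_both": table.passed_both,
                    "failed_both": table.failed_both,
                    "failed_gamma": table.failed_gamma,
                    "failed_dd": table.failed_dd,
                }
            )
    for fd in fixed_dd:
        tg218_rows.append(_tg218_row("dd", None, fd.threshold, dds, "two_sided", n))

    config_json = config.model_dump_json()
    provenance = {
        "seed": config.seed,
        "n_plans": n,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "version": __version__,
    }
    return StudyReport(
        results=results_frame,
        action_levels=al_frame,
        combined=pd.DataFrame(combined_rows),
        tg218=pd.DataFrame(tg218_rows),
        provenance=provenance,
    )
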