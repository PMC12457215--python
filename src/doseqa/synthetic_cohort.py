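"""Synthetic paired dose distributions and result-level QA cohorts.

Two generator tiers stand in for the clinical cohort this kind of study runs
on:

* a *voxel tier* producing paired reference/evaluated :class:`DoseGrid`
  objects with controllable systematic scale error, smooth local
  perturbations, rigid shifts and calibrated Monte-Carlo-like voxel noise —
  used to exercise the gamma/ΔD mechanics; and
* a *result tier* sampling :class:`PlanQAResult` records directly from the
  cohort-level distributions (Gaussian ΔD per flavor, right-clipped latent
  Gaussian GPR per criterion) — used for action-level and TG-218 statistics
  at scale.

Every stochastic operation derives one RNG stream per plan from
``(master seed, plan index)`` so cohorts are reproducible regardless of
evaluation order.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.ndimage import distance_transform_edt, gaussian_filter, shift as nd_shift

from .dose_model import DoseGrid, GridGeometry, StructureMask, fractional_mask
from .errors import GeometryError, ParameterError
from .gamma_engine import GammaCriterion
from .plan_metrics import DEFAULT_CRITERIA, PlanQAResult

__all__ = [
    "PlanSimConfig",
    "CohortSimConfig",
    "FLAVOR_DEFAULTS",
    "make_reference_plan",
    "perturb",
    "make_plan_pair",
    "sample_result_cohort",
]


class PlanSimConfig(BaseModel):
    """Configuration of one synthetic plan pair (voxel tier)."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    target_center_mm: Optional[tuple[float, float, float]] = None  # None -> grid center
    target_radii_mm: tuple[float, float, float] = (30.0, 25.0, 20.0)
    prescription_gy: float = Field(60.0, gt=0)
    falloff_mm: float = Field(15.0, gt=0)
    # systematic scale error s (%) drawn per plan from N(sys_mu, sys_sigma)
    sys_mu: float = 0.0
    sys_sigma: float = Field(0.0, ge=0)
    local_amp_pct: float = Field(0.0, ge=0)
    local_corr_mm: float = Field(10.0, gt=0)
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mc_noise_rel_sd_pct: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "PlanSimConfig":
        if any(n <= 0 for n in self.shape):
            raise ValueError("shape must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if any(r <= 0 for r in self.target_radii_mm):
            raise ValueError("target radii must be positive")
        return self

    def geometry(self) -> GridGeometry:
        return GridGeometry((0.0, 0.0, 0.0), self.spacing_mm, self.shape)


#: cohort-level defaults per ISDC flavor: ΔD mean/SD plus latent GPR
#: (mean, SD) per criterion, ordered lenient -> strict. ΔD numbers follow the
#: study cohort; GPR numbers are plausible-range defaults and config-exposed.
FLAVOR_DEFAULTS: dict[str, dict] = {
    "m3d": {
        "delta_d": (1.75, 2.41),
        "gpr": {(5, 3): (99.4, 0.7), (3, 3): (96.5, 3.2), (2, 2): (88.0, 7.0), (2, 1): (76.0, 11.0)},
    },
    "smcgen": {
        "delta_d": (-0.17, 1.03),
        "gpr": {(5, 3): (99.9, 0.25), (3, 3): (99.2, 1.1), (2, 2): (97.4, 1.9), (2, 1): (94.6, 3.0)},
    },
    "smccbm": {
        "delta_d": (-0.11, 0.78),
        "gpr": {(5, 3): (99.9, 0.2), (3, 3): (99.5, 0.8), (2, 2): (98.0, 1.4), (2, 1): (96.0, 2.0)},
    },
}


class CohortSimConfig(BaseModel):
    """Configuration of a result-level cohort (result tier)."""

    flavor: str = "m3d"
    n_case_classes: int = Field(20, ge=1)
    plans_per_class: int = Field(5, ge=1)
    delta_d_mu: Optional[float] = None  # None -> flavor default
    delta_d_sigma: Optional[float] = Field(None, gt=0)
    gpr_params: Optional[dict[tuple[float, float], tuple[float, float]]] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSimConfig":
        if self.flavor not in FLAVOR_DEFAULTS and (
            self.delta_d_mu is None or self.delta_d_sigma is None or self.gpr_params is None
        ):
            raise ValueError(
                f"unknown flavor {self.flavor!r}: supply delta_d_mu/sigma and gpr_params"
            )
        return self

    @property
    def n_plans(self) -> int:
        return self.n_case_classes * self.plans_per_class

    def resolved_delta_d(self) -> tuple[float, float]:
        default = FLAVOR_DEFAULTS.get(self.flavor, {}).get("delta_d", (None, None))
        mu = self.delta_d_mu if self.delta_d_mu is not None else default[0]
        sigma = self.delta_d_sigma if self.delta_d_sigma is not None else default[1]
        return float(mu), float(sigma)

    def resolved_gpr(self) -> dict[GammaCriterion, tuple[float, float]]:
        raw = self.gpr_params or FLAVOR_DEFAULTS[self.flavor]["gpr"]
        out = {}
        for key, (mu, sd) in raw.items():
            dd, dta = key
            out[GammaCriterion(float(dd), float(dta))] = (float(mu), float(sd))
        return out


def _plan_rng(seed: int, plan_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(plan_index)]))


def make_reference_plan(cfg: PlanSimConfig, seed: int = 0) -> tuple[DoseGrid, StructureMask]:
    """Build the reference dose: prescription inside an ellipsoidal target,
    exponential falloff with distance outside. Deterministic given ``cfg``."""
    geom = cfg.geometry()
    center = (
        np.asarray(cfg.target_center_mm)
        if cfg.target_center_mm is not None
        else np.array([geom.voxel_centers(a).mean() for a in range(3)])
    )
    radii = np.asarray(cfg.target_radii_mm)
    extent_lo = np.asarray(geom.origin)
    extent_hi = extent_lo + (np.asarray(geom.shape) - 1) * np.asarray(geom.spacing)
    if np.any(center - radii < extent_lo) or np.any(center + radii > extent_hi):
        raise GeometryError("target ellipsoid extends outside the grid")

    axes = [geom.voxel_centers(a) for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    inside = (
        ((xx - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((zz - center[2]) / radii[2]) ** 2
    ) <= 1.0
    # physical distance (mm) from each outside voxel to the nearest target voxel
    dist = distance_transform_edt(~inside, sampling=geom.spacing)
    dose = cfg.prescription_gy * np.exp(-dist / cfg.falloff_mm)
    dose[inside] = cfg.prescription_gy
    return DoseGrid(dose, geom), StructureMask(inside, geom, role="target")


def perturb(ref: DoseGrid, cfg: PlanSimConfig, seed: int = 0) -> DoseGrid:
    """Derive an evaluated grid from the reference:

        eval = shift(ref) * (1 + s/100) * (1 + f/100) + noise

    with ``s ~ N(sys_mu, sys_sigma)`` per plan, ``f`` a Gaussian-correlated
    random field of SD ``local_amp_pct`` and correlation length
    ``local_corr_mm``, and voxel noise of relative SD ``mc_noise_rel_sd_pct``
    (exact, by construction, inside the >=70%-of-max region used for
    calibration checks). Negative doses arising from noise are clipped to 0.
    """
    rng = _plan_rng(seed, 0)
    values = ref.values
    if any(abs(s) > 0 for s in cfg.shift_mm):
        # positive shift moves the dose pattern toward the positive axis
        shift_vox = [cfg.shift_mm[a] / ref.spacing[a] for a in range(3)]
        values = nd_shift(values, shift_vox, order=1, mode="nearest")

    s = rng.normal(cfg.sys_mu, cfg.sys_sigma) if cfg.sys_sigma > 0 else cfg.sys_mu
    values = values * (1.0 + s / 100.0)

    if cfg.local_amp_pct > 0:
        white = rng.standard_normal(ref.shape)
        sigma_vox = [cfg.local_corr_mm / sp for sp in ref.spacing]
        f = gaussian_filter(white, sigma_vox)
        f *= cfg.local_amp_pct / max(f.std(), 1e-12)
        values = values * (1.0 + f / 100.0)

    if cfg.mc_noise_rel_sd_pct > 0:
        # proportional noise: relative SD is the configured value everywhere,
        # in particular inside the >=70% calibration region (fractional_mask)
        fractional_mask(ref, 0.7)  # raises on degenerate grids
        noise = values * (cfg.mc_noise_rel_sd_pct / 100.0) * rng.standard_normal(ref.shape)
        values = values + noise

    return DoseGrid(np.clip(values, 0.0, None), ref.geometry)


def make_plan_pair(
    cfg: PlanSimConfig, seed: int = 0
) -> tuple[DoseGrid, DoseGrid, StructureMask]:
    """Convenience: (reference, evaluated, target mask) for one plan."""
    ref, mask = make_reference_plan(cfg, seed)
    return ref, perturb(ref, cfg, seed), mask


def sample_result_cohort(cfg: CohortSimConfig, seed: int | None = None) -> list[PlanQAResult]:
    """Sample a result-level cohort of ``n_case_classes * plans_per_class``
    plans.

    ΔD is Gaussian per flavor. GPRs share one latent standard-normal draw per
    plan (plus small idiosyncratic jitter), are clipped at 100, and the
    monotone criterion ordering (lenient >= strict) is enforced by a running
    maximum from the strictest criterion upward.
    """
    master = cfg.seed if seed is None else seed
    dd_mu, dd_sigma = cfg.resolved_delta_d()
    gpr_params = cfg.resolved_gpr()
    # order strict -> lenient by (dd, dta): smaller tolerances are stricter
    ordered = sorted(gpr_params, key=lambda c: (c.dd, c.dta))
    results = []
    for i in range(cfg.n_plans):
        rng = _plan_rng(master, i)
        z = rng.standard_normal()
        delta_d = rng.normal(dd_mu, dd_sigma)
        gpr: dict[GammaCriterion, float] = {}
        running = -np.inf
        for crit in ordered:
            mu, sd = gpr_params[crit]
            raw = mu + sd * (0.9 * z + 0.436 * rng.standard_normal())
            running = max(running, raw)
            gpr[crit] = float(np.clip(running, 0.0, 100.0))
        results.append(
            PlanQAResult(
                plan_id=f"plan{i:03d}",
                case_class=f"class{i // cfg.plans_per_class:02d}",
                technique="synthetic",
                gpr=gpr,
                delta_d=float(delta_d),
            )
        )
    return results
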