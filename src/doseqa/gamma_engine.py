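"""Global 3D gamma-index computation.

The optimized engine (:func:`gamma_map`) minimizes the gamma functional over a
sub-voxel search lattice with an expanding-shell early-exit bound; the
exhaustive oracle (:func:`brute_force_gamma`) minimizes over all evaluated
voxel centers with no shortcuts and exists to validate the engine.

Normalization is *global*: the dose-difference denominator and the low-dose
exclusion are both taken relative to the maximum of the reference grid unless
an explicit normalization dose is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .dose_model import DoseGrid
from .errors import (
    EmptyGridError,
    EmptyStatisticsError,
    GeometryError,
    ParameterError,
    SizeError,
)

__all__ = ["GammaCriterion", "GammaMap", "gamma_map", "brute_force_gamma", "gamma_pass_rate"]

#: gamma values are capped here; irrelevant to the pass rate (cap > 1) but
#: bounds the search radius at cap * DTA.
DEFAULT_CAP = 2.0

#: sentinel stored outside the evaluated mask
GAMMA_SENTINEL = np.nan


@dataclass(frozen=True)
class GammaCriterion:
    """A (DD, DTA, low-dose threshold) gamma acceptance criterion.

    ``dd`` is the dose-difference tolerance in percent of the global
    normalization dose; ``dta`` the distance-to-agreement tolerance in mm;
    ``low_dose_threshold`` the proportion of the reference maximum below
    which reference voxels are excluded from the statistics.
    """

    dd: float
    dta: float
    low_dose_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.dd <= 0:
            raise ParameterError(f"dd must be > 0, got {self.dd}")
        if self.dta <= 0:
            raise ParameterError(f"dta must be > 0, got {self.dta}")
        if not 0 <= self.low_dose_threshold < 1:
            raise ParameterError(
                f"low_dose_threshold must be in [0, 1), got {self.low_dose_threshold}"
            )

    @property
    def label(self) -> str:
        return f"gpr_{self.dd:g}_{self.dta:g}".replace(".", "p")

    def __str__(self) -> str:
        return f"({self.dd:g}%, {self.dta:g} mm)"


@dataclass(frozen=True)
class GammaMap:
    """Per-voxel gamma values on the reference grid plus the evaluated mask."""

    values: np.ndarray
    evaluated_mask: np.ndarray
    criterion: GammaCriterion
    cap: float = DEFAULT_CAP

    def included_values(self) -> np.ndarray:
        return self.values[self.evaluated_mask]


def _included_reference(ref: DoseGrid, crit: GammaCriterion, normalization: float | None):
    norm = float(normalization) if normalization is not None else ref.max()
    if norm <= 0:
        raise EmptyGridError("reference grid has non-positive maximum")
    include = ref.values >= crit.low_dose_threshold * ref.max()
    return norm, include


def _grid_points(grid: DoseGrid, mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask).astype(np.float64)
    return grid.geometry.origin + idx * grid.geometry.spacing


def _search_offsets(
    crit: GammaCriterion,
    cap: float,
    step_ratio: int,
    interpolate: bool,
    eval_spacing: tuple[float, float, float] | None,
) -> np.ndarray:
    """Candidate displacement vectors sorted by length.

    With interpolation: a cubic lattice of pitch dta/step_ratio out to the
    radius cap*dta beyond which the distance term alone exceeds the cap.
    Voxel-pitch offsets of the evaluated grid (when supplied) are appended so
    that every oracle candidate is also an engine candidate.
    """
    r_max = cap * crit.dta
    lattices = []
    if interpolate:
        step = crit.dta / step_ratio
        n = int(np.floor(r_max / step))
        ax = step * np.arange(-n, n + 1)
        lattices.append(np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3))
    if eval_spacing is not None:
        axes = [sp * np.arange(-int(np.floor(r_max / sp)), int(np.floor(r_max / sp)) + 1)
                for sp in eval_spacing]
        lattices.append(
            np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
        )
    offsets = np.concatenate(lattices, axis=0)
    dist = np.linalg.norm(offsets, axis=1)
    keep = dist <= r_max + 1e-12
    offsets, dist = offsets[keep], dist[keep]
    order = np.argsort(dist, kind="stable")
    return offsets[order]


def gamma_map(
    ref: DoseGrid,
    eval_grid: DoseGrid,
    crit: GammaCriterion,
    *,
    interpolate: bool = True,
    step_ratio: int = 10,
    cap: float = DEFAULT_CAP,
    normalization: float | None = None,
    chunk: int = 32,
) -> GammaMap:
    """Compute the global gamma index of ``eval_grid`` against ``ref``.

    Gamma is evaluated at every reference voxel at or above the low-dose
    threshold. The evaluated dose is sampled by trilinear interpolation on
    its native grid; candidate positions outside the evaluated grid's support
    are skipped. With ``interpolate=False`` only evaluated voxel centers are
    candidates, which requires both grids to share one geometry (this mode
    exists to compare against :func:`brute_force_gamma`).
    """
    same_geometry = ref.geometry == eval_grid.geometry
    if not interpolate and not same_geometry:
        raise GeometryError("interpolate=False requires ref and eval on one geometry")

    norm, include = _included_reference(ref, crit, normalization)
    if not include.any():
        raise EmptyStatisticsError("no reference voxels above the low-dose threshold")

    points = _grid_points(ref, include)  # (N, 3) physical mm
    ref_dose = ref.values[include]
    n = points.shape[0]

    offsets = _search_offsets(
        crit,
        cap,
        step_ratio,
        interpolate,
        eval_grid.geometry.spacing if same_geometry else None,
    )
    dist = np.linalg.norm(offsets, axis=1)

    origin = np.asarray(eval_grid.geometry.origin)
    spacing = np.asarray(eval_grid.geometry.spacing)
    upper = np.asarray(eval_grid.shape, dtype=np.float64) - 1.0
    dd_abs = crit.dd / 100.0 * norm

    gamma2 = np.full(n, cap * cap, dtype=np.float64)
    any_valid = np.zeros(n, dtype=bool)
    active = np.arange(n)

    pos = 0
    while pos < len(offsets) and active.size:
        hi = min(pos + chunk, len(offsets))
        d_lo = dist[pos]
        # a point whose best gamma already beats the pure distance term of
        # every remaining offset can never improve
        keep = gamma2[active] > (d_lo / crit.dta) ** 2
        active = active[keep]
        if not active.size:
            break
        off = offsets[pos:hi]
        cand = points[active][:, None, :] + off[None, :, :]  # (na, c, 3)
        frac = (cand - origin) / spacing
        # tolerance guards voxel-center candidates against float round-off
        inside = np.all((frac >= -1e-9) & (frac <= upper + 1e-9), axis=2)
        vals = np.full(frac.shape[:2], np.nan)
        if inside.any():
            coords = np.clip(frac[inside], 0.0, upper).T
            vals[inside] = map_coordinates(eval_grid.values, coords, order=1)
        diff2 = ((vals - ref_dose[active][:, None]) / dd_abs) ** 2
        g2 = diff2 + (dist[pos:hi][None, :] / crit.dta) ** 2
        valid = np.isfinite(g2)
        g2 = np.where(valid, g2, np.inf)
        best = g2.min(axis=1)
        any_valid[active] |= valid.any(axis=1)
        gamma2[active] = np.minimum(gamma2[active], best)
        pos = hi

    values = np.full(ref.shape, GAMMA_SENTINEL)
    gamma = np.minimum(np.sqrt(gamma2), cap)
    gamma[~any_valid] = GAMMA_SENTINEL
    values[include] = gamma
    evaluated = include.copy()
    evaluated[include] = any_valid
    return GammaMap(values, evaluated, crit, cap=cap)


def brute_force_gamma(
    ref: DoseGrid,
    eval_grid: DoseGrid,
    crit: GammaCriterion,
    *,
    cap: float = DEFAULT_CAP,
    normalization: float | None = None,
    max_voxels: int = 25**3,
) -> GammaMap:
    """Exhaustive gamma oracle: minimize over *all* evaluated voxel centers.

    No interpolation, no search-radius bound — only the final cap is applied.
    Restricted to small grids; use :func:`gamma_map` for production work.
    """
    for g in (ref, eval_grid):
        if int(np.prod(g.shape)) > max_voxels:
            raise SizeError(f"brute-force oracle limited to {max_voxels} voxels per grid")

    norm, include = _included_reference(ref, crit, normalization)
    if not include.any():
        raise EmptyStatisticsError("no reference voxels above the low-dose threshold")

    ref_points = _grid_points(ref, include)
    ref_dose = ref.values[include]
    eval_points = _grid_points(eval_grid, np.ones(eval_grid.shape, dtype=bool))
    eval_dose = eval_grid.values.ravel()
    dd_abs = crit.dd / 100.0 * norm

    gamma = np.empty(ref_points.shape[0])
    step = max(1, int(2e7 // max(eval_points.shape[0], 1)))
    for lo in range(0, ref_points.shape[0], step):
        hi = lo + step
        d2 = ((ref_points[lo:hi, None, :] - eval_points[None, :, :]) ** 2).sum(-1)
        dd2 = ((eval_dose[None, :] - ref_dose[lo:hi, None]) / dd_abs) ** 2
        g2 = d2 / crit.dta**2 + dd2
        gamma[lo:hi] = np.sqrt(g2.min(axis=1))

    values = np.full(ref.shape, GAMMA_SENTINEL)
    values[include] = np.minimum(gamma, cap)
    return GammaMap(values, include, crit, cap=cap)


def gamma_pass_rate(gmap: GammaMap) -> float:
    """Percentage of evaluated voxels with gamma strictly below 1."""
    included = gmap.included_values()
    if included.size == 0:
        raise EmptyStatisticsError("gamma map has no evaluated voxels")
    return 100.0 * float(np.count_nonzero(included < 1.0)) / included.size
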