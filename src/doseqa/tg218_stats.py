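"""TG-218 action-interval formalism and related Gaussian/truncated statistics.

The action interval around a QA target value ``T`` is

    2A = beta * sqrt(sigma^2 + (mean - T)^2)

with action levels ``T - A`` and ``T + A`` (only ``T - A`` is meaningful for a
one-sided metric such as GPR). ``beta/2`` and the nominal failure rate ``q``
are interconvertible through the standard normal distribution; for GPR the
sample distribution is right-truncated at 100 and the Gaussian conversion
breaks down near the bound, which :func:`truncation_beta_correction`
quantifies by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .errors import ParameterError

__all__ = [
    "TG218Params",
    "action_interval",
    "beta_half_from_q",
    "q_from_beta_half",
    "expected_fail_rate",
    "binomial_se",
    "clipped_normal_moments",
    "match_clipped_normal",
    "sample_clipped_gpr",
    "truncation_beta_correction",
]

Sidedness = Literal["one_sided", "two_sided"]


@dataclass(frozen=True)
class TG218Params:
    """Symbols of the action-interval formula: target T, observed mean and SD,
    and the dimensionless multiplier beta."""

    target: float
    mean: float
    sd: float
    beta: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ParameterError(f"sd must be >= 0, got {self.sd}")
        if self.beta <= 0:
            raise ParameterError(f"beta must be > 0, got {self.beta}")


def action_interval(p: TG218Params) -> tuple[float, float]:
    """Return (T - A, T + A) with A = (beta/2) * sqrt(sd^2 + (mean - T)^2).

    One-sided metrics use only the lower bound.
    """
    half_width = 0.5 * p.beta * float(np.hypot(p.sd, p.mean - p.target))
    return (p.target - half_width, p.target + half_width)


def beta_half_from_q(q: float, sidedness: Sidedness) -> float:
    """beta/2 such that a Gaussian QA process fails at rate q.

    One-sided: solve 1 - Phi(z) = q. Two-sided: solve 2(1 - Phi(z)) = q.
    """
    if not 0 < q < 1:
        raise ParameterError(f"q must be in (0, 1), got {q}")
    if sidedness == "one_sided":
        return float(norm.isf(q))
    if sidedness == "two_sided":
        return float(norm.isf(q / 2.0))
    raise ParameterError(f"unknown sidedness {sidedness!r}")


def q_from_beta_half(b: float, sidedness: Sidedness) -> float:
    """Exact inverse of :func:`beta_half_from_q`."""
    if b < 0:
        raise ParameterError(f"beta/2 must be >= 0, got {b}")
    if sidedness == "one_sided":
        return float(norm.sf(b))
    if sidedness == "two_sided":
        return float(min(2.0 * norm.sf(b), 1.0))
    raise ParameterError(f"unknown sidedness {sidedness!r}")


def expected_fail_rate(
    mean: float, sd: float, threshold: float, sidedness: Sidedness
) -> float:
    """Gaussian-model failure percentage at an action level.

    One-sided (GPR-like): fail when the metric falls below ``threshold``.
    Two-sided (ΔD-like): fail when |metric| exceeds ``threshold``.
    """
    if sd < 0:
        raise ParameterError(f"sd must be >= 0, got {sd}")
    if sd == 0:
        if sidedness == "one_sided":
            return 100.0 if mean < threshold else 0.0
        return 100.0 if abs(mean) > threshold else 0.0
    if sidedness == "one_sided":
        return 100.0 * float(norm.cdf((threshold - mean) / sd))
    if sidedness == "two_sided":
        upper = float(norm.sf((threshold - mean) / sd))
        lower = float(norm.cdf((-threshold - mean) / sd))
        return 100.0 * (upper + lower)
    raise ParameterError(f"unknown sidedness {sidedness!r}")


def binomial_se(p: float, n: int) -> float:
    """Binomial standard error of a proportion, in percentage points."""
    if not 0 <= p <= 1:
        raise ParameterError(f"p must be in [0, 1], got {p}")
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    return 100.0 * float(np.sqrt(p * (1.0 - p) / n))


# ---------------------------------------------------------------------------
# Right-truncated (clipped) GPR model
# ---------------------------------------------------------------------------

def clipped_normal_moments(mu: float, sigma: float, bound: float = 100.0) -> tuple[float, float]:
    """Mean and SD of min(X, bound) for X ~ N(mu, sigma)."""
    if sigma <= 0:
        return min(mu, bound), 0.0
    alpha = (bound - mu) / sigma
    phi, cdf = norm.pdf(alpha), norm.cdf(alpha)
    m1 = mu * cdf - sigma * phi + bound * (1.0 - cdf)
    m2 = (mu**2 + sigma**2) * cdf - sigma * (bound + mu) * phi + bound**2 * (1.0 - cdf)
    var = max(m2 - m1**2, 0.0)
    return float(m1), float(np.sqrt(var))


def match_clipped_normal(
    target_mean: float, target_sd: float, bound: float = 100.0
) -> tuple[float, float]:
    """Latent (mu, sigma) whose clipped-at-``bound`` law has the given moments.

    Raises :class:`ParameterError` when no latent Gaussian can produce them.
    """
    if target_mean > bound:
        raise ParameterError(f"target mean {target_mean} exceeds the bound {bound}")
    if target_sd <= 0:
        raise ParameterError(f"target sd must be > 0, got {target_sd}")

    def residuals(x):
        m, s = clipped_normal_moments(x[0], np.exp(x[1]), bound)
        return [m - target_mean, s - target_sd]

    sol = optimize.least_squares(
        residuals,
        x0=[target_mean, np.log(target_sd)],
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    m, s = clipped_normal_moments(mu, sigma, bound)
    if abs(m - target_mean) > 1e-6 * max(1, abs(target_mean)) or abs(s - target_sd) > 1e-6 * target_sd:
        raise ParameterError(
            f"no clipped Gaussian matches mean {target_mean}, sd {target_sd}"
        )
    return mu, sigma


def sample_clipped_gpr(
    mean: float,
    sd: float,
    size: int,
    rng: np.random.Generator,
    bound: float = 100.0,
) -> np.ndarray:
    """Sample a right-clipped Gaussian moment-matched to (mean, sd)."""
    mu, sigma = match_clipped_normal(mean, sd, bound)
    return np.minimum(rng.normal(mu, sigma, size), bound)


def truncation_beta_correction(
    gpr_mean: float,
    gpr_sd: float,
    q: float,
    reps: int = 100_000,
    seed: int | None = 0,
) -> float:
    """Simulated correction factor to beta/2 for right-truncated GPR cohorts.

    Draws ``reps`` clipped-Gaussian GPR samples moment-matched to
    (``gpr_mean``, ``gpr_sd``), measures the standardized distance from the
    sample mean to the empirical q-quantile, and returns its ratio to the
    untruncated Gaussian beta/2 for the same q. Far from the bound the factor
    approaches 1; near 100 the heavy lower tail pushes it above 1.
    """
    if not 0 < q < 1:
        raise ParameterError(f"q must be in (0, 1), got {q}")
    if reps < 10_000:
        raise ParameterError(f"reps must be >= 10000 for a stable quantile, got {reps}")
    rng = np.random.default_rng(seed)
    sample = sample_clipped_gpr(gpr_mean, gpr_sd, reps, rng)
    m, s = float(sample.mean()), float(sample.std(ddof=1))
    quantile = float(np.quantile(sample, q))
    empirical = (m - quantile) / s
    return empirical / beta_half_from_q(q, "one_sided")
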