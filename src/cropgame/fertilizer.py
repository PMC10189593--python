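"""Fertilizer as a skew-normal perturbation of the stationary soil law.

Fertilizer acts only on a rotation already at steady state: a nonnegative
mass profile f_i (a discretized skew-normal with location mu, spread sigma
and skewness alpha, evaluated at integer soil qualities) is added to the
stationary distribution and the sum renormalized,

    x_i  ->  (x_i + f_i) / (1 + sum_j f_j).

Shifting mass above the profit threshold theta raises the winning chances
of a cash season; mass below theta lowers them — so fertilizer can either
raise or lower the critical threshold theta*, and the decision report makes
that direction explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .markov import critical_theta, soil_stationary, win_probability_from_distribution
from .params import FertilizerParams, ModelParams, Timing

__all__ = [
    "skew_normal_profile",
    "apply_fertilizer",
    "critical_theta_with_fertilizer",
    "FertilizerReport",
    "fertilizer_decision_report",
]


def skew_normal_profile(fp: FertilizerParams, K: int) -> np.ndarray:
    """Skew-normal density evaluated at soil qualities 0..K (not renormalized).

    f_i = exp(-(i-mu)^2 / 2 sigma^2) * erfc(-alpha (i-mu) / (sqrt(2) sigma))
          / (sqrt(2 pi) sigma),

    i.e. the standard skew-normal pdf 2*phi((i-mu)/sigma)*Phi(alpha (i-mu)/sigma)/sigma.
    At alpha=0 it reduces to the normal density.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    i = np.arange(K + 1)
    return stats.skewnorm.pdf(i, a=fp.skew, loc=fp.mu, scale=fp.sigma)


def apply_fertilizer(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Perturb a soil-quality distribution by the fertilizer profile f."""
    x = np.asarray(x, dtype=float)
    f = np.asarray(f, dtype=float)
    if x.shape != f.shape:
        raise ValueError(f"shape mismatch: x {x.shape} vs f {f.shape}")
    if np.any(f < 0):
        raise ValueError("fertilizer profile must be nonnegative")
    if not np.isclose(x.sum(), 1.0, atol=1e-10):
        raise ValueError("x must sum to 1")
    return (x + f) / (1.0 + f.sum())


def _resolve_profile(
    fp: "FertilizerParams | np.ndarray", K: int
) -> np.ndarray:
    """Accept either skew-normal parameters or an explicit mass profile."""
    if isinstance(fp, FertilizerParams):
        return skew_normal_profile(fp, K)
    f = np.asarray(fp, dtype=float)
    if f.shape != (K + 1,):
        raise ValueError(f"profile must have length K+1 = {K + 1}")
    if np.any(f < 0):
        raise ValueError("fertilizer profile must be nonnegative")
    return f


def _fertilized_pwin_factory(fp: "FertilizerParams | np.ndarray", timing: Timing):
    """PwinR(gamma) curve evaluated on the fertilizer-modified steady state."""

    def factory(params: ModelParams):
        f = _resolve_profile(fp, params.K)

        def curve(gamma: float) -> float:
            x = apply_fertilizer(soil_stationary(params, gamma), f)
            return win_probability_from_distribution(params, x, gamma, timing)

        return curve

    return factory


def critical_theta_with_fertilizer(
    params: ModelParams,
    fp: "FertilizerParams | np.ndarray",
    timing: Timing = "post",
    grid_step: float = 0.005,
) -> Optional[int]:
    """theta* when every PwinR evaluation uses the fertilizer-modified law.

    ``fp`` is either skew-normal parameters or an explicit nonnegative mass
    profile of length K+1 (for constructed what-if profiles)."""
    return critical_theta(
        params,
        timing=timing,
        grid_step=grid_step,
        pwin_factory=_fertilized_pwin_factory(fp, timing),
    )


@dataclass(frozen=True)
class FertilizerReport:
    theta_star_without: Optional[int]
    theta_star_with: Optional[int]
    difference: Optional[int]
    verdict: str  # beneficial | harmful | neutral


def fertilizer_decision_report(
    params: ModelParams,
    fp: "FertilizerParams | np.ndarray",
    timing: Timing = "post",
    grid_step: float = 0.005,
) -> FertilizerReport:
    """Compare theta* with and without fertilizer and issue a verdict.

    "beneficial" means fertilizer raises the largest winnable threshold,
    "harmful" that it lowers it; a threshold that exists only on one side
    counts as a change in that direction.
    """
    without = critical_theta(params, timing=timing, grid_step=grid_step)
    with_f = critical_theta_with_fertilizer(params, fp, timing, grid_step)
    lo = -1 if without is None else without
    hi = -1 if with_f is None else with_f
    diff = hi - lo
    verdict = "neutral" if diff == 0 else ("beneficial" if diff > 0 else "harmful")
    return FertilizerReport(
        theta_star_without=without,
        theta_star_with=with_f,
        difference=None if (without is None and with_f is None) else diff,
        verdict=verdict,
    )
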