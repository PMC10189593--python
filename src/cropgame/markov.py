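"""Markov-chain analysis of randomized crop rotation.

One season of randomized rotation moves soil quality i up to min(i+a, K)
with probability gamma (cover crop) or down to max(i-b, 0) with probability
1-gamma (cash crop). For 0 < gamma < 1 the chain has a unique stationary
distribution x*; the long-run per-season win probability is

    PwinR = sum_i x*_i * [gamma*p + (1-gamma)*p_cash(i)]

where p_cash is p1 on soil quality <= theta and p2 above it. Two timing
conventions are supported for which soil quality classifies the cash
payoff: ``pre`` uses the quality at the start of the season (the literal
stationary-sum form q1*sum_{i<=theta} x_i + q2*sum_{i>theta} x_i), ``post``
uses the end-of-season quality max(i-b, 0). The default is ``post``.

A rotation is "winning" when PwinR > 1/2; the winning gamma-interval
(gamma_min, gamma_max) and the critical threshold theta* (largest theta
that admits a winning interval) are computed by grid scan + bisection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import linalg

from .params import ModelParams, Timing, validate_timing

__all__ = [
    "WinRegion",
    "build_transition_matrix",
    "stationary_distribution",
    "win_probability_from_distribution",
    "win_probability_randomized",
    "win_region",
    "critical_theta",
]

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class WinRegion:
    """Winning gamma-interval where PwinR > 1/2 (absent if none exists)."""

    exists: bool
    gamma_min: Optional[float] = None
    gamma_max: Optional[float] = None
    gamma_grid_resolution: float = 0.0

    @property
    def width(self) -> float:
        if not self.exists:
            return 0.0
        return self.gamma_max - self.gamma_min  # type: ignore[operator]


def _check_gamma(gamma: float) -> float:
    gamma = float(gamma)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma out of [0,1]: got {gamma!r}")
    return gamma


def build_transition_matrix(params: ModelParams, gamma: float) -> np.ndarray:
    """One-season (K+1)x(K+1) transition matrix of the soil-quality chain.

    Row i carries mass gamma on min(i+a, K) and 1-gamma on max(i-b, 0);
    coincident destinations accumulate.
    """
    gamma = _check_gamma(gamma)
    n = params.n_states
    T = np.zeros((n, n))
    i = np.arange(n)
    up = np.minimum(i + params.a, params.K)
    down = np.maximum(i - params.b, 0)
    np.add.at(T, (i, up), gamma)
    np.add.at(T, (i, down), 1.0 - gamma)
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary law x with x @ T = x, solved via the null space of T' - I.

    Requires a row-stochastic T with a one-dimensional stationary space
    (guaranteed here for 0 < gamma < 1; pass gamma-endpoint chains through
    :func:`soil_stationary` instead, which returns the absorbing point mass).
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < -_ROW_SUM_TOL) or np.any(T > 1 + _ROW_SUM_TOL):
        raise ValueError("transition matrix entries must lie in [0,1]")
    if not np.allclose(T.sum(axis=1), 1.0, atol=_ROW_SUM_TOL):
        raise ValueError("transition matrix rows must sum to 1")
    ns = linalg.null_space(T.T - np.eye(T.shape[0]), rcond=1e-10)
    if ns.shape[1] != 1:
        raise ValueError(
            f"stationary distribution is not unique ({ns.shape[1]} null vectors)"
        )
    x = ns[:, 0]
    x = np.abs(x)  # null vector sign is arbitrary
    x /= x.sum()
    return x


def soil_stationary(params: ModelParams, gamma: float) -> np.ndarray:
    """Stationary soil-quality law, including the absorbing endpoints.

    gamma = 0 pins the soil at 0 (cash monoculture strips the field);
    gamma = 1 pins it at the carrying capacity K.
    """
    gamma = _check_gamma(gamma)
    n = params.n_states
    if gamma == 0.0:
        x = np.zeros(n)
        x[0] = 1.0
        return x
    if gamma == 1.0:
        x = np.zeros(n)
        x[-1] = 1.0
        return x
    return stationary_distribution(build_transition_matrix(params, gamma))


def _cash_class_probs(params: ModelParams, timing: Timing) -> np.ndarray:
    """Per-state cash-crop profit probability under the timing convention."""
    i = np.arange(params.n_states)
    if timing == "pre":
        ref = i
    else:  # post: classify on the end-of-season quality
        ref = np.maximum(i - params.b, 0)
    return np.where(ref <= params.theta, params.p1, params.p2)


def win_probability_from_distribution(
    params: ModelParams,
    x: np.ndarray,
    gamma: float,
    timing: Timing = "post",
    p_eff: Optional[float] = None,
    p1_eff: Optional[float] = None,
    p2_eff: Optional[float] = None,
) -> float:
    """Per-season win probability given a soil-quality distribution x.

    The optional effective probabilities substitute for (p, p1, p2); the
    pathogen extension uses them.
    """
    gamma = _check_gamma(gamma)
    validate_timing(timing)
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_states,):
        raise ValueError(f"distribution must have length K+1 = {params.n_states}")
    p = params.p if p_eff is None else p_eff
    p1 = params.p1 if p1_eff is None else p1_eff
    p2 = params.p2 if p2_eff is None else p2_eff
    sub = ModelParams(params.K, params.theta, params.a, params.b, p, p1, p2)
    p_cash = _cash_class_probs(sub, timing)
    return float(gamma * p + (1.0 - gamma) * np.dot(x, p_cash))


def win_probability_randomized(
    params: ModelParams, gamma: float, timing: Timing = "post"
) -> float:
    """Long-run win probability PwinR of the randomized rotation at gamma.

    Monoculture limits hold exactly for both timings: gamma=0 gives p1,
    gamma=1 gives p.
    """
    x = soil_stationary(params, gamma)
    return win_probability_from_distribution(params, x, gamma, timing)


def _bisect_crossing(
    f: Callable[[float], float], lo: float, hi: float, tol: float
) -> float:
    """Root of f (sign change assumed between lo and hi) by bisection."""
    flo = f(lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        if (flo < 0) == (fmid < 0):
            lo, flo = mid, fmid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def win_region(
    params: ModelParams,
    grid_step: float = 0.005,
    refine_tol: float = 1e-6,
    timing: Timing = "post",
    pwin: Optional[Callable[[float], float]] = None,
) -> WinRegion:
    """Winning gamma-interval of PwinR(gamma) > 1/2, or exists=False.

    Scans a uniform gamma grid on (0, 1), then refines each boundary by
    bisection. If several disjoint winning intervals appear, the widest is
    returned with a warning. ``pwin`` overrides the evaluated curve (the
    fertilizer and pathogen modules pass their modified curves).
    """
    if not 0 < grid_step <= 0.01:
        raise ValueError("grid_step must be in (0, 0.01]")
    if pwin is None:
        pwin = lambda g: win_probability_randomized(params, g, timing)  # noqa: E731
    f = lambda g: pwin(g) - 0.5  # noqa: E731

    grid = np.arange(grid_step, 1.0, grid_step)
    vals = np.array([f(g) for g in grid])
    winning = vals > 0
    if not winning.any():
        return WinRegion(exists=False, gamma_grid_resolution=grid_step)

    # contiguous winning runs on the grid
    idx = np.flatnonzero(winning)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    if len(starts) > 1:
        warnings.warn(
            f"{len(starts)} disjoint winning gamma-intervals detected; "
            "reporting the widest",
            stacklevel=2,
        )
        widths = grid[ends] - grid[starts]
        k = int(np.argmax(widths))
        starts, ends = starts[[k]], ends[[k]]
    s, e = int(starts[0]), int(ends[0])

    lo_outer = grid[s] - grid_step if s > 0 else 0.0
    gamma_min = (
        _bisect_crossing(f, lo_outer, grid[s], refine_tol)
        if f(lo_outer) <= 0
        else lo_outer
    )
    hi_outer = grid[e] + grid_step if e < len(grid) - 1 else 1.0
    gamma_max = (
        _bisect_crossing(f, grid[e], hi_outer, refine_tol)
        if f(hi_outer) <= 0
        else hi_outer
    )
    return WinRegion(
        exists=True,
        gamma_min=float(gamma_min),
        gamma_max=float(gamma_max),
        gamma_grid_resolution=grid_step,
    )


def critical_theta(
    params: ModelParams,
    timing: Timing = "post",
    grid_step: float = 0.005,
    pwin_factory: Optional[Callable[[ModelParams], Callable[[float], float]]] = None,
) -> Optional[int]:
    """Largest theta in {0..K} with a winning gamma-interval, or None.

    Scans every theta rather than assuming monotonicity in theta. The
    ``pwin_factory`` hook supplies a modified PwinR curve per theta (used
    by the fertilizer module).
    """
    best: Optional[int] = None
    for theta in range(params.K + 1):
        sub = params.with_theta(theta)
        curve = pwin_factory(sub) if pwin_factory is not None else None
        region = win_region(sub, grid_step=grid_step, timing=timing, pwin=curve)
        if region.exists:
            best = theta
    return best
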