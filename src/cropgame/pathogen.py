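"""Parrondo effect under pathogen pressure.

A crop-borne pathogen proliferates on cash crops and subsides under cover
crops: its load n walks on {0..L}, up by ``growth_step`` with probability
1-gamma (a cash season) and down by ``decay_step`` with probability gamma,
clipped at the boundaries. Severity beta in [0,1] scales how strongly the
load suppresses cash-crop profitability.

Default severity mapping (pluggable): the cover crop is unaffected
(p_eff = p) and each cash probability is averaged over the stationary load
law y with a linear suppression factor,

    p_i_eff = p_i * sum_n y_n (1 - beta * n / L) = p_i * (1 - beta * E[n]/L).

At beta = 0 the baseline model is recovered exactly. The effective win
probability uses the soil stationary law with the effective probabilities
(marginal soil and pathogen summaries multiply; the crop draw's correlation
with both states is deliberately ignored — a joint soil x load product
chain is available as a diagnostic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import optimize

from .markov import (
    soil_stationary,
    stationary_distribution,
    win_probability_from_distribution,
)
from .params import ModelParams, PathogenParams, Timing, validate_timing

__all__ = [
    "EffectiveProbabilities",
    "pathogen_stationary",
    "effective_probabilities",
    "win_probability_pathogen",
    "gamma_opt",
    "joint_chain_win_probability",
]

# severity mapping: (p_i, beta, load law y, L) -> effective probability
SeverityMapping = Callable[[float, float, np.ndarray, int], float]


def linear_suppression(p_i: float, beta: float, y: np.ndarray, L: int) -> float:
    """Default mapping: p_i * E_y[1 - beta * n / L]."""
    if beta == 0.0:  # exact identity, no float residue from the dot product
        return float(p_i)
    n = np.arange(len(y))
    return float(p_i * np.dot(y, 1.0 - beta * n / L))


@dataclass(frozen=True)
class EffectiveProbabilities:
    p_eff: float
    p1_eff: float
    p2_eff: float


def pathogen_stationary(gamma: float, pp: PathogenParams) -> np.ndarray:
    """Stationary law of the pathogen-load chain on {0..L} at cover rate gamma."""
    gamma = float(gamma)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma out of [0,1]: got {gamma!r}")
    n = pp.L + 1
    if gamma == 1.0:  # cover monoculture starves the pathogen
        y = np.zeros(n)
        y[0] = 1.0
        return y
    if gamma == 0.0:  # cash monoculture pins the load at L
        y = np.zeros(n)
        y[-1] = 1.0
        return y
    # same clipped birth-death structure as the soil chain, with up-rate 1-gamma
    load_chain = ModelParams(K=pp.L, theta=0, a=pp.growth_step, b=pp.decay_step)
    i = np.arange(n)
    T = np.zeros((n, n))
    up = np.minimum(i + load_chain.a, pp.L)
    down = np.maximum(i - load_chain.b, 0)
    np.add.at(T, (i, up), 1.0 - gamma)
    np.add.at(T, (i, down), gamma)
    return stationary_distribution(T)


def effective_probabilities(
    params: ModelParams,
    gamma: float,
    pp: PathogenParams,
    mapping: SeverityMapping = linear_suppression,
) -> EffectiveProbabilities:
    """Pathogen-adjusted profit probabilities at cover rate gamma."""
    y = pathogen_stationary(gamma, pp)
    return EffectiveProbabilities(
        p_eff=params.p,  # the pathogen affects only the cash crop
        p1_eff=mapping(params.p1, pp.beta, y, pp.L),
        p2_eff=mapping(params.p2, pp.beta, y, pp.L),
    )


def win_probability_pathogen(
    params: ModelParams,
    gamma: float,
    pp: PathogenParams,
    timing: Timing = "post",
    mapping: SeverityMapping = linear_suppression,
) -> float:
    """Effective long-run win probability under pathogen pressure."""
    validate_timing(timing)
    eff = effective_probabilities(params, gamma, pp, mapping)
    x = soil_stationary(params, gamma)
    return win_probability_from_distribution(
        params, x, gamma, timing,
        p_eff=eff.p_eff, p1_eff=eff.p1_eff, p2_eff=eff.p2_eff,
    )


def gamma_opt(
    params: ModelParams,
    pp: PathogenParams,
    timing: Timing = "post",
    grid_step: float = 0.002,
    mapping: SeverityMapping = linear_suppression,
) -> tuple[float, float]:
    """Cover-crop rate maximizing the pathogen-adjusted win probability.

    Grid search over (0, 1) followed by a bounded scalar refinement around
    the best grid point; deterministic.
    """
    if grid_step > 0.005:
        raise ValueError("grid_step must be <= 0.005")
    f = lambda g: win_probability_pathogen(params, g, pp, timing, mapping)  # noqa: E731
    grid = np.arange(grid_step, 1.0, grid_step)
    vals = np.array([f(g) for g in grid])
    k = int(np.argmax(vals))
    lo = grid[k] - grid_step if k > 0 else grid_step / 2
    hi = grid[k] + grid_step if k < len(grid) - 1 else 1.0 - grid_step / 2
    res = optimize.minimize_scalar(
        lambda g: -f(g), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-7},
    )
    g_best = float(res.x)
    p_best = float(-res.fun)
    if vals[k] > p_best:  # refinement can only improve on the grid point
        g_best, p_best = float(grid[k]), float(vals[k])
    return g_best, p_best


def joint_chain_win_probability(
    params: ModelParams,
    gamma: float,
    pp: PathogenParams,
    timing: Timing = "post",
) -> float:
    """Diagnostic: win probability from the joint soil x load product chain.

    Tracks the crop draw's simultaneous effect on soil and load (which the
    marginal effective-probability formula ignores). For comparison only.
    """
    validate_timing(timing)
    gamma = float(gamma)
    if gamma in (0.0, 1.0):
        x = soil_stationary(params, gamma)
        y = pathogen_stationary(gamma, pp)
    else:
        nK, nL = params.n_states, pp.L + 1
        T = np.zeros((nK * nL, nK * nL))
        for i in range(nK):
            for n in range(nL):
                s = i * nL + n
                iu = min(i + params.a, params.K)
                nd = max(n - pp.decay_step, 0)
                T[s, iu * nL + nd] += gamma
                idn = max(i - params.b, 0)
                nu = min(n + pp.growth_step, pp.L)
                T[s, idn * nL + nu] += 1.0 - gamma
        z = stationary_distribution(T).reshape(nK, nL)
        x = z.sum(axis=1)
        y = z.sum(axis=0)
    # suppression applied with the same linear factor, on the joint law's margins
    supp = float(np.dot(y, 1.0 - pp.beta * np.arange(pp.L + 1) / pp.L))
    return win_probability_from_distribution(
        params, x, gamma, timing,
        p_eff=params.p, p1_eff=params.p1 * supp, p2_eff=params.p2 * supp,
    )
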