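"""Exact and Monte-Carlo evaluation of deterministic rotation schedules.

A deterministic schedule (alpha_1, ..., alpha_n) repeats with period
sum(alpha_i); the soil trajectory it drives is deterministic and, because
the state space is finite, falls onto a limit cycle. The exact long-run win
probability is the average of the per-season win probabilities over that
cycle — no simulation required. The Monte-Carlo route (the capital draws
are still random) serves as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DeterministicSequence, ModelParams, SimulationConfig, Timing, \
    validate_timing
from .simulate import SlopeEstimate, fit_slope, run_batch

__all__ = [
    "SequenceEvaluation",
    "sequence_win_probability_exact",
    "scan_sequences",
    "top_sequences",
    "sequence_win_probability_mc",
]


@dataclass(frozen=True)
class SequenceEvaluation:
    sequence: DeterministicSequence
    pwin: float
    cycle_length: int
    transient_length: int
    q0: int


def sequence_win_probability_exact(
    seq: DeterministicSequence,
    params: ModelParams,
    q0: int = 0,
    timing: Timing = "post",
) -> SequenceEvaluation:
    """Exact long-run win probability of a periodic schedule from q0.

    Iterates the deterministic soil map until a (position-in-period, soil)
    pair repeats, then averages the per-season win probabilities over the
    detected cycle. Zero-net-drift schedules can have q0-dependent cycles;
    the starting state is recorded in the result.
    """
    validate_timing(timing)
    if not 0 <= q0 <= params.K:
        raise ValueError(f"q0 must be in [0, K], got {q0}")
    crops = seq.crops()
    period = seq.period

    seen: dict[tuple[int, int], int] = {}
    wins: list[float] = []   # per-season win probability along the orbit
    soil = q0
    step = 0
    while (step % period, soil) not in seen:
        seen[(step % period, soil)] = step
        cover = crops[step % period]
        prev = soil
        soil = min(soil + params.a, params.K) if cover else max(soil - params.b, 0)
        if cover:
            wins.append(params.p)
        else:
            ref = soil if timing == "post" else prev
            wins.append(params.p1 if ref <= params.theta else params.p2)
        step += 1

    start = seen[(step % period, soil)]
    cycle = wins[start:]
    return SequenceEvaluation(
        sequence=seq,
        pwin=float(np.mean(cycle)),
        cycle_length=len(cycle),
        transient_length=start,
        q0=q0,
    )


def scan_sequences(
    alpha_max: int,
    params: ModelParams,
    q0: int = 0,
    timing: Timing = "post",
) -> pd.DataFrame:
    """Evaluate every (alpha1, alpha2) pair with entries in {0..alpha_max}.

    Returns a DataFrame with columns alpha1, alpha2, pwin, is_winning
    (pwin > 0.5), skipping the empty (0, 0) pair.
    """
    if alpha_max < 1:
        raise ValueError("alpha_max must be >= 1")
    rows = []
    for a1 in range(alpha_max + 1):
        for a2 in range(alpha_max + 1):
            if a1 == 0 and a2 == 0:
                continue
            ev = sequence_win_probability_exact(
                DeterministicSequence((a1, a2)), params, q0=q0, timing=timing
            )
            rows.append((a1, a2, ev.pwin, ev.pwin > 0.5))
    return pd.DataFrame(rows, columns=["alpha1", "alpha2", "pwin", "is_winning"])


def top_sequences(
    table: pd.DataFrame, k: int = 5, precision: int = 2, winning_only: bool = True
) -> pd.DataFrame:
    """Top-k rows of a scan table ranked by win probability.

    pwin is rounded to ``precision`` decimals for ranking only; ties break
    by smaller total period, then lexicographically on (alpha1, alpha2).
    """
    df = table.copy()
    df["pwin_rounded"] = df["pwin"].round(precision)
    if winning_only:
        df = df[df["pwin_rounded"] >= 0.5]
    df["period"] = df["alpha1"] + df["alpha2"]
    df = df.sort_values(
        ["pwin_rounded", "period", "alpha1", "alpha2"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).drop(columns="period")
    return df.head(k).reset_index(drop=True)


def sequence_win_probability_mc(
    seq: DeterministicSequence, params: ModelParams, cfg: SimulationConfig
) -> SlopeEstimate:
    """Monte-Carlo estimate of a schedule's win probability via the slope fit."""
    cfg = SimulationConfig(
        n_seasons=cfg.n_seasons,
        n_reps=cfg.n_reps,
        policy=seq,
        seed=cfg.seed,
        q0=cfg.q0,
        timing=cfg.timing,
    )
    return fit_slope(run_batch(params, cfg))
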