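"""Seeded Monte-Carlo engine for cropping sequences.

Each replicate is an independent cropping sequence: per season a crop is
drawn (randomized policy, cover with probability gamma) or read off a
deterministic schedule; soil quality moves +a (cover) or -b (cash), clipped
to [0, K]; the season yields +1 capital with the crop's profit probability
(p for cover; p1/p2 by the timing-convention soil quality for cash) and -1
otherwise. The long-run win probability is estimated from the slope s of
the mean capital trajectory: with ±1 payoffs, P_win = (1 + s) / 2.

Replicates draw from independent SeedSequence-spawned streams keyed by
replicate index, so replicate r is bit-identical regardless of n_reps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DeterministicSequence, ModelParams, SimulationConfig

__all__ = ["TrajectoryBatch", "SlopeEstimate", "run_batch", "fit_slope",
           "occupancy_frequencies"]


@dataclass(frozen=True)
class TrajectoryBatch:
    """Simulated trajectories: arrays of shape (n_reps, n_seasons + 1).

    Column t holds the state after season t (column 0 = the start: soil q0,
    capital 0). ``crops`` has shape (n_reps, n_seasons); True = cover crop.
    """

    soil: np.ndarray      # int16
    capital: np.ndarray   # int32, cumulative ±1 yield
    crops: np.ndarray     # bool
    config: SimulationConfig
    params: ModelParams

    @property
    def n_seasons(self) -> int:
        return self.crops.shape[1]

    @property
    def n_reps(self) -> int:
        return self.crops.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: replicate, season, crop, soil, capital."""
        m, n = self.n_reps, self.n_seasons
        rep = np.repeat(np.arange(m), n)
        season = np.tile(np.arange(1, n + 1), m)
        return pd.DataFrame(
            {
                "replicate": rep,
                "season": season,
                "crop": np.where(self.crops.ravel(), "cover", "cash"),
                "soil": self.soil[:, 1:].ravel(),
                "capital": self.capital[:, 1:].ravel(),
            }
        )


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS slope of mean capital vs season and the implied win probability."""

    slope: float
    pwin_hat: float
    stderr: float

    def to_dict(self) -> dict:
        return {"slope": self.slope, "pwin_hat": self.pwin_hat,
                "stderr": self.stderr}


def _replicate_uniforms(seed: int, n_reps: int, n_seasons: int):
    """Per-replicate uniform blocks (crop draws, win draws).

    Each replicate gets its own spawned stream; its draws do not depend on
    how many other replicates run alongside it.
    """
    children = np.random.SeedSequence(seed).spawn(n_reps)
    u_crop = np.empty((n_reps, n_seasons))
    u_win = np.empty((n_reps, n_seasons))
    for r, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        u_crop[r] = rng.random(n_seasons)
        u_win[r] = rng.random(n_seasons)
    return u_crop, u_win


def run_batch(params: ModelParams, cfg: SimulationConfig) -> TrajectoryBatch:
    """Simulate a batch of cropping sequences; fully reproducible from seed."""
    if cfg.q0 > params.K:
        raise ValueError(f"q0 must be <= K, got {cfg.q0} > {params.K}")
    m, n = cfg.n_reps, cfg.n_seasons
    u_crop, u_win = _replicate_uniforms(cfg.seed, m, n)

    if isinstance(cfg.policy, DeterministicSequence):
        period = np.array(cfg.policy.crops(), dtype=bool)
        sched = np.resize(period, n)
        crops = np.broadcast_to(sched, (m, n)).copy()
    else:
        crops = u_crop < float(cfg.policy)

    soil = np.empty((m, n + 1), dtype=np.int16)
    capital = np.empty((m, n + 1), dtype=np.int32)
    soil[:, 0] = cfg.q0
    capital[:, 0] = 0
    yields = np.empty((m, n), dtype=np.int32)

    for t in range(n):
        cover = crops[:, t]
        prev = soil[:, t]
        nxt = np.where(
            cover,
            np.minimum(prev + params.a, params.K),
            np.maximum(prev - params.b, 0),
        ).astype(np.int16)
        soil[:, t + 1] = nxt
        ref = nxt if cfg.timing == "post" else prev
        p_season = np.where(
            cover, params.p, np.where(ref <= params.theta, params.p1, params.p2)
        )
        yields[:, t] = np.where(u_win[:, t] < p_season, 1, -1)

    np.cumsum(yields, axis=1, out=capital[:, 1:])
    return TrajectoryBatch(soil=soil, capital=capital, crops=crops,
                           config=cfg, params=params)


def fit_slope(batch: TrajectoryBatch) -> SlopeEstimate:
    """OLS line through (season, mean capital); pwin_hat = (1 + slope) / 2.

    The standard error of pwin_hat comes from the spread of per-replicate
    slopes (each replicate's capital trajectory fit with the same design).
    """
    n = batch.n_seasons
    if n < 2:
        raise ValueError("slope fit needs at least 2 seasons")
    t = np.arange(n + 1, dtype=float)
    tc = t - t.mean()
    denom = np.dot(tc, tc)
    # per-replicate OLS slopes share the centred design, so one matvec
    slopes = batch.capital @ tc / denom
    slope = float(slopes.mean())
    stderr_slope = float(slopes.std(ddof=1) / np.sqrt(batch.n_reps)) \
        if batch.n_reps > 1 else float("nan")
    return SlopeEstimate(
        slope=slope,
        pwin_hat=(1.0 + slope) / 2.0,
        stderr=stderr_slope / 2.0,
    )


def occupancy_frequencies(batch: TrajectoryBatch, burn_in: int = 0) -> np.ndarray:
    """Empirical soil-quality frequencies over all replicates after burn-in."""
    if burn_in >= batch.n_seasons:
        raise ValueError("burn_in must be < n_seasons")
    states = batch.soil[:, burn_in + 1:]
    counts = np.bincount(states.ravel(), minlength=batch.params.n_states)
    return counts / counts.sum()
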