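"""Parameter containers and validation for the crop-rotation game.

The model is a discrete random walk of soil quality on {0, ..., K}: a cover
crop (planted with probability ``gamma`` under randomized rotation) raises
soil quality by ``a`` units and yields a profit with probability ``p``; a
cash crop lowers it by ``b`` units and yields a profit with probability
``p1`` on poor soil (quality <= theta) or ``p2`` on good soil (quality >
theta). Jumps clip to the boundaries 0 and K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

Timing = Literal["pre", "post"]

__all__ = [
    "ModelParams",
    "FertilizerParams",
    "PathogenParams",
    "SimulationConfig",
    "DeterministicSequence",
    "Timing",
    "validate_timing",
]


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} out of [0,1]: got {value!r}")


def validate_timing(timing: str) -> Timing:
    if timing not in ("pre", "post"):
        raise ValueError(f"timing must be 'pre' or 'post', got {timing!r}")
    return timing  # type: ignore[return-value]


@dataclass(frozen=True)
class ModelParams:
    """The crop/soil game parameters.

    Attributes
    ----------
    K : int
        Maximum soil quality (carrying capacity); states are 0..K.
    theta : int
        Profit threshold: soil quality <= theta is "bad" for a cash crop.
    a : int
        Soil-quality gain per cover-crop season.
    b : int
        Soil-quality loss per cash-crop season.
    p : float
        Profit probability of a cover crop (state-independent).
    p1, p2 : float
        Cash-crop profit probabilities on bad / good soil.
    """

    K: int
    theta: int
    a: int = 1
    b: int = 1
    p: float = 0.4
    p1: float = 0.0
    p2: float = 0.8

    def __post_init__(self) -> None:
        if not (isinstance(self.K, int) and self.K >= 1):
            raise ValueError(f"K must be a positive integer, got {self.K!r}")
        for name in ("a", "b"):
            v = getattr(self, name)
            if not (isinstance(v, int) and 0 < v <= self.K):
                raise ValueError(f"{name} must be an integer in (0, K], got {v!r}")
        if not (isinstance(self.theta, int) and 0 <= self.theta <= self.K):
            raise ValueError(f"theta must be an integer in [0, K], got {self.theta!r}")
        for name in ("p", "p1", "p2"):
            _check_prob(name, getattr(self, name))

    @property
    def n_states(self) -> int:
        return self.K + 1

    def with_theta(self, theta: int) -> "ModelParams":
        """Copy with a different profit threshold."""
        return ModelParams(self.K, theta, self.a, self.b, self.p, self.p1, self.p2)


@dataclass(frozen=True)
class FertilizerParams:
    """Skew-normal fertilizer effect: location mu, spread sigma > 0, skew alpha."""

    mu: float
    sigma: float
    skew: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma!r}")


@dataclass(frozen=True)
class PathogenParams:
    """Pathogen load chain: severity beta in [0,1], max load L, +/- steps per season."""

    beta: float
    L: int = 10
    growth_step: int = 1
    decay_step: int = 1

    def __post_init__(self) -> None:
        _check_prob("beta", self.beta)
        if not (isinstance(self.L, int) and self.L >= 1):
            raise ValueError(f"L must be a positive integer, got {self.L!r}")
        for name in ("growth_step", "decay_step"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


@dataclass(frozen=True)
class DeterministicSequence:
    """Run-length encoding of a periodic rotation schedule.

    ``alphas`` has even length; odd positions (1-indexed) count consecutive
    cover-crop seasons, even positions consecutive cash-crop seasons.
    E.g. (2, 3) = two cover seasons then three cash seasons, repeating.
    """

    alphas: tuple[int, ...]

    def __init__(self, alphas: Sequence[int]) -> None:
        object.__setattr__(self, "alphas", tuple(int(x) for x in alphas))
        if len(self.alphas) == 0 or len(self.alphas) % 2 != 0:
            raise ValueError("alphas must be a non-empty even-length sequence")
        if any(x < 0 for x in self.alphas):
            raise ValueError("alphas must be nonnegative")
        if all(x == 0 for x in self.alphas):
            raise ValueError("at least one alpha must be positive")

    @property
    def period(self) -> int:
        return sum(self.alphas)

    def crops(self) -> tuple[bool, ...]:
        """One period as per-season flags (True = cover crop)."""
        out: list[bool] = []
        for i, n in enumerate(self.alphas):
            out.extend([i % 2 == 0] * n)
        return tuple(out)

    def net_drift(self, a: int, b: int) -> int:
        """Soil-quality change over one unclipped period: a*sum(odd) - b*sum(even)."""
        cover = sum(self.alphas[0::2])
        cash = sum(self.alphas[1::2])
        return a * cover - b * cash


@dataclass(frozen=True)
class SimulationConfig:
    """Monte-Carlo run configuration.

    ``policy`` is either a cover-crop probability gamma (float) or a
    :class:`DeterministicSequence`. One RNG stream is spawned per replicate
    from ``seed`` so results per replicate do not depend on ``n_reps``.
    """

    n_seasons: int
    n_reps: int
    policy: float | DeterministicSequence
    seed: int = 0
    q0: int = 0
    timing: Timing = "post"

    def __post_init__(self) -> None:
        if self.n_seasons < 1:
            raise ValueError("n_seasons must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.q0 < 0:
            raise ValueError("q0 must be >= 0")
        if isinstance(self.policy, (int, float)) and not isinstance(self.policy, bool):
            _check_prob("policy (gamma)", float(self.policy))
        elif not isinstance(self.policy, DeterministicSequence):
            raise TypeError(
                "policy must be a gamma in [0,1] or a DeterministicSequence"
            )
        validate_timing(self.timing)
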