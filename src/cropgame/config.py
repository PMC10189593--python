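"""Run configuration: YAML/JSON loading, validation and manifests.

A run config bundles the model parameters with a policy (randomized gamma
or a deterministic schedule) and the optional fertilizer / pathogen /
simulation blocks. Unknown keys are rejected so typos fail loudly, and a
manifest written after a run reloads to an identical config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from .params import (
    DeterministicSequence,
    FertilizerParams,
    ModelParams,
    PathogenParams,
    SimulationConfig,
    Timing,
    validate_timing,
)

__all__ = ["RunConfig", "load_config", "parse_config", "write_manifest"]

CONFIG_VERSION = 1

_TOP_KEYS = {"version", "model", "policy", "fertilizer", "pathogen",
             "simulation", "timing", "output"}
_MODEL_KEYS = {"K", "theta", "a", "b", "p", "p1", "p2"}
_FERT_KEYS = {"mu", "sigma", "skew"}
_PATH_KEYS = {"beta", "L", "growth_step", "decay_step"}
_SIM_KEYS = {"n_seasons", "n_reps", "seed", "q0"}


class ConfigError(ValueError):
    """Configuration parse or validation failure, naming the offending key."""


def _reject_unknown(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")


@dataclass(frozen=True)
class RunConfig:
    model: ModelParams
    policy: float | DeterministicSequence
    timing: Timing = "post"
    fertilizer: Optional[FertilizerParams] = None
    pathogen: Optional[PathogenParams] = None
    simulation: Optional[SimulationConfig] = None
    output: Optional[str] = None

    def simulation_config(self) -> SimulationConfig:
        if self.simulation is None:
            raise ConfigError("this command needs a 'simulation' block")
        return self.simulation

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "version": CONFIG_VERSION,
            "model": dataclasses.asdict(self.model),
            "timing": self.timing,
        }
        if isinstance(self.policy, DeterministicSequence):
            d["policy"] = {"sequence": list(self.policy.alphas)}
        else:
            d["policy"] = {"gamma": self.policy}
        if self.fertilizer is not None:
            d["fertilizer"] = dataclasses.asdict(self.fertilizer)
        if self.pathogen is not None:
            d["pathogen"] = dataclasses.asdict(self.pathogen)
        if self.simulation is not None:
            d["simulation"] = {
                "n_seasons": self.simulation.n_seasons,
                "n_reps": self.simulation.n_reps,
                "seed": self.simulation.seed,
                "q0": self.simulation.q0,
            }
        if self.output is not None:
            d["output"] = self.output
        return d


def parse_config(raw: dict[str, Any]) -> RunConfig:
    """Validate a raw mapping into a RunConfig (all constraints checked)."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown("top level", raw, _TOP_KEYS)
    if raw.get("version", CONFIG_VERSION) != CONFIG_VERSION:
        raise ConfigError(f"unsupported config version {raw['version']!r}")

    if "model" not in raw:
        raise ConfigError("missing required section 'model'")
    msec = dict(raw["model"])
    _reject_unknown("model", msec, _MODEL_KEYS)
    for req in ("K", "theta"):
        if req not in msec:
            raise ConfigError(f"missing required key 'model.{req}'")
    try:
        model = ModelParams(**msec)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"model: {e}") from e

    psec = raw.get("policy", {"gamma": 0.5})
    _reject_unknown("policy", psec, {"gamma", "sequence"})
    if "gamma" in psec and "sequence" in psec:
        raise ConfigError("policy: give either 'gamma' or 'sequence', not both")
    if "sequence" in psec:
        try:
            policy: float | DeterministicSequence = DeterministicSequence(
                psec["sequence"]
            )
        except (TypeError, ValueError) as e:
            raise ConfigError(f"policy.sequence: {e}") from e
    else:
        g = float(psec.get("gamma", 0.5))
        if not 0.0 <= g <= 1.0:
            raise ConfigError(f"policy.gamma out of [0,1]: got {g}")
        policy = g

    timing = raw.get("timing", "post")
    try:
        validate_timing(timing)
    except ValueError as e:
        raise ConfigError(str(e)) from e

    fert = None
    if "fertilizer" in raw:
        fsec = dict(raw["fertilizer"])
        _reject_unknown("fertilizer", fsec, _FERT_KEYS)
        try:
            fert = FertilizerParams(**fsec)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"fertilizer: {e}") from e

    path = None
    if "pathogen" in raw:
        psec2 = dict(raw["pathogen"])
        _reject_unknown("pathogen", psec2, _PATH_KEYS)
        try:
            path = PathogenParams(**psec2)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"pathogen: {e}") from e

    sim = None
    if "simulation" in raw:
        ssec = dict(raw["simulation"])
        _reject_unknown("simulation", ssec, _SIM_KEYS)
        try:
            sim = SimulationConfig(
                n_seasons=int(ssec.get("n_seasons", 1000)),
                n_reps=int(ssec.get("n_reps", 1000)),
                policy=policy,
                seed=int(ssec.get("seed", 0)),
                q0=int(ssec.get("q0", 0)),
                timing=timing,
            )
        except (TypeError, ValueError) as e:
            raise ConfigError(f"simulation: {e}") from e

    return RunConfig(
        model=model,
        policy=policy,
        timing=timing,
        fertilizer=fert,
        pathogen=path,
        simulation=sim,
        output=raw.get("output"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON — a YAML subset) config file.

    A run manifest (which nests the config under a 'config' key alongside
    run metadata) reloads to the identical RunConfig.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ConfigError(f"could not parse {path}: {e}") from e
    if isinstance(raw, dict) and "config" in raw:
        raw = raw["config"]
    return parse_config(raw)


def write_manifest(cfg: RunConfig, path: str | Path, **extra: Any) -> None:
    """Write a JSON manifest: the fully-resolved config plus run metadata."""
    from . import __version__

    d: dict[str, Any] = {"config": cfg.to_dict(), "package_version": __version__}
    d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
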