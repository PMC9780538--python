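"""Experiment configuration, presets, and serialization.

A single :class:`ExperimentConfig` carries every parameter of one
experiment: the grids, the transition-curve shapes, the reward and
discount structure, the individual's traits (``p_r``, ``sigma``), the
initial state, horizon, ensemble size and master seed.  Configurations
round-trip losslessly through YAML, and every run's outputs embed the
configuration hash.

The named presets bind the parameter sets printed with the published
experiments: ``fig6`` (moderately analytical individual, constant
discount) and the emotion runs ``fig7a/b/c`` (analytical, p_r = 0.8) and
``fig8a/b/c`` (intuitive, p_r = 0.2).  The ``a`` panels of the emotion
figures are diagnostics of the same runs as the ``b`` panels, so those
preset names alias the same configuration.  No preset fixes a master
seed: every run demands one explicitly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .kernel import ConfigurationError, CurveShape, StateGrid
from .policies import HabitualParams
from .rewards import EmotionProfile, RewardParams

__all__ = [
    "CurveShapeConfig",
    "RewardConfig",
    "EmotionConfig",
    "ExperimentConfig",
    "PRESETS",
    "preset",
    "preset_names",
    "load_config",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class CurveShapeConfig(_StrictModel):
    p_floor: float = 0.05
    p_peak: float = 0.85
    peak_analytical: float = 0.8
    peak_intuitive: float = 0.2
    sharp_analytical: float = 5.0
    sharp_intuitive: float = 0.72

    def build(self) -> CurveShape:
        return CurveShape(**self.model_dump())


class RewardConfig(_StrictModel):
    alpha: float
    beta: float
    gamma: tuple[float, float, float]
    delta: float = Field(gt=0.0, lt=1.0)
    terminal_scale: float = 10.0
    terminal_rate: float = 5.0

    @field_validator("gamma")
    @classmethod
    def _gamma_positive(cls, v):
        if any(g <= 0 for g in v):
            raise ValueError("gamma components must be positive")
        return v

    def build(self) -> RewardParams:
        return RewardParams(**self.model_dump())


class EmotionConfig(_StrictModel):
    enabled: bool = False
    c: float = 4.0
    k_e: float = 4.0

    def build(self) -> EmotionProfile:
        return EmotionProfile(**self.model_dump())


class ExperimentConfig(_StrictModel):
    """All parameters of one experiment.

    ``sigma``, ``T`` and the individual's ``p_r`` have no defaults: an
    experiment must state them.  ``seed`` may stay unset while editing a
    configuration but any simulation refuses to run without it.
    """

    p_r: float = Field(ge=0.0, le=1.0)
    sigma: float = Field(ge=0.0)
    s0: Union[float, Literal["uniform"]]
    T: int = Field(gt=0)
    N: int = Field(default=3000, ge=1)
    seed: int | None = None
    step: float = 0.01
    p_stay: float = 0.1
    shape: CurveShapeConfig = CurveShapeConfig()
    rewards: RewardConfig
    emotion: EmotionConfig = EmotionConfig()

    @field_validator("s0")
    @classmethod
    def _s0_in_range(cls, v):
        if isinstance(v, float) and not (0.0 < v < 1.0):
            raise ValueError("s0 must lie in (0, 1) or be 'uniform'")
        return v

    # -- builders for the domain objects ------------------------------------
    def grid(self) -> StateGrid:
        return StateGrid(step=self.step)

    def action_grid(self) -> StateGrid:
        return StateGrid(step=self.step)

    def curve_shape(self) -> CurveShape:
        return self.shape.build()

    def reward_params(self) -> RewardParams:
        return self.rewards.build()

    def emotion_profile(self) -> EmotionProfile:
        return self.emotion.build()

    def habitual_params(self) -> HabitualParams:
        return HabitualParams(p_r=self.p_r, sigma=self.sigma)

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigurationError(
                "no master seed set: simulations require an explicit seed "
                "for reproducibility (pass seed= or --seed)"
            )
        return int(self.seed)

    # -- serialization -------------------------------------------------------
    def hash(self) -> str:
        """Hash of every model parameter (the seed included)."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ExperimentConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"config source {source!r} is not a mapping")
        return cls.model_validate(data)


_FIG6 = {
    "p_r": 0.6,
    "sigma": 0.08,
    "s0": 0.2,
    "T": 100,
    "N": 3000,
    "rewards": {"alpha": 1.0, "beta": 1.5, "gamma": (3.0, 1.0, 0.1), "delta": 0.75},
    "emotion": {"enabled": False},
}

_EMOTION_REWARDS = {
    "alpha": 10.0,
    "beta": 20.0,
    "gamma": (3.7, 1.0, 0.01),
    "delta": 0.75,
}


def _emotion_run(p_r: float, s0: float) -> dict:
    return {
        "p_r": p_r,
        "sigma": 0.08,
        "s0": s0,
        "T": 300,
        "N": 3000,
        "rewards": dict(_EMOTION_REWARDS),
        "emotion": {"enabled": True},
    }


PRESETS: dict[str, dict] = {
    "fig6": _FIG6,
    # Analytical individual with emotions; the 'a' panel is the delta(s)
    # diagnostic of the low-start run.
    "fig7a": _emotion_run(0.8, 0.2),
    "fig7b": _emotion_run(0.8, 0.2),
    "fig7c": _emotion_run(0.8, 0.9),
    # Intuitive individual with emotions; the 'a' panel is the policy
    # matrix of the low-start run.
    "fig8a": _emotion_run(0.2, 0.2),
    "fig8b": _emotion_run(0.2, 0.2),
    "fig8c": _emotion_run(0.2, 0.9),
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def preset(name: str, **overrides) -> ExperimentConfig:
    """Build a named preset, optionally overriding fields (e.g. seed=1)."""
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; known presets: {', '.join(preset_names())}"
        )
    data = json.loads(json.dumps(PRESETS[name]))  # deep copy
    data.update(overrides)
    return ExperimentConfig.model_validate(data)


def load_config(source: str | Path, **overrides) -> ExperimentConfig:
    """Load a configuration from a preset name or a YAML file path."""
    if isinstance(source, str) and source in PRESETS:
        return preset(source, **overrides)
    cfg = ExperimentConfig.from_yaml(source)
    if overrides:
        cfg = cfg.model_copy(update=overrides)
    return cfg
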