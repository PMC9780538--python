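"""Stage reward, terminal reward, and the (possibly state- and
time-dependent) discount factor.

The stage reward is linear, ``r(s, u) = alpha*s - beta*u``: awareness is
good for overall well-being, analytical deliberation is costly.  The
terminal reward is a normalised exponential in the final state that
pushes the planner toward ending high.  With the emotion extension
enabled, the constant future weight ``delta`` is replaced by
``delta(s) * t / T`` where ``delta(s) = 1 - c*exp(-k_e*s)`` is negative
at low awareness (visceral immediacy overrides the future, harmfully)
and close to 1 at high awareness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import ConfigurationError

__all__ = [
    "RewardParams",
    "EmotionProfile",
    "stage_reward",
    "terminal_reward",
    "emotion_delta",
    "effective_discount",
]


@dataclass(frozen=True)
class RewardParams:
    """Scalar parameters of the reward structure.

    ``gamma`` holds the per-direction weights (up, stay, down) applied
    inside the Bellman backup; the model text restricts them to (0, 1)
    but every reported experiment uses values such as (3, 1, 0.1), so
    any positive values are accepted.
    """

    alpha: float = 1.0
    beta: float = 1.5
    gamma: tuple[float, float, float] = (3.0, 1.0, 0.1)
    delta: float = 0.75
    terminal_scale: float = 10.0
    terminal_rate: float = 5.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ConfigurationError("alpha and beta must be nonnegative")
        if len(self.gamma) != 3:
            raise ConfigurationError(
                f"gamma must have exactly 3 components, got {len(self.gamma)}"
            )
        if any(g <= 0 for g in self.gamma):
            raise ConfigurationError("gamma components must be positive")
        if not (0.0 < self.delta < 1.0):
            raise ConfigurationError(f"delta must lie in (0, 1), got {self.delta}")
        if self.terminal_scale < 0:
            raise ConfigurationError("terminal_scale must be nonnegative")

    @property
    def gamma_array(self) -> np.ndarray:
        return np.asarray(self.gamma, dtype=float)


@dataclass(frozen=True)
class EmotionProfile:
    """State-dependent discount curve ``delta(s) = 1 - c*exp(-k_e*s)``.

    ``c`` sets the depth of the low-awareness penalty (the curve is
    negative below s = ln(c)/k_e) and ``k_e`` the recovery rate toward 1.
    The defaults place the zero crossing near s = 0.35, so that an
    individual starting at s = 0.2 is inside the harmful regime — the
    condition under which emotions derail low-awareness planners while
    leaving aware ones nearly undiscounted (see docs/methods.md).
    """

    enabled: bool = False
    c: float = 4.0
    k_e: float = 4.0

    def __post_init__(self) -> None:
        if self.c < 0 or self.k_e <= 0:
            raise ConfigurationError("emotion profile needs c >= 0 and k_e > 0")


def stage_reward(s, u, params: RewardParams):
    """Linear stage reward ``alpha*s - beta*u``."""
    return params.alpha * np.asarray(s, dtype=float) - params.beta * np.asarray(
        u, dtype=float
    )


def terminal_reward(s, params: RewardParams):
    """Normalised exponential terminal reward.

    ``R * (exp(k*s) - 1) / (exp(k) - 1)``: zero at s = 0, ``R`` at s = 1,
    strictly increasing, and convex for k > 0 so that ending high is
    rewarded disproportionately.
    """
    s = np.asarray(s, dtype=float)
    k = params.terminal_rate
    if abs(k) < 1e-12:
        out = params.terminal_scale * s
    else:
        out = params.terminal_scale * np.expm1(k * s) / np.expm1(k)
    return out if out.ndim else float(out)


def emotion_delta(s, profile: EmotionProfile):
    """State-dependent discount ``1 - c*exp(-k_e*s)``."""
    out = 1.0 - profile.c * np.exp(-profile.k_e * np.asarray(s, dtype=float))
    return out if out.ndim else float(out)


def effective_discount(
    s,
    t: int,
    T: int,
    params: RewardParams,
    profile: EmotionProfile = EmotionProfile(),
):
    """Discount applied to the future term of the backup at stage ``t``.

    Emotions disabled: the constant ``delta``.  Enabled: the emotion
    curve scaled linearly in time, ``delta(s) * t / T`` — early epochs
    weigh the future little, and the weight at a given stage can be
    negative when awareness is low.
    """
    if T <= 0:
        raise ConfigurationError(f"horizon T must be positive, got {T}")
    s = np.asarray(s, dtype=float)
    if not profile.enabled:
        out = np.full_like(s, params.delta)
    else:
        out = np.asarray(emotion_delta(s, profile), dtype=float) * (t / T)
    return out if out.ndim else float(out)
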