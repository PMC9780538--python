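"""Habitual and self-aware (optimal) policies.

The habitual policy is pure noise around the individual's reasoning
propensity: at every epoch the decision is an independent draw
``e ~ Normal(p_r, sigma)`` clipped to the action range and snapped to the
action grid, regardless of state — the automatic, unaware mode.

The self-aware policy is computed by backward induction on the
finite-horizon problem

    max_mu  E[ sum_t r(s_t, mu(s_t, t)) + r(s_T) ]

with the direction-weighted backup used throughout the experiments::

    V_tau(s) = max_u  r(s, u)
               + D(s, tau) * [ gamma_1 * V_{tau+1}(s+) * p_up(u)
                             + gamma_2 * V_{tau+1}(s)  * p_stay
                             + gamma_3 * V_{tau+1}(s-) * p_down(u) ]

where ``s+``/``s-`` are the clamped neighbours and ``D`` is either the
constant ``delta`` or the emotion-modulated ``delta(s) * tau / T``.  The
gamma weights distort the expectation exactly as specified (they are not
renormalised); with gamma = (1, 1, 1) and constant D the backup reduces
to the textbook expected-value recursion.

The module exposes a generic array-level solver core
(:func:`solve_backward`, :func:`evaluate_policy`, :func:`q_values`) that
the exhaustive-enumeration oracle reuses, so tests can distinguish
solver bugs from backup-semantics mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import ConfigurationError, CurveShape, StateGrid, transition_matrix
from .rewards import EmotionProfile, RewardParams, emotion_delta, stage_reward, terminal_reward

__all__ = [
    "HabitualParams",
    "PolicyTable",
    "ValueTable",
    "habitual_action",
    "habitual_actions",
    "snap_to_grid",
    "q_values",
    "solve_backward",
    "evaluate_policy",
    "bellman_backup",
    "solve_sdp",
    "discount_matrix",
]


@dataclass(frozen=True)
class HabitualParams:
    """Parameters of the habitual (state-independent, noisy) policy."""

    p_r: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_r <= 1.0):
            raise ConfigurationError(f"p_r must lie in [0, 1], got {self.p_r}")
        if self.sigma < 0:
            raise ConfigurationError(f"sigma must be nonnegative, got {self.sigma}")


@dataclass(frozen=True)
class PolicyTable:
    """Deterministic decision table over (state, epoch).

    ``decisions[i, t]`` is the action value prescribed in state
    ``levels[i]`` at epoch ``t``; ``action_index`` holds the same policy
    as indices into ``actions``.
    """

    levels: np.ndarray
    actions: np.ndarray
    decisions: np.ndarray
    action_index: np.ndarray
    mode: str = "optimal"
    config_hash: str | None = None

    @property
    def horizon(self) -> int:
        return self.decisions.shape[1]


@dataclass(frozen=True)
class ValueTable:
    """Value function over (state, epoch 0..T); column T is the terminal reward."""

    levels: np.ndarray
    values: np.ndarray


def snap_to_grid(u, grid: StateGrid) -> np.ndarray:
    """Clip to the grid range and round to the nearest grid level."""
    u = np.clip(np.asarray(u, dtype=float), grid.lower, grid.upper)
    idx = np.rint((u - grid.lower) / grid.step).astype(int)
    return grid.levels[np.clip(idx, 0, grid.n - 1)]


def habitual_actions(
    params: HabitualParams,
    rng: np.random.Generator,
    size: int,
    grid: StateGrid = StateGrid(),
) -> np.ndarray:
    """Draw ``size`` habitual decisions (clipped Gaussian, grid-snapped)."""
    e = rng.normal(params.p_r, params.sigma, size)
    return snap_to_grid(e, grid)


def habitual_action(
    params: HabitualParams,
    rng: np.random.Generator,
    grid: StateGrid = StateGrid(),
) -> float:
    """One habitual decision; independent of state and epoch."""
    return float(habitual_actions(params, rng, 1, grid)[0])


# ---------------------------------------------------------------------------
# Array-level solver core, shared with the enumeration oracle.
# ---------------------------------------------------------------------------

def _neighbour_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(n)
    return np.minimum(idx + 1, n - 1), np.maximum(idx - 1, 0)


def q_values(
    v_next: np.ndarray,
    r_as: np.ndarray,
    rows: np.ndarray,
    gamma: np.ndarray,
    d_col: np.ndarray,
) -> np.ndarray:
    """Backup values Q[a, s] for one stage.

    ``v_next``: values at the next stage, shape (S,); ``r_as``: stage
    rewards, shape (A, S); ``rows``: (p_up, p_stay, p_down) per action,
    shape (A, 3); ``d_col``: per-state discount at this stage, shape (S,).
    Boundary moves use the clamped neighbour's value.
    """
    iup, idn = _neighbour_indices(len(v_next))
    future = (
        gamma[0] * np.outer(rows[:, 0], v_next[iup])
        + gamma[1] * np.outer(rows[:, 1], v_next)
        + gamma[2] * np.outer(rows[:, 2], v_next[idn])
    )
    return r_as + d_col[None, :] * future


def solve_backward(
    r_as: np.ndarray,
    rows: np.ndarray,
    terminal: np.ndarray,
    gamma: np.ndarray,
    d_st: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Backward induction over a horizon of ``T = d_st.shape[1]`` stages.

    Returns ``(policy_index, values)`` with shapes (S, T) and (S, T+1).
    Ties in the argmax break toward the smallest action index (the
    cheaper, less analytical decision), which is well defined because
    actions are ordered increasingly.
    """
    n_actions, n_states = r_as.shape
    horizon = d_st.shape[1]
    if n_actions == 0:
        raise ConfigurationError("empty action grid")
    values = np.empty((n_states, horizon + 1))
    values[:, horizon] = terminal
    policy = np.empty((n_states, horizon), dtype=np.int64)
    for tau in range(horizon - 1, -1, -1):
        q = q_values(values[:, tau + 1], r_as, rows, gamma, d_st[:, tau])
        best = np.argmax(q, axis=0)  # first maximum = smallest u on ties
        policy[:, tau] = best
        values[:, tau] = q[best, np.arange(n_states)]
    return policy, values


def evaluate_policy(
    policy_index: np.ndarray,
    r_as: np.ndarray,
    rows: np.ndarray,
    terminal: np.ndarray,
    gamma: np.ndarray,
    d_st: np.ndarray,
) -> np.ndarray:
    """Value of a fixed deterministic policy under the same backup semantics.

    Shares :func:`q_values` with the solver, so the number it returns is
    exactly the objective the solver maximises.
    """
    n_states, horizon = policy_index.shape
    values = np.empty((n_states, horizon + 1))
    values[:, horizon] = terminal
    rng_states = np.arange(n_states)
    for tau in range(horizon - 1, -1, -1):
        q = q_values(values[:, tau + 1], r_as, rows, gamma, d_st[:, tau])
        values[:, tau] = q[policy_index[:, tau], rng_states]
    return values


# ---------------------------------------------------------------------------
# Model-level wrappers.
# ---------------------------------------------------------------------------

def discount_matrix(
    levels: np.ndarray,
    horizon: int,
    params: RewardParams,
    profile: EmotionProfile,
) -> np.ndarray:
    """Per-(state, stage) discount D(s, tau), shape (S, T)."""
    if horizon <= 0:
        raise ConfigurationError(f"horizon T must be positive, got {horizon}")
    if not profile.enabled:
        return np.full((len(levels), horizon), params.delta)
    taus = np.arange(horizon) / horizon
    return np.outer(emotion_delta(levels, profile), taus)


def _model_arrays(config) -> dict:
    """Assemble the array inputs of the solver core from a configuration."""
    grid: StateGrid = config.grid()
    agrid: StateGrid = config.action_grid()
    shape: CurveShape = config.curve_shape()
    params: RewardParams = config.reward_params()
    profile: EmotionProfile = config.emotion_profile()
    levels = grid.levels
    actions = agrid.levels
    rows = transition_matrix(actions, config.p_r, shape, config.p_stay)
    r_as = stage_reward(levels[None, :], actions[:, None], params)
    term = terminal_reward(levels, params)
    d_st = discount_matrix(levels, config.T, params, profile)
    return {
        "levels": levels,
        "actions": actions,
        "rows": rows,
        "r_as": r_as,
        "terminal": term,
        "gamma": params.gamma_array,
        "d_st": d_st,
    }


def solve_sdp(config) -> tuple[PolicyTable, ValueTable]:
    """Compute the self-aware (optimal) policy for a configuration.

    Deterministic: no randomness enters the backward induction, so the
    result is bit-reproducible for a fixed configuration.
    """
    arr = _model_arrays(config)
    pol_idx, values = solve_backward(
        arr["r_as"], arr["rows"], arr["terminal"], arr["gamma"], arr["d_st"]
    )
    policy = PolicyTable(
        levels=arr["levels"],
        actions=arr["actions"],
        decisions=arr["actions"][pol_idx],
        action_index=pol_idx,
        mode="optimal",
        config_hash=config.hash(),
    )
    return policy, ValueTable(levels=arr["levels"], values=values)


def bellman_backup(s: float, u: float, v_next: np.ndarray, tau: int, config) -> float:
    """Single (state, action) backup value at stage ``tau``.

    ``v_next`` must be defined on the full state grid (epoch tau+1).
    """
    arr = _model_arrays(config)
    grid = config.grid()
    agrid = config.action_grid()
    si = grid.index_of(s)
    ai = agrid.index_of(u)
    q = q_values(
        np.asarray(v_next, dtype=float),
        arr["r_as"][ai : ai + 1],
        arr["rows"][ai : ai + 1],
        arr["gamma"],
        arr["d_st"][:, tau],
    )
    return float(q[0, si])
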