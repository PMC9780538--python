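"""Exact reference computations used for testing the solver and simulator.

Two oracles live here:

* :func:`propagate_exact` pushes the full state-occupancy vector through
  the kernel epoch by epoch, giving the exact per-epoch state
  distribution, mean state/decision paths and the exact (unweighted)
  expected cumulative reward of a policy — the infinite-N limit of the
  Monte Carlo ensemble.

* :class:`TinyInstance` plus :func:`exhaustive_best_policy` enumerate
  every deterministic (state, epoch) -> action mapping of a reduced
  problem and evaluate each with the solver's own backup semantics
  (:func:`awaremdp.policies.evaluate_policy`), so the backward-induction
  solution can be checked against a brute-force maximum.  A separate
  plain-expectation evaluator, implemented independently by forward
  propagation, cross-checks the gamma = (1, 1, 1), constant-discount
  case where the distorted backup reduces to a textbook expectation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .kernel import ConfigurationError, transition_matrix
from .policies import HabitualParams, evaluate_policy, solve_backward
from .rewards import stage_reward, terminal_reward
from .simulate import PolicyLike

__all__ = [
    "ExactPropagation",
    "propagate_exact",
    "habitual_action_pmf",
    "TinyInstance",
    "random_instance",
    "exhaustive_best_policy",
    "plain_expected_return",
]


# ---------------------------------------------------------------------------
# Exact distribution propagation for the full model.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExactPropagation:
    """Exact epoch-by-epoch distribution of the awareness state."""

    distributions: np.ndarray  # (T+1, S) occupancy vectors
    mean_state: np.ndarray  # (T+1,)
    mean_decision: np.ndarray  # (T,)
    expected_stage_reward: np.ndarray  # (T,)
    expected_cumulative_reward: float  # unweighted, incl. terminal


def habitual_action_pmf(params: HabitualParams, agrid) -> np.ndarray:
    """Exact pmf of the clipped, grid-snapped Gaussian habitual decision.

    Interior grid points collect the Gaussian mass of their half-step
    band; the first and last points additionally absorb the clipped
    tails, matching the clip-then-snap sampling contract exactly.
    """
    edges = np.concatenate(
        [[-np.inf], agrid.levels[:-1] + agrid.step / 2.0, [np.inf]]
    )
    if params.sigma == 0.0:
        pmf = np.zeros(agrid.n)
        pmf[np.searchsorted(edges, params.p_r, side="right") - 1] = 1.0
        return pmf
    cdf = norm.cdf(edges, loc=params.p_r, scale=params.sigma)
    return np.diff(cdf)


def _push(dist: np.ndarray, p_up: np.ndarray, p_stay: np.ndarray, p_down: np.ndarray) -> np.ndarray:
    """One clamped birth/stay/death step of the occupancy vector."""
    nxt = dist * p_stay
    nxt[1:] += (dist * p_up)[:-1]
    nxt[-1] += dist[-1] * p_up[-1]  # clamped top: an up-move stays put
    nxt[:-1] += (dist * p_down)[1:]
    nxt[0] += dist[0] * p_down[0]  # clamped bottom
    return nxt


def propagate_exact(policy: PolicyLike, config) -> ExactPropagation:
    """Exact forward propagation of the state distribution under a policy.

    For a deterministic :class:`PolicyTable` the kernel row at each state
    is the row of the prescribed action; for :class:`HabitualParams` the
    state-independent action distribution is marginalised out of the
    kernel, which is exact because decisions are drawn independently of
    the state and the shock.
    """
    grid = config.grid()
    agrid = config.action_grid()
    levels = grid.levels
    horizon = config.T
    params = config.reward_params()
    rows = transition_matrix(agrid.levels, config.p_r, config.curve_shape(), config.p_stay)

    dist = np.zeros(grid.n)
    if config.s0 == "uniform":
        dist[:] = 1.0 / grid.n
    else:
        dist[grid.index_of(float(config.s0))] = 1.0

    habitual = isinstance(policy, HabitualParams)
    if habitual:
        pmf = habitual_action_pmf(policy, agrid)
        row_bar = pmf @ rows  # marginal kernel, same in every state
        u_bar = float(pmf @ agrid.levels)

    dists = np.empty((horizon + 1, grid.n))
    dists[0] = dist
    mean_dec = np.empty(horizon)
    exp_stage = np.empty(horizon)
    for t in range(horizon):
        if habitual:
            p_up = np.full(grid.n, row_bar[0])
            p_stay = np.full(grid.n, row_bar[1])
            p_down = np.full(grid.n, row_bar[2])
            mean_dec[t] = u_bar
            exp_stage[t] = float(dist @ (params.alpha * levels) - params.beta * u_bar)
        else:
            a_idx = policy.action_index[:, t]
            p_up, p_stay, p_down = rows[a_idx].T
            u_t = policy.decisions[:, t]
            mean_dec[t] = float(dist @ u_t)
            exp_stage[t] = float(dist @ stage_reward(levels, u_t, params))
        dist = _push(dist, p_up, p_stay, p_down)
        dists[t + 1] = dist

    total = float(exp_stage.sum() + dist @ terminal_reward(levels, params))
    return ExactPropagation(
        distributions=dists,
        mean_state=dists @ levels,
        mean_decision=mean_dec,
        expected_stage_reward=exp_stage,
        expected_cumulative_reward=total,
    )


# ---------------------------------------------------------------------------
# Tiny instances and exhaustive policy enumeration.
# ---------------------------------------------------------------------------

MAX_ENUMERATION = 1_000_000


@dataclass(frozen=True)
class TinyInstance:
    """A reduced finite-horizon problem small enough to enumerate.

    Kernel rows are per-action (state-independent, as in the full
    model), rewards are an arbitrary (action, state) table, and the
    discount is an arbitrary per-(state, stage) matrix so that both the
    constant-delta and the emotion-modulated regimes can be represented.
    """

    levels: np.ndarray  # (S,)
    rows: np.ndarray  # (A, 3)
    r_as: np.ndarray  # (A, S)
    terminal: np.ndarray  # (S,)
    gamma: np.ndarray  # (3,)
    d_st: np.ndarray  # (S, T)

    def __post_init__(self) -> None:
        sums = self.rows.sum(axis=1)
        if np.any(self.rows < -1e-12) or np.any(np.abs(sums - 1.0) > 1e-9):
            raise ConfigurationError("tiny-instance rows must be row-stochastic")
        if self.enumeration_size > MAX_ENUMERATION:
            raise ConfigurationError(
                f"enumeration size {self.enumeration_size} exceeds "
                f"{MAX_ENUMERATION}"
            )

    @property
    def n_states(self) -> int:
        return len(self.levels)

    @property
    def n_actions(self) -> int:
        return self.rows.shape[0]

    @property
    def horizon(self) -> int:
        return self.d_st.shape[1]

    @property
    def enumeration_size(self) -> int:
        return self.n_actions ** (self.n_states * self.horizon)

    def solve(self) -> tuple[np.ndarray, np.ndarray]:
        """Backward-induction solution (policy indices, values)."""
        return solve_backward(self.r_as, self.rows, self.terminal, self.gamma, self.d_st)

    def evaluate(self, policy_index: np.ndarray) -> np.ndarray:
        """Value of a fixed policy under the solver's backup semantics."""
        return evaluate_policy(
            policy_index, self.r_as, self.rows, self.terminal, self.gamma, self.d_st
        )

    # JSON fixtures -------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        data = {
            "levels": self.levels.tolist(),
            "rows": self.rows.tolist(),
            "r_as": self.r_as.tolist(),
            "terminal": self.terminal.tolist(),
            "gamma": self.gamma.tolist(),
            "d_st": self.d_st.tolist(),
        }
        text = json.dumps(data, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TinyInstance":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        return cls(**{k: np.asarray(v, dtype=float) for k, v in data.items()})


def random_instance(
    rng: np.random.Generator,
    n_states: int = 3,
    n_actions: int = 3,
    horizon: int = 3,
    emotion: bool = False,
    gamma: tuple[float, float, float] | None = None,
) -> TinyInstance:
    """Draw a random valid instance.

    ``emotion=True`` uses an emotion-style discount ``delta(s) * tau/T``
    on levels where the emotion curve is nonnegative (backward induction
    is only guaranteed optimal for nonnegative discount weights).
    """
    levels = np.linspace(0.5, 0.9, n_states)
    rows = rng.dirichlet(np.ones(3), size=n_actions)
    r_as = rng.uniform(-2.0, 2.0, size=(n_states * n_actions)).reshape(n_actions, n_states)
    term = rng.uniform(0.0, 5.0, size=n_states)
    if gamma is None:
        g = rng.uniform(0.05, 4.0, size=3)
    else:
        g = np.asarray(gamma, dtype=float)
    if emotion:
        delta_s = 1.0 - 4.0 * np.exp(-4.0 * levels)
        d_st = np.outer(delta_s, np.arange(horizon) / horizon)
    else:
        d_st = np.full((n_states, horizon), rng.uniform(0.2, 0.95))
    return TinyInstance(
        levels=levels, rows=rows, r_as=r_as, terminal=term, gamma=g, d_st=d_st
    )


def exhaustive_best_policy(instance: TinyInstance) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate every deterministic policy and return the best.

    Returns ``(best_policy_index, best_values)`` where ``best_values[s]``
    is the maximum over all policies of the epoch-0 value at state ``s``
    (evaluated with the solver's backup semantics).  Refuses instances
    beyond the enumeration bound.
    """
    n_cells = instance.n_states * instance.horizon
    best_vals = np.full(instance.n_states, -np.inf)
    best_pol = None
    for combo in itertools.product(range(instance.n_actions), repeat=n_cells):
        pol = np.asarray(combo, dtype=np.int64).reshape(
            instance.n_states, instance.horizon
        )
        v0 = instance.evaluate(pol)[:, 0]
        if v0.sum() > best_vals.sum():
            best_pol = pol
        best_vals = np.maximum(best_vals, v0)
    return best_pol, best_vals


def plain_expected_return(instance: TinyInstance, policy_index: np.ndarray) -> np.ndarray:
    """Independent plain-expectation evaluator for the undistorted case.

    Computes ``E[sum_t delta^t r_t + delta^T r_T]`` by forward
    propagation of the occupancy vector from every initial state.  Only
    meaningful when ``gamma = (1, 1, 1)`` and the discount matrix is a
    constant ``delta``; deliberately shares no code with the backup.
    """
    if not np.allclose(instance.gamma, 1.0):
        raise ValueError("plain expectation requires gamma = (1, 1, 1)")
    delta = float(instance.d_st.flat[0])
    if not np.allclose(instance.d_st, delta):
        raise ValueError("plain expectation requires a constant discount")
    S, T = instance.n_states, instance.horizon
    out = np.empty(S)
    for s0 in range(S):
        dist = np.zeros(S)
        dist[s0] = 1.0
        total = 0.0
        for t in range(T):
            a_idx = policy_index[:, t]
            r_t = instance.r_as[a_idx, np.arange(S)]
            total += delta**t * float(dist @ r_t)
            p_up, p_stay, p_down = instance.rows[a_idx].T
            dist = _push(dist, p_up, p_stay, p_down)
        total += delta**T * float(dist @ instance.terminal)
        out[s0] = total
    return out
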