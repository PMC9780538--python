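"""Monte Carlo trajectory simulation and ensemble aggregation.

A trajectory realises the controlled random walk: starting from the
configured initial state (a fixed level, or a uniform draw from the
grid), at every epoch the decision comes from the policy (a
:class:`~awaremdp.policies.PolicyTable` looked up at the current state,
or a fresh habitual draw), the transition row for that decision is
evaluated, a shock in {+1, 0, -1} is sampled, and the state takes one
clamped grid step.  Stage rewards are recorded unweighted — the gamma
and discount weights belong to the planner's objective only — and the
terminal reward is added at the horizon.

Reproducibility contract: every run consumes its own
``numpy.random.Generator`` built from
``SeedSequence(master_seed).spawn(N)``, so run ``i`` of an ensemble is
bit-identical to ``run_trajectory`` with that run's child seed, and a
(config, master_seed) pair fully determines every reported number.
Within a run the stream is consumed in a fixed order: the uniform
initial-state draw (if any), then the T habitual decision draws (if the
policy is habitual), then the T shock uniforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .kernel import transition_matrix
from .policies import HabitualParams, PolicyTable, snap_to_grid, solve_sdp
from .rewards import stage_reward, terminal_reward

__all__ = [
    "Trajectory",
    "EnsembleSummary",
    "PolicyComparison",
    "run_trajectory",
    "run_ensemble",
    "compare_policies",
]

PolicyLike = Union[PolicyTable, HabitualParams]


@dataclass(frozen=True)
class Trajectory:
    """One realised path of states, decisions, shocks and rewards."""

    states: np.ndarray  # (T+1,) awareness levels
    decisions: np.ndarray  # (T,) actions taken
    shocks: np.ndarray  # (T,) in {+1, 0, -1}
    stage_rewards: np.ndarray  # (T,)
    terminal_reward: float
    seed: object  # int or numpy SeedSequence (an ensemble child seed)

    @property
    def cumulative_reward(self) -> float:
        return float(self.stage_rewards.sum() + self.terminal_reward)


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-epoch ensemble means with standard errors of the mean."""

    n_runs: int
    state_mean: np.ndarray  # (T+1,)
    state_se: np.ndarray
    decision_mean: np.ndarray  # (T,)
    decision_se: np.ndarray
    reward_mean: np.ndarray  # (T,) stage rewards
    reward_se: np.ndarray
    cum_reward_mean: np.ndarray  # (T+1,) running sum incl. terminal at T
    final_state_mean: float
    final_state_se: float
    mean_cumulative_reward: float
    config_hash: str | None = None
    mode: str = ""

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_runs": self.n_runs,
            "final_state_mean": self.final_state_mean,
            "final_state_se": self.final_state_se,
            "mean_cumulative_reward": self.mean_cumulative_reward,
            "state_mean": self.state_mean.tolist(),
            "state_se": self.state_se.tolist(),
            "decision_mean": self.decision_mean.tolist(),
            "decision_se": self.decision_se.tolist(),
            "reward_mean": self.reward_mean.tolist(),
            "reward_se": self.reward_se.tolist(),
            "cum_reward_mean": self.cum_reward_mean.tolist(),
            "config_hash": self.config_hash,
        }


@dataclass(frozen=True)
class PolicyComparison:
    """Paired habitual vs self-aware summaries on a shared epoch axis."""

    habitual: EnsembleSummary
    optimal: EnsembleSummary

    @property
    def state_mean_difference(self) -> np.ndarray:
        return self.optimal.state_mean - self.habitual.state_mean

    @property
    def decision_mean_difference(self) -> np.ndarray:
        return self.optimal.decision_mean - self.habitual.decision_mean


def _simulate_batch(policy: PolicyLike, config, seeds) -> dict:
    """Simulate one trajectory per seed; vectorised across runs.

    Each run gets its own Generator and consumes draws in the documented
    order, so results are independent of the batch layout.
    """
    grid = config.grid()
    agrid = config.action_grid()
    levels = grid.levels
    n_states = grid.n
    horizon = config.T
    rows = transition_matrix(
        agrid.levels, config.p_r, config.curve_shape(), config.p_stay
    )
    thresh_up = rows[:, 0]
    thresh_stay = rows[:, 0] + rows[:, 1]
    n_runs = len(seeds)

    habitual = isinstance(policy, HabitualParams)
    if not habitual and policy.decisions.shape != (n_states, horizon):
        raise ValueError(
            f"policy table shape {policy.decisions.shape} does not match "
            f"grid/horizon ({n_states}, {horizon})"
        )

    s0_uniform = config.s0 == "uniform"
    if not s0_uniform:
        s0_idx_fixed = grid.index_of(float(config.s0))

    s_idx = np.empty(n_runs, dtype=np.int64)
    shock_u = np.empty((n_runs, horizon))
    dec_idx_habitual = np.empty((n_runs, horizon), dtype=np.int64) if habitual else None
    for i, seed in enumerate(seeds):
        rng = np.random.Generator(np.random.PCG64(seed))
        s_idx[i] = rng.integers(n_states) if s0_uniform else s0_idx_fixed
        if habitual:
            e = snap_to_grid(rng.normal(policy.p_r, policy.sigma, horizon), agrid)
            dec_idx_habitual[i] = np.rint((e - agrid.lower) / agrid.step).astype(int)
        shock_u[i] = rng.random(horizon)

    states_idx = np.empty((n_runs, horizon + 1), dtype=np.int64)
    decisions_idx = np.empty((n_runs, horizon), dtype=np.int64)
    shocks = np.empty((n_runs, horizon), dtype=np.int8)
    states_idx[:, 0] = s_idx
    for t in range(horizon):
        if habitual:
            a_idx = dec_idx_habitual[:, t]
        else:
            a_idx = policy.action_index[s_idx, t]
        x = shock_u[:, t]
        w = np.where(x < thresh_up[a_idx], 1, np.where(x < thresh_stay[a_idx], 0, -1))
        s_idx = np.clip(s_idx + w, 0, n_states - 1)
        decisions_idx[:, t] = a_idx
        shocks[:, t] = w
        states_idx[:, t + 1] = s_idx

    params = config.reward_params()
    states = levels[states_idx]
    decisions = agrid.levels[decisions_idx]
    stage = stage_reward(states[:, :-1], decisions, params)
    term = terminal_reward(states[:, -1], params)
    return {
        "states": states,
        "decisions": decisions,
        "shocks": shocks.astype(np.int64),
        "stage_rewards": stage,
        "terminal_rewards": np.atleast_1d(term),
    }


def _resolve_policy(policy: PolicyLike | str, config) -> PolicyLike:
    if isinstance(policy, str):
        if policy == "habitual":
            return config.habitual_params()
        if policy == "optimal":
            return solve_sdp(config)[0]
        raise ValueError(f"unknown policy mode {policy!r}")
    return policy


def run_trajectory(policy: PolicyLike | str, config, seed: int | None = None) -> Trajectory:
    """Simulate a single trajectory.

    ``seed`` defaults to the configuration's master seed; a missing seed
    is an error — reproducibility is mandatory.
    """
    if seed is None:
        seed = config.require_seed()
    policy = _resolve_policy(policy, config)
    out = _simulate_batch(policy, config, [seed])
    return Trajectory(
        states=out["states"][0],
        decisions=out["decisions"][0],
        shocks=out["shocks"][0],
        stage_rewards=out["stage_rewards"][0],
        terminal_reward=float(out["terminal_rewards"][0]),
        seed=seed,
    )


def _summarise(out: dict, config, mode: str) -> EnsembleSummary:
    states = out["states"]
    decisions = out["decisions"]
    stage = out["stage_rewards"]
    term = out["terminal_rewards"]
    n = states.shape[0]
    scale = np.sqrt(n) if n > 1 else 1.0

    def se(a: np.ndarray) -> np.ndarray:
        if n == 1:
            return np.zeros(a.shape[1])
        return a.std(axis=0, ddof=1) / scale

    cum = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(stage, axis=1)], axis=1
    )
    cum[:, -1] += term
    return EnsembleSummary(
        n_runs=n,
        state_mean=states.mean(axis=0),
        state_se=se(states),
        decision_mean=decisions.mean(axis=0),
        decision_se=se(decisions),
        reward_mean=stage.mean(axis=0),
        reward_se=se(stage),
        cum_reward_mean=cum.mean(axis=0),
        final_state_mean=float(states[:, -1].mean()),
        final_state_se=float(se(states)[-1]) if n > 1 else 0.0,
        mean_cumulative_reward=float(cum[:, -1].mean()),
        config_hash=config.hash(),
        mode=mode,
    )


def run_ensemble(
    policy: PolicyLike | str,
    config,
    n_runs: int | None = None,
    master_seed: int | None = None,
) -> EnsembleSummary:
    """Simulate ``n_runs`` independent trajectories and aggregate them.

    Per-run seeds are spawned from ``SeedSequence(master_seed)``; the
    master seed defaults to the configuration's seed and must exist.
    """
    if master_seed is None:
        master_seed = config.require_seed()
    if n_runs is None:
        n_runs = config.N
    policy = _resolve_policy(policy, config)
    mode = "habitual" if isinstance(policy, HabitualParams) else policy.mode
    seeds = np.random.SeedSequence(master_seed).spawn(n_runs)
    out = _simulate_batch(policy, config, seeds)
    return _summarise(out, config, mode)


def compare_policies(
    config,
    n_runs: int | None = None,
    master_seed: int | None = None,
) -> PolicyComparison:
    """Run paired habitual and self-aware ensembles from one configuration.

    Both ensembles use the same spawned seed set, so the comparison is
    a common-random-numbers pairing on a shared epoch axis.
    """
    if master_seed is None:
        master_seed = config.require_seed()
    habitual = run_ensemble("habitual", config, n_runs, master_seed)
    optimal = run_ensemble("optimal", config, n_runs, master_seed)
    return PolicyComparison(habitual=habitual, optimal=optimal)
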