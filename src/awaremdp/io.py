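"""Result serialization: tidy CSV tables, JSON summaries, run bundles."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .kernel import transition_matrix
from .policies import PolicyTable, ValueTable, solve_sdp
from .rewards import emotion_delta, terminal_reward
from .simulate import EnsembleSummary, PolicyComparison, compare_policies, _simulate_batch

__all__ = [
    "curves_frame",
    "reward_curves_frame",
    "policy_frame",
    "value_frame",
    "trajectories_frame",
    "summary_payload",
    "run_experiment",
]


def curves_frame(config: ExperimentConfig) -> pd.DataFrame:
    """Transition-probability diagnostics over the action grid.

    Columns: u, p_up, p_stay, p_down, p_r — the realised mixture curves,
    for visual comparison with the model's forward/stationary/backward
    probability sketches.
    """
    agrid = config.action_grid()
    rows = transition_matrix(agrid.levels, config.p_r, config.curve_shape(), config.p_stay)
    return pd.DataFrame(
        {
            "u": agrid.levels,
            "p_up": rows[:, 0],
            "p_stay": rows[:, 1],
            "p_down": rows[:, 2],
            "p_r": config.p_r,
        }
    )


def reward_curves_frame(config: ExperimentConfig) -> pd.DataFrame:
    """Terminal-reward and emotion-discount curves over the state grid."""
    grid = config.grid()
    params = config.reward_params()
    profile = config.emotion_profile()
    return pd.DataFrame(
        {
            "s": grid.levels,
            "terminal_reward": terminal_reward(grid.levels, params),
            "emotion_delta": emotion_delta(grid.levels, profile),
        }
    )


def policy_frame(policy: PolicyTable) -> pd.DataFrame:
    """Policy matrix as CSV-ready frame: rows = states, columns = epochs."""
    return pd.DataFrame(
        policy.decisions,
        index=pd.Index(policy.levels, name="state"),
        columns=[f"t{t}" for t in range(policy.horizon)],
    )


def value_frame(table: ValueTable) -> pd.DataFrame:
    return pd.DataFrame(
        table.values,
        index=pd.Index(table.levels, name="state"),
        columns=[f"t{t}" for t in range(table.values.shape[1])],
    )


def trajectories_frame(policy, config: ExperimentConfig, n_runs: int) -> pd.DataFrame:
    """Tidy long-format realisations: run, epoch, state, decision, shock, stage_reward."""
    seeds = np.random.SeedSequence(config.require_seed()).spawn(n_runs)
    out = _simulate_batch(policy, config, seeds)
    horizon = config.T
    run_idx = np.repeat(np.arange(n_runs), horizon)
    epoch = np.tile(np.arange(horizon), n_runs)
    return pd.DataFrame(
        {
            "run": run_idx,
            "epoch": epoch,
            "state": out["states"][:, :-1].ravel(),
            "decision": out["decisions"].ravel(),
            "shock": out["shocks"].ravel(),
            "stage_reward": out["stage_rewards"].ravel(),
        }
    )


def summary_payload(comparison: PolicyComparison, config: ExperimentConfig) -> dict:
    """JSON-ready summary of a paired habitual/self-aware experiment."""
    return {
        "config": config.model_dump(mode="json"),
        "config_hash": config.hash(),
        "seed": config.seed,
        "habitual": comparison.habitual.to_dict(),
        "optimal": comparison.optimal.to_dict(),
        "final_state_difference": float(
            comparison.optimal.final_state_mean - comparison.habitual.final_state_mean
        ),
    }


def run_experiment(
    config: ExperimentConfig,
    outdir: str | Path,
    n_trajectories_csv: int = 20,
) -> Path:
    """Run the full paired experiment for a configuration and write a bundle.

    Writes the policy/value matrices, paired ensemble summaries,
    probability- and reward-curve diagnostics, a thinned trajectory
    table, the configuration echo, and a log carrying the configuration
    hash, seed and wall time.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    config.require_seed()

    policy, values = solve_sdp(config)
    comparison = compare_policies(config)

    config.to_yaml(outdir / "config.yaml")
    policy_frame(policy).to_csv(outdir / "policy.csv")
    value_frame(values).to_csv(outdir / "value.csv")
    curves_frame(config).to_csv(outdir / "transition_curves.csv", index=False)
    reward_curves_frame(config).to_csv(outdir / "reward_curves.csv", index=False)
    trajectories_frame(policy, config, min(n_trajectories_csv, config.N)).to_csv(
        outdir / "trajectories_optimal.csv", index=False
    )
    payload = summary_payload(comparison, config)
    (outdir / "summary.json").write_text(json.dumps(payload, indent=1))
    (outdir / "run.log").write_text(
        "\n".join(
            [
                f"config_hash: {config.hash()}",
                f"seed: {config.seed}",
                f"n_runs: {comparison.optimal.n_runs}",
                f"wall_time_s: {time.time() - t0:.2f}",
                f"timestamp: {time.strftime('%Y-%m-%dT%H:%M:%S')}",
            ]
        )
        + "\n"
    )
    return outdir
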