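"""Trial structure of the aversion-reward conflict (ARC) task.

The task is a repeated binary choice between a safe option (a guaranteed
$0.01, no aversive stimulation) and a risky option paying $0.05-$0.95 with a
10%, 50% or 90% chance of aversive stimulation.  Risk levels are
counterbalanced (equal trial counts per level) and rewards are sampled
uniformly over the cent grid within each risk level.  The reward enters the
choice model as a standardized (mean-0, SD-1) continuous predictor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "generate_design",
    "normalize_reward",
    "read_design",
    "write_design",
    "RISK_LEVELS",
    "N_TRIALS",
    "REWARD_MIN",
    "REWARD_MAX",
]

RISK_LEVELS = (0.10, 0.50, 0.90)
N_TRIALS = 108
REWARD_MIN = 0.05
REWARD_MAX = 0.95


class DesignError(ValueError):
    """Raised when a requested trial design is infeasible."""


def _on_cent_grid(x: float) -> bool:
    cents = x * 100.0
    return abs(cents - round(cents)) < 1e-9


def normalize_reward(rewards, ddof: int = 0) -> np.ndarray:
    """Standardize rewards to mean 0, SD 1.

    Parameters
    ----------
    rewards : array-like of float
        Reward values in dollars (length >= 2, not all identical).
    ddof : int
        0 for the population-SD convention (default; gives exactly unit SD
        for the fixed design) or 1 for the sample-SD convention.

    Returns
    -------
    ndarray of dimensionless standardized rewards.
    """
    r = np.asarray(rewards, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two rewards to standardize")
    sd = r.std(ddof=ddof)
    if sd == 0.0:
        raise ValueError("rewards are constant: zero variance, cannot standardize")
    return (r - r.mean()) / sd


def generate_design(
    n_trials: int = N_TRIALS,
    risk_levels=RISK_LEVELS,
    reward_min: float = REWARD_MIN,
    reward_max: float = REWARD_MAX,
    seed: int = 0,
    ddof: int = 0,
) -> pd.DataFrame:
    """Build the fixed trial sequence shared by all participants.

    Rewards are drawn stratified-uniformly (with replacement) from the cent
    grid within each risk level, risk levels are counterbalanced, and the
    trial order is a seeded permutation.  Reproducible bit-for-bit given the
    seed.

    Returns a DataFrame with columns ``trial`` (1-based), ``risk``,
    ``reward`` and ``reward_z``.
    """
    risk_levels = tuple(sorted(risk_levels))
    if len(risk_levels) == 0 or n_trials <= 0:
        raise ValueError("need at least one trial and one risk level")
    if n_trials % len(risk_levels) != 0:
        raise DesignError(
            f"{n_trials} trials cannot be counterbalanced over "
            f"{len(risk_levels)} risk levels"
        )
    if reward_min > reward_max:
        raise ValueError("reward_min must not exceed reward_max")
    if not (_on_cent_grid(reward_min) and _on_cent_grid(reward_max)):
        raise ValueError("reward bounds must be integer numbers of cents")

    rng = np.random.default_rng(seed)
    per_level = n_trials // len(risk_levels)
    lo, hi = round(reward_min * 100), round(reward_max * 100)
    grid = np.arange(lo, hi + 1)  # cents

    risk = np.repeat(risk_levels, per_level)
    reward_cents = np.concatenate(
        [rng.choice(grid, size=per_level, replace=True) for _ in risk_levels]
    )
    order = rng.permutation(n_trials)
    risk, reward_cents = risk[order], reward_cents[order]
    reward = reward_cents / 100.0

    df = pd.DataFrame(
        {
            "trial": np.arange(1, n_trials + 1),
            "risk": risk,
            "reward": reward,
        }
    )
    if n_trials >= 2 and reward.std() > 0:
        df["reward_z"] = normalize_reward(reward, ddof=ddof)
    else:
        df["reward_z"] = 0.0
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"trial", "risk", "reward", "reward_z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design file missing columns: {sorted(missing)}")
    return df
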