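"""Synthetic reward processes used in the simulation experiments.

Generators are deterministic given their seed and return the latent
state alongside the observations, since the tracking benchmark scores
predictions against the latent mean rather than the noisy rewards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DriftingGaussianParams",
    "PavlovianScheduleParams",
    "DiscreteRewardDistribution",
    "RewardTrajectory",
    "generate_drifting_rewards",
    "generate_pavlovian_schedule",
    "distribution_moments",
    "UNIFORM_LIKE_DISTRIBUTION",
    "NORMAL_LIKE_DISTRIBUTION",
]


@dataclass(frozen=True)
class DriftingGaussianParams:
    """Random-walk latent mean (sd ``nu`` per step) observed with noise ``sigma``."""

    mu0: float = 0.0
    nu: float = 1.0
    sigma: float = 1.0
    n_trials: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.nu < 0 or self.sigma < 0:
            raise ValueError("nu and sigma must be nonnegative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class RewardTrajectory:
    """Latent means ``mu`` and observed rewards ``r``, with provenance."""

    mu: np.ndarray
    r: np.ndarray
    params: DriftingGaussianParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial": np.arange(self.mu.size), "mu": self.mu, "r": self.r}
        )


def generate_drifting_rewards(params: DriftingGaussianParams) -> RewardTrajectory:
    """Simulate ``r_t ~ N(mu_t, sigma)`` with ``mu_{t+1} ~ N(mu_t, nu)``."""
    rng = np.random.default_rng(params.seed)
    n = params.n_trials
    steps = params.nu * rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    mu = params.mu0 + np.concatenate(([0.0], np.cumsum(steps)))
    r = mu + params.sigma * rng.standard_normal(n)
    return RewardTrajectory(mu=mu, r=r, params=params)


@dataclass(frozen=True)
class PavlovianScheduleParams:
    """Block-balanced binary reward schedule with fixed magnitude.

    Each aligned block of ``block_size`` trials contains exactly
    ``block_size * p_reward`` rewarded trials in a uniformly shuffled
    order, so a 50% schedule has two rewarded and two unrewarded trials
    in every four successive (aligned) trials.
    """

    magnitude: float
    p_reward: float = 0.5
    block_size: int = 4
    n_trials: int = 2000
    n_discard: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_reward <= 1:
            raise ValueError("p_reward must be in [0, 1]")
        if self.block_size < 1 or self.n_trials < 1:
            raise ValueError("block_size and n_trials must be >= 1")
        n_rewarded = self.block_size * self.p_reward
        if abs(n_rewarded - round(n_rewarded)) > 1e-9:
            raise ValueError(
                f"block_size * p_reward = {n_rewarded} is not an integer; "
                "the balanced-block schedule is not constructible"
            )
        if not 0 <= self.n_discard < self.n_trials:
            raise ValueError("n_discard must be in [0, n_trials)")


def generate_pavlovian_schedule(params: PavlovianScheduleParams) -> np.ndarray:
    """Reward sequence: ``magnitude`` on rewarded trials, 0 otherwise."""
    rng = np.random.default_rng(params.seed)
    n_rewarded = round(params.block_size * params.p_reward)
    block = np.zeros(params.block_size)
    block[:n_rewarded] = params.magnitude
    n_blocks = -(-params.n_trials // params.block_size)
    blocks = np.tile(block, (n_blocks, 1))
    perms = rng.permuted(blocks, axis=1)
    return perms.ravel()[: params.n_trials]


@dataclass(frozen=True)
class DiscreteRewardDistribution:
    """Finite reward distribution on a strictly increasing support."""

    support: tuple[float, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        support = tuple(float(x) for x in self.support)
        probs = tuple(float(p) for p in self.probs)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", probs)
        if len(support) != len(probs) or not support:
            raise ValueError("support and probs must be nonempty and equal length")
        if any(p < 0 for p in probs):
            raise ValueError("probabilities must be nonnegative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1, got {sum(probs)}")
        if any(b <= a for a, b in zip(support, support[1:])):
            raise ValueError("support must be strictly increasing")


def distribution_moments(dist: DiscreteRewardDistribution) -> tuple[float, float]:
    """Exact mean and standard deviation of a discrete reward distribution."""
    x = np.asarray(dist.support)
    p = np.asarray(dist.probs)
    mean = float(np.dot(p, x))
    var = float(np.dot(p, (x - mean) ** 2))
    return mean, np.sqrt(var)


# Default discrete distributions for the two-cue Pavlovian comparison:
# same support, same mean and range, different spread.  The flat variant
# draws the three magnitudes equally often; the peaked variant
# concentrates mass on the middle magnitude.
UNIFORM_LIKE_DISTRIBUTION = DiscreteRewardDistribution(
    support=(0.1, 0.2, 0.3), probs=(1 / 3, 1 / 3, 1 / 3)
)
NORMAL_LIKE_DISTRIBUTION = DiscreteRewardDistribution(
    support=(0.1, 0.2, 0.3), probs=(0.1, 0.8, 0.1)
)
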