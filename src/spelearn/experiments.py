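"""Simulation studies built on the learning rules and reward generators.

Four drivers are provided:

* ``run_tracking_benchmark`` — mean-squared tracking error of RW (over a
  learning-rate grid), the SPE learner, and the true-parameter Kalman
  filter on drifting-Gaussian rewards across observation-noise levels;
* ``run_tobler_experiment`` — Pavlovian 50%-reward schedules at several
  magnitudes; per-model normalized mean prediction errors for rewarded
  and unrewarded outcomes;
* ``rothenhoefer_responses`` / ``reward_taxis_response`` — analytic
  per-reward responses for discrete reward distributions and the
  log-scale alternative model;
* ``kalman_curves`` — posterior-variance convergence and the steady
  state gain against its high-noise approximation.

All drivers return tidy :class:`pandas.DataFrame` tables carrying the
parameters and seeds that produced each record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .learners import (
    KalmanParams,
    RWParams,
    SPEParams,
    high_noise_gain,
    run_kalman,
    run_rw,
    run_spe,
    steady_state_gain,
    steady_state_posterior_var,
)
from .reward_sim import (
    DiscreteRewardDistribution,
    DriftingGaussianParams,
    PavlovianScheduleParams,
    distribution_moments,
    generate_drifting_rewards,
    generate_pavlovian_schedule,
)

__all__ = [
    "BenchmarkConfig",
    "run_tracking_benchmark",
    "run_tobler_experiment",
    "rothenhoefer_responses",
    "reward_taxis_response",
    "kalman_curves",
    "default_sigma_grid",
    "default_rw_alphas",
]


def default_sigma_grid(n: int = 100) -> np.ndarray:
    """Observation-noise levels, log-evenly spaced from 0.1353 to 1096.6."""
    return np.exp(np.linspace(math.log(0.1353), math.log(1096.6), n))


def default_rw_alphas(n: int = 10) -> np.ndarray:
    """Linearly spaced RW learning rates spanning 0.007 to 0.993."""
    return np.linspace(0.007, 0.993, n)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Configuration of the value-tracking benchmark."""

    rw_alphas: tuple[float, ...] = tuple(default_rw_alphas())
    sigma_grid: tuple[float, ...] = tuple(default_sigma_grid())
    nu: float = 1.0
    n_trials: int = 100_000
    spe_alpha_m: float = 1.0
    spe_alpha_s: float = 0.1
    spe_s_floor: float = 1e-3
    kalman_w0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rw_alphas or not self.sigma_grid:
            raise ValueError("rw_alphas and sigma_grid must be nonempty")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def run_tracking_benchmark(config: BenchmarkConfig) -> pd.DataFrame:
    """Score each learner's tracking of the drifting latent mean.

    For every observation-noise level one reward trajectory is drawn
    (seeded from ``config.seed``) and shared by all learners at that
    level, so their errors are directly comparable.  The metric is the
    mean over trials of ``(m_t - mu_t)**2`` and its base-10 logarithm.
    """
    records = []
    child_seeds = np.random.SeedSequence(config.seed).spawn(len(config.sigma_grid))
    for sigma, seed_seq in zip(config.sigma_grid, child_seeds):
        traj = generate_drifting_rewards(
            DriftingGaussianParams(
                mu0=0.0,
                nu=config.nu,
                sigma=sigma,
                n_trials=config.n_trials,
                seed=seed_seq,
            )
        )

        def record(learner: str, param_name: str, param: float, m: np.ndarray):
            mse = float(np.mean((m - traj.mu) ** 2))
            records.append(
                {
                    "experiment": "tracking_benchmark",
                    "learner": learner,
                    param_name: param,
                    "sigma": sigma,
                    "nu": config.nu,
                    "n_trials": config.n_trials,
                    "seed": config.seed,
                    "mse": mse,
                    "log10_mse": math.log10(mse) if mse > 0 else -math.inf,
                }
            )

        for alpha in config.rw_alphas:
            record("rw", "alpha", alpha, run_rw(RWParams(alpha=alpha), traj.r).m)
        spe = run_spe(
            SPEParams(
                alpha_m=config.spe_alpha_m,
                alpha_s=config.spe_alpha_s,
                s_floor=config.spe_s_floor,
            ),
            traj.r,
        )
        record("spe", "alpha", config.spe_alpha_m, spe.m)
        kal = run_kalman(
            KalmanParams(nu=config.nu, sigma=sigma, w0=config.kalman_w0), traj.r
        )
        record("kalman", "alpha", math.nan, kal.m)
    return pd.DataFrame.from_records(records)


def run_tobler_experiment(
    magnitudes: tuple[float, ...] = (0.05, 0.15, 0.5),
    alpha_m: float = 0.0067,
    alpha_s: float = 0.0067,
    n_trials: int = 2000,
    n_discard: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Pavlovian 50%-reward simulation at several reward magnitudes.

    For each magnitude the RW and SPE learners run through a balanced
    50% schedule; prediction errors from the post-burn-in trials are
    averaged separately for rewarded and unrewarded outcomes.  The six
    per-model averages (three magnitudes x two outcomes) are then
    normalized by their population standard deviation within each model.
    """
    if any(m <= 0 for m in magnitudes):
        raise ValueError("reward magnitudes must be positive")
    records = []
    child_seeds = np.random.SeedSequence(seed).spawn(len(magnitudes))
    for magnitude, seed_seq in zip(magnitudes, child_seeds):
        sched = PavlovianScheduleParams(
            magnitude=magnitude, n_trials=n_trials, n_discard=n_discard, seed=seed_seq
        )
        rewards = generate_pavlovian_schedule(sched)
        rewarded = rewards[n_discard:] > 0
        if rewarded.all() or not rewarded.any():
            raise ValueError("degenerate schedule: only one outcome present")
        traces = {
            "rw": run_rw(RWParams(alpha=alpha_m, m0=0.0), rewards),
            "spe": run_spe(SPEParams(alpha_m=alpha_m, alpha_s=alpha_s), rewards),
        }
        for model, trace in traces.items():
            delta = trace.delta[n_discard:]
            for outcome, mask in (("rewarded", rewarded), ("unrewarded", ~rewarded)):
                records.append(
                    {
                        "experiment": "tobler",
                        "model": model,
                        "magnitude": magnitude,
                        "outcome": outcome,
                        "mean_delta": float(delta[mask].mean()),
                        "n_trials": n_trials,
                        "n_discard": n_discard,
                        "alpha_m": alpha_m,
                        "alpha_s": alpha_s,
                        "seed": seed,
                    }
                )
    df = pd.DataFrame.from_records(records)
    df["normalized_delta"] = df.groupby("model")["mean_delta"].transform(
        lambda x: x / x.std(ddof=0)
    )
    return df


def rothenhoefer_responses(
    dist: DiscreteRewardDistribution, model: str
) -> pd.DataFrame:
    """Analytic per-reward responses for a fully learned discrete distribution.

    ``rw`` responds with ``r - mu``; ``spe`` with ``(r - mu) / sigma``,
    where ``(mu, sigma)`` are the exact distribution moments.
    """
    if model not in ("rw", "spe"):
        raise ValueError(f"model must be rw|spe, got {model!r}")
    mu, sigma = distribution_moments(dist)
    r = np.asarray(dist.support)
    if model == "spe":
        if sigma == 0:
            raise ValueError("zero-variance distribution: SPE scaling undefined")
        response = (r - mu) / sigma
    else:
        response = r - mu
    return pd.DataFrame(
        {
            "experiment": "rothenhoefer",
            "model": model,
            "reward": r,
            "prob": dist.probs,
            "response": response,
            "dist_mean": mu,
            "dist_sd": sigma,
        }
    )


def reward_taxis_response(r: float, p_reward: float) -> float:
    """Log-scale prediction error ``log(r) - log(p_reward * r) = -log(p_reward)``.

    Independent of reward size: at 50% reward probability it is
    ``log 2`` for every magnitude.
    """
    if r <= 0:
        raise ValueError(f"reward must be positive, got {r}")
    if not 0 < p_reward <= 1:
        raise ValueError(f"p_reward must be in (0, 1], got {p_reward}")
    return math.log(r) - math.log(p_reward * r)


def kalman_curves(
    sigma_grid: np.ndarray | None = None,
    nu_list: tuple[float, ...] = (0.0, 0.5, 1.0),
    n_steps: int = 50,
    sigma_for_trajectories: float = 1.0,
    w0: float = 1.0,
) -> pd.DataFrame:
    """Posterior-variance trajectories and steady-state gain comparison.

    Returns a long table with two parts: ``posterior_variance`` rows
    tabulate ``w_t`` over ``n_steps`` observations for each process
    noise (at fixed observation noise), including the steady-state
    value; ``gain`` rows compare ``k_inf`` with ``nu / sigma`` across
    ``sigma_grid`` at ``nu = 1``.
    """
    if sigma_grid is None:
        sigma_grid = default_sigma_grid(25)
    records = []
    for nu in nu_list:
        w = w0
        nu2 = nu**2
        sig2 = sigma_for_trajectories**2
        w_inf = steady_state_posterior_var(nu, sigma_for_trajectories)
        for t in range(1, n_steps + 1):
            prior = w + nu2
            k = prior / (prior + sig2)
            w = (1.0 - k) * prior
            records.append(
                {
                    "part": "posterior_variance",
                    "nu": nu,
                    "sigma": sigma_for_trajectories,
                    "step": t,
                    "w": w,
                    "k": k,
                    "w_inf": w_inf,
                }
            )
    for sigma in np.asarray(sigma_grid, dtype=float):
        records.append(
            {
                "part": "gain",
                "nu": 1.0,
                "sigma": sigma,
                "k_inf": steady_state_gain(1.0, sigma),
                "nu_over_sigma": high_noise_gain(1.0, sigma),
                "w_inf": steady_state_posterior_var(1.0, sigma),
            }
        )
    return pd.DataFrame.from_records(records)
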