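"""Trial-level reward-learning rules.

Three trackers of a scalar reward signal are implemented:

* the scaled-prediction-error (SPE) learner, which maintains online
  estimates of the reward mean ``m`` and standard deviation ``s`` and
  drives both from the scaled error ``delta = (r - m) / s``;
* the Rescorla-Wagner (RW) delta rule — the special case of the SPE
  learner with ``alpha_s = 0`` and ``s = 1``;
* the one-dimensional Kalman filter for a Gaussian random-walk latent
  mean, together with its steady-state gain / posterior variance and
  the high-noise approximation ``nu / sigma`` that links the steady
  state filter to the SPE rule.

All single-step updates are pure: they take a state, return a new state
plus the prediction error that produced it.  The ``run_*`` helpers apply
a rule along a full reward sequence and return per-trial traces.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "SPEState",
    "SPEParams",
    "RWState",
    "RWParams",
    "KalmanState",
    "KalmanParams",
    "spe_delta",
    "spe_update",
    "rw_update",
    "kalman_update",
    "steady_state_gain",
    "steady_state_posterior_var",
    "high_noise_gain",
    "run_spe",
    "run_rw",
    "run_kalman",
]


def _check_reward(r: float) -> float:
    r = float(r)
    if not math.isfinite(r):
        raise ValueError(f"reward must be finite, got {r!r}")
    return r


# ---------------------------------------------------------------------------
# states and parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SPEState:
    """Current estimates of reward mean ``m`` and standard deviation ``s``."""

    m: float
    s: float

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError(f"spread estimate must be positive, got s={self.s}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SPEParams:
    """Learning rates and initial state of the SPE learner.

    ``s_floor`` is the smallest admissible spread; the spread update is
    clipped there so the scaled error stays defined even when a large
    ``alpha_s`` would otherwise drive ``s`` through zero.
    """

    alpha_m: float
    alpha_s: float
    s_floor: float = 1e-3
    m0: float = 0.0
    s0: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_m <= 1:
            raise ValueError(f"alpha_m must be in (0, 1], got {self.alpha_m}")
        if self.alpha_s < 0:
            raise ValueError(f"alpha_s must be >= 0, got {self.alpha_s}")
        if not self.s_floor > 0:
            raise ValueError(f"s_floor must be positive, got {self.s_floor}")
        if not self.s0 > 0:
            raise ValueError(f"s0 must be positive, got {self.s0}")

    def initial_state(self) -> SPEState:
        return SPEState(m=self.m0, s=self.s0)


@dataclass(frozen=True)
class RWState:
    """Current mean-reward estimate of the Rescorla-Wagner learner."""

    m: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RWParams:
    alpha: float
    m0: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")

    def initial_state(self) -> RWState:
        return RWState(m=self.m0)


@dataclass(frozen=True)
class KalmanState:
    """Posterior mean ``m``, posterior variance ``w``, and last gain ``k``."""

    m: float
    w: float
    k: float = 0.0

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError(f"posterior variance must be >= 0, got {self.w}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class KalmanParams:
    """Process-noise sd ``nu``, observation-noise sd ``sigma``, initial ``w0``."""

    nu: float
    sigma: float
    w0: float = 1.0

    def __post_init__(self) -> None:
        if self.nu < 0 or self.sigma < 0:
            raise ValueError("nu and sigma must be nonnegative")
        if self.nu == 0 and self.sigma == 0:
            raise ValueError("nu and sigma cannot both be zero")
        if self.w0 < 0:
            raise ValueError(f"w0 must be >= 0, got {self.w0}")

    def initial_state(self, m0: float = 0.0) -> KalmanState:
        return KalmanState(m=m0, w=self.w0)


# ---------------------------------------------------------------------------
# single-step updates
# ---------------------------------------------------------------------------


def spe_delta(state: SPEState, r: float) -> float:
    """Scaled prediction error ``(r - m) / s`` at the current state."""
    r = _check_reward(r)
    return (r - state.m) / state.s


def spe_update(state: SPEState, params: SPEParams, r: float) -> tuple[SPEState, float]:
    """One SPE step: ``m += alpha_m * delta``, ``s += alpha_s * (delta**2 - 1)``.

    The scaled error is computed from the pre-update state; ``m`` and
    ``s`` are then both updated from that same error.  Returns the new
    state and the error used.
    """
    delta = spe_delta(state, r)
    m_new = state.m + params.alpha_m * delta
    s_new = max(params.s_floor, state.s + params.alpha_s * (delta * delta - 1.0))
    return SPEState(m=m_new, s=s_new), delta


def rw_update(state: RWState, params: RWParams, r: float) -> tuple[RWState, float]:
    """One Rescorla-Wagner step: ``m += alpha * (r - m)``."""
    r = _check_reward(r)
    delta = r - state.m
    return RWState(m=state.m + params.alpha * delta), delta


def kalman_update(
    state: KalmanState, params: KalmanParams, r: float
) -> tuple[KalmanState, float]:
    """One Kalman step for a random-walk latent mean.

    Gain ``k = (w + nu^2) / (w + nu^2 + sigma^2)`` is computed from the
    pre-update variance, then ``m += k * (r - m)`` and
    ``w' = (1 - k) * (w + nu^2)``.
    """
    r = _check_reward(r)
    prior_var = state.w + params.nu**2
    denom = prior_var + params.sigma**2
    if denom == 0:
        raise ZeroDivisionError(
            "degenerate Kalman gain: w, nu and sigma are all zero"
        )
    k = prior_var / denom
    delta = r - state.m
    return KalmanState(m=state.m + k * delta, w=(1.0 - k) * prior_var, k=k), delta


# ---------------------------------------------------------------------------
# steady-state Kalman quantities
# ---------------------------------------------------------------------------


def steady_state_gain(nu: float, sigma: float) -> float:
    """Asymptotic Kalman gain ``k_inf``.

    Closed form ``(sqrt(4 sigma^2/nu^2 + 1) + 1) /
    (sqrt(4 sigma^2/nu^2 + 1) + 1 + 2 sigma^2/nu^2)``.  ``nu = 0`` is
    exposed as the documented limit ``k_inf -> 0`` (for ``sigma > 0``);
    ``sigma = 0`` gives ``k_inf = 1``.
    """
    if nu < 0 or sigma < 0:
        raise ValueError("nu and sigma must be nonnegative")
    if nu == 0 and sigma == 0:
        raise ValueError("nu and sigma cannot both be zero")
    if nu == 0:
        return 0.0
    q = 4.0 * sigma**2 / nu**2
    root = math.sqrt(q + 1.0)
    return (root + 1.0) / (root + 1.0 + 2.0 * sigma**2 / nu**2)


def steady_state_posterior_var(nu: float, sigma: float) -> float:
    """Asymptotic posterior variance ``w_inf = nu^2/2 (sqrt(4 sigma^2/nu^2 + 1) - 1)``.

    ``nu = 0`` returns the limit 0.  For large ``sigma/nu`` the value
    approaches the geometric mean ``nu * sigma`` of the two variances.
    """
    if nu < 0 or sigma < 0:
        raise ValueError("nu and sigma must be nonnegative")
    if nu == 0 and sigma == 0:
        raise ValueError("nu and sigma cannot both be zero")
    if nu == 0:
        return 0.0
    q = 4.0 * sigma**2 / nu**2
    return 0.5 * nu**2 * (math.sqrt(q + 1.0) - 1.0)


def high_noise_gain(nu: float, sigma: float) -> float:
    """High-observation-noise approximation ``nu / sigma`` of the gain."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if nu < 0:
        raise ValueError(f"nu must be nonnegative, got {nu}")
    return nu / sigma


# ---------------------------------------------------------------------------
# sequence runners
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LearnerTrace:
    """Per-trial traces of a learner applied to a reward sequence.

    ``m[t]`` is the estimate after observing reward ``t``; ``delta[t]``
    the prediction error used on that trial.  ``s``, ``w`` and ``k`` are
    populated only for the rules that maintain them.
    """

    m: np.ndarray
    delta: np.ndarray
    s: np.ndarray | None = None
    w: np.ndarray | None = None
    k: np.ndarray | None = None


def run_spe(params: SPEParams, rewards: np.ndarray) -> LearnerTrace:
    rewards = np.asarray(rewards, dtype=float)
    if not np.all(np.isfinite(rewards)):
        raise ValueError("rewards must be finite")
    n = rewards.size
    m_out = np.empty(n)
    s_out = np.empty(n)
    d_out = np.empty(n)
    m, s = params.m0, params.s0
    a_m, a_s, floor = params.alpha_m, params.alpha_s, params.s_floor
    for t in range(n):
        d = (rewards[t] - m) / s
        m = m + a_m * d
        s = max(floor, s + a_s * (d * d - 1.0))
        m_out[t], s_out[t], d_out[t] = m, s, d
    return LearnerTrace(m=m_out, delta=d_out, s=s_out)


def run_rw(params: RWParams, rewards: np.ndarray) -> LearnerTrace:
    # linear recursion m_t = (1-a) m_{t-1} + a r_t, solved with lfilter
    rewards = np.asarray(rewards, dtype=float)
    if not np.all(np.isfinite(rewards)):
        raise ValueError("rewards must be finite")
    a = params.alpha
    m, _ = lfilter([a], [1.0, -(1.0 - a)], rewards, zi=[(1.0 - a) * params.m0])
    m_prev = np.concatenate(([params.m0], m[:-1]))
    return LearnerTrace(m=m, delta=rewards - m_prev)


def run_kalman(
    params: KalmanParams, rewards: np.ndarray, m0: float = 0.0
) -> LearnerTrace:
    rewards = np.asarray(rewards, dtype=float)
    if not np.all(np.isfinite(rewards)):
        raise ValueError("rewards must be finite")
    n = rewards.size
    m_out = np.empty(n)
    w_out = np.empty(n)
    k_out = np.empty(n)
    d_out = np.empty(n)
    m, w = m0, params.w0
    nu2, sig2 = params.nu**2, params.sigma**2
    for t in range(n):
        prior = w + nu2
        k = prior / (prior + sig2)
        d = rewards[t] - m
        m = m + k * d
        w = (1.0 - k) * prior
        m_out[t], w_out[t], k_out[t], d_out[t] = m, w, k, d
    return LearnerTrace(m=m_out, delta=d_out, w=w_out, k=k_out)
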