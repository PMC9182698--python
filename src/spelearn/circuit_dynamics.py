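"""Continuous-time dopamine-thalamus feedback loop.

A two-unit leaky-integrator model: the dopamine signal ``delta``
relaxes toward the reward input minus thalamic activity, while the
thalamic unit ``T`` relaxes toward the dopamine-modulated difference of
the direct and indirect pathway drives,

    tau_delta * d(delta)/dt = -delta + r - T
    tau_T     * dT/dt       = -T + (1 + delta/lam)/2 * G
                                 - (1 - delta/lam)/2 * N

with ``G``, ``N`` and ``r`` supplied as step functions.  At
equilibrium the dopamine signal equals the weight-space scaled
prediction error, so the circuit computes the trial-level teaching
signal in continuous time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .basal_ganglia import PathwayWeights, scaled_pe_from_weights

__all__ = [
    "CircuitParams",
    "StepInputs",
    "CircuitTrajectory",
    "circuit_derivatives",
    "simulate_circuit",
    "equilibrium_delta",
    "settling_time",
]


@dataclass(frozen=True)
class CircuitParams:
    """Time constants (ms) of the dopamine and thalamic units, and ``lam``."""

    tau_delta: float = 300.0
    tau_T: float = 10.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_delta > 0 and self.tau_T > 0):
            raise ValueError("time constants must be positive")
        if not self.lam > 0:
            raise ValueError("lam must be positive")


@dataclass(frozen=True)
class StepInputs:
    """Step-function inputs: zero before ``t_on``, constant levels after.

    The step is right-continuous: inputs already take their post-step
    values at exactly ``t_on``.
    """

    G_step: float = 10.0
    N_step: float = 6.0
    r_step: float = 4.0
    t_on: float = 0.0

    def __post_init__(self) -> None:
        for name in ("G_step", "N_step", "r_step", "t_on"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def at(self, t: float) -> tuple[float, float, float]:
        if t >= self.t_on:
            return self.G_step, self.N_step, self.r_step
        return 0.0, 0.0, 0.0


@dataclass(frozen=True)
class CircuitTrajectory:
    """Time series of the dopamine signal and thalamic activity."""

    t: np.ndarray
    delta: np.ndarray
    T: np.ndarray
    params: CircuitParams
    inputs: StepInputs

    def __post_init__(self) -> None:
        if self.t.shape != self.delta.shape or self.t.shape != self.T.shape:
            raise ValueError("t, delta, T must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ms": self.t, "delta": self.delta, "T": self.T})


def circuit_derivatives(
    delta: float, T: float, t: float, inputs: StepInputs, params: CircuitParams
) -> tuple[float, float]:
    """Instantaneous derivatives ``(d delta/dt, dT/dt)`` at state ``(delta, T)``."""
    G, N, r = inputs.at(t)
    d_delta = (-delta + r - T) / params.tau_delta
    gain = delta / params.lam
    d_T = (-T + 0.5 * (1.0 + gain) * G - 0.5 * (1.0 - gain) * N) / params.tau_T
    return d_delta, d_T


def equilibrium_delta(r: float, G: float, N: float, lam: float = 1.0) -> float:
    """Closed-form fixed point of the loop; equals the weight-space scaled error."""
    return scaled_pe_from_weights(r, PathwayWeights(G=G, N=N, lam=lam))


def simulate_circuit(
    params: CircuitParams | None = None,
    inputs: StepInputs | None = None,
    t_span: tuple[float, float] = (-200.0, 500.0),
    rtol: float = 1e-8,
    atol: float = 1e-10,
    dt_out: float = 1.0,
) -> CircuitTrajectory:
    """Integrate the loop from rest and sample it on a fixed output grid.

    The integration is split at the input onset so the adaptive stiff
    solver never steps across the discontinuity.  Output is sampled
    every ``dt_out`` ms regardless of the internal step sizes.
    """
    params = params or CircuitParams()
    inputs = inputs or StepInputs()
    t0, t1 = t_span
    if not t0 <= inputs.t_on <= t1:
        raise ValueError(f"t_span {t_span} must cover the input onset {inputs.t_on}")

    t_grid = np.arange(t0, t1 + 0.5 * dt_out, dt_out)
    delta = np.empty_like(t_grid)
    T = np.empty_like(t_grid)

    def rhs(t, y):
        return circuit_derivatives(y[0], y[1], t, inputs, params)

    # before onset the system sits at its rest state exactly: inputs are
    # zero and integration starts from (0, 0)
    pre = t_grid < inputs.t_on
    delta[pre] = 0.0
    T[pre] = 0.0

    post = ~pre
    if post.any():
        sol = solve_ivp(
            rhs, (inputs.t_on, t1), [0.0, 0.0],
            t_eval=t_grid[post], method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"post-onset integration failed: {sol.message}")
        delta[post], T[post] = sol.y

    return CircuitTrajectory(t=t_grid, delta=delta, T=T, params=params, inputs=inputs)


def settling_time(
    traj: CircuitTrajectory, rel_tol: float = 0.05
) -> float:
    """First time after onset from which ``delta`` stays within ``rel_tol`` of equilibrium.

    Returns NaN (with a warning) if the trajectory never settles within
    its time span.
    """
    if not rel_tol > 0:
        raise ValueError("rel_tol must be positive")
    star = equilibrium_delta(
        traj.inputs.r_step, traj.inputs.G_step, traj.inputs.N_step, traj.params.lam
    )
    tol = rel_tol * abs(star) if star != 0 else rel_tol
    after = traj.t >= traj.inputs.t_on
    t = traj.t[after]
    err = np.abs(traj.delta[after] - star)
    inside = err <= tol
    if not inside[-1]:
        warnings.warn("trajectory does not settle within its time span")
        return float("nan")
    # last index that is outside tolerance; settled from the next sample on
    outside = np.nonzero(~inside)[0]
    return float(t[0]) if outside.size == 0 else float(t[outside[-1] + 1])
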