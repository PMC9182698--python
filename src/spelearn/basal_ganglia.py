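"""Pathway-weight formulation of scaled-prediction-error learning.

The mean and spread estimates ``(m, s)`` are carried by two synaptic
inputs: the direct-pathway weight ``G`` and the indirect-pathway weight
``N``, with ``m = (G - N) / 2`` and ``lam * (s - 1) = (G + N) / 2``.
Plasticity acts on the weights through an asymmetric nonlinearity ``f``
plus an activity-dependent decay, and the scaled prediction error is
read out directly from the weights.

Two modes are supported.  ``unconstrained`` keeps the exact algebraic
equivalence with the ``(m, s)`` update rules and is used for
equivalence tests.  ``constrained`` clips weights at zero after each
update (synaptic weights cannot be negative), which limits accurate
spread tracking to ``s >= |m| / lam + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PathwayWeights",
    "PlasticityParams",
    "EncodingInfeasibleError",
    "encode_weights",
    "decode_stats",
    "nonlinearity_f",
    "weight_update",
    "scaled_pe_from_weights",
    "run_pathway_learner",
]


class EncodingInfeasibleError(ValueError):
    """Raised when (m, s) cannot be stored in nonnegative weights."""


@dataclass(frozen=True)
class PathwayWeights:
    """Direct (``G``) and indirect (``N``) synaptic inputs with coefficient ``lam``."""

    G: float
    N: float
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lam must be positive, got {self.lam}")

    def to_dict(self) -> dict:
        return {"G": self.G, "N": self.N, "lam": self.lam}


@dataclass(frozen=True)
class PlasticityParams:
    alpha_m: float
    alpha_s: float
    lam: float = 1.0
    mode: str = "unconstrained"

    def __post_init__(self) -> None:
        if not self.alpha_m > 0:
            raise ValueError("alpha_m must be positive (f divides by it)")
        if self.alpha_s < 0:
            raise ValueError("alpha_s must be nonnegative")
        if not self.lam > 0:
            raise ValueError("lam must be positive")
        if self.mode not in ("constrained", "unconstrained"):
            raise ValueError(f"mode must be constrained|unconstrained, got {self.mode}")


def encode_weights(
    m: float, s: float, lam: float = 1.0, constrained: bool = False
) -> PathwayWeights:
    """Store ``(m, s)`` in weights: ``G = m + lam (s - 1)``, ``N = lam (s - 1) - m``."""
    G = m + lam * (s - 1.0)
    N = lam * (s - 1.0) - m
    if constrained and (G < 0 or N < 0):
        raise EncodingInfeasibleError(
            f"(m={m}, s={s}) needs a negative weight (G={G}, N={N}); "
            f"nonnegative encoding requires s >= |m|/lam + 1 = {abs(m) / lam + 1}"
        )
    return PathwayWeights(G=G, N=N, lam=lam)


def decode_stats(weights: PathwayWeights) -> tuple[float, float]:
    """Recover ``m = (G - N)/2`` and ``s = 1 + (G + N)/(2 lam)`` from weights."""
    m = 0.5 * (weights.G - weights.N)
    s = 1.0 + 0.5 * (weights.G + weights.N) / weights.lam
    return m, s


def nonlinearity_f(delta: float, params: PlasticityParams):
    """Asymmetric plasticity transform ``f(delta) = delta + (lam a_s / a_m) delta^2``.

    Steeper for positive than negative errors; satisfies
    ``f(d) - f(-d) = 2 d``.
    """
    delta = np.asarray(delta, dtype=float)
    out = delta + (params.lam * params.alpha_s / params.alpha_m) * delta**2
    return out if out.ndim else float(out)


def weight_update(
    weights: PathwayWeights, delta: float, params: PlasticityParams
) -> PathwayWeights:
    """Apply ``dG = a_m f(delta) - lam a_s`` and ``dN = a_m f(-delta) - lam a_s``.

    In constrained mode the updated weights are clipped at zero after
    the full update is applied.
    """
    decay = params.lam * params.alpha_s
    G = weights.G + params.alpha_m * nonlinearity_f(delta, params) - decay
    N = weights.N + params.alpha_m * nonlinearity_f(-delta, params) - decay
    if params.mode == "constrained":
        G = max(0.0, G)
        N = max(0.0, N)
    return replace(weights, G=G, N=N)


def scaled_pe_from_weights(r: float, weights: PathwayWeights) -> float:
    """Read the scaled error ``(r - (G - N)/2) / (1 + (G + N)/(2 lam))`` off the weights."""
    denom = 1.0 + 0.5 * (weights.G + weights.N) / weights.lam
    if denom <= 0:
        raise ValueError(
            f"nonpositive readout denominator {denom}; weights encode s <= 0"
        )
    return (r - 0.5 * (weights.G - weights.N)) / denom


@dataclass(frozen=True)
class PathwayTrace:
    """Per-trial weight trajectory with the decoded statistics."""

    G: np.ndarray
    N: np.ndarray
    delta: np.ndarray
    m: np.ndarray
    s: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.G.size),
                "G": self.G,
                "N": self.N,
                "decoded_m": self.m,
                "decoded_s": self.s,
                "delta": self.delta,
            }
        )


def run_pathway_learner(
    params: PlasticityParams,
    rewards: np.ndarray,
    m0: float = 0.0,
    s0: float = 1.0,
) -> PathwayTrace:
    """Run the weight-space learner along a reward sequence.

    The initial state is encoded from ``(m0, s0)``; in constrained mode
    the initial encoding must itself be feasible.
    """
    rewards = np.asarray(rewards, dtype=float)
    if not np.all(np.isfinite(rewards)):
        raise ValueError("rewards must be finite")
    w = encode_weights(m0, s0, params.lam, constrained=params.mode == "constrained")
    n = rewards.size
    G = np.empty(n)
    N = np.empty(n)
    d = np.empty(n)
    for t in range(n):
        d[t] = scaled_pe_from_weights(rewards[t], w)
        w = weight_update(w, d[t], params)
        G[t], N[t] = w.G, w.N
    m = 0.5 * (G - N)
    s = 1.0 + 0.5 * (G + N) / params.lam
    return PathwayTrace(G=G, N=N, delta=d, m=m, s=s)
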