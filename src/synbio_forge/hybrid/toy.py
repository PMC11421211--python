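"""Small analytically tractable models used for statistical validation.

The linear birth–death process (birth at constant rate k, death at rate γ per
molecule) has stationary law Poisson(k/γ): mean k/γ, variance k/γ, and
autocorrelation time 1/γ — everything a tau-leaping implementation can be
checked against.
"""

from __future__ import annotations

import numpy as np

from .model import HybridModel, HybridState, Reaction

__all__ = ["birth_death_model", "birth_death_x0", "dimerization_model", "decay_euler_model"]


def birth_death_model(k: float = 50.0, gamma: float = 1.0) -> HybridModel:
    """One stochastic species X: ∅ →(k) X, X →(γ·X) ∅; no deterministic part."""
    reactions = (
        Reaction("birth", {"X": +1}, lambda x, p: np.broadcast_to(p["k"], x.shape[:-1]).astype(float)),
        Reaction("death", {"X": -1}, lambda x, p: p["gamma"] * x[..., 0]),
    )
    return HybridModel(
        species_names=("X",),
        stoch_idx=np.array([0]),
        det_idx=np.array([], dtype=np.int64),
        reactions=reactions,
        drift=lambda x, p: np.zeros(x.shape[:-1] + (0,)),
        params={"k": float(k), "gamma": float(gamma)},
    )


def birth_death_x0(k: float = 50.0, gamma: float = 1.0) -> HybridState:
    """Start at the stationary mean (rounded) to minimize burn-in."""
    return HybridState(counts=np.array([round(k / gamma)], dtype=float),
                       levels=np.array([]), t=0.0)


def dimerization_model(k_in: float = 40.0, k_dim: float = 0.02, k_deg: float = 0.5) -> HybridModel:
    """Monomer M produced at k_in, dimerizing pairwise, dimer D degraded.

    ∅ →(k_in) M;  2M →(k_dim·M(M−1)/2) D;  D →(k_deg·D) ∅.
    Nonlinear propensity exercises tau-leaping beyond the linear case.
    """
    reactions = (
        Reaction("influx", {"M": +1}, lambda x, p: np.broadcast_to(p["k_in"], x.shape[:-1]).astype(float)),
        Reaction("dimerize", {"M": -2, "D": +1},
                 lambda x, p: p["k_dim"] * x[..., 0] * np.maximum(x[..., 0] - 1, 0.0) / 2.0),
        Reaction("deg", {"D": -1}, lambda x, p: p["k_deg"] * x[..., 1]),
    )
    return HybridModel(
        species_names=("M", "D"),
        stoch_idx=np.array([0, 1]),
        det_idx=np.array([], dtype=np.int64),
        reactions=reactions,
        drift=lambda x, p: np.zeros(x.shape[:-1] + (0,)),
        params={"k_in": float(k_in), "k_dim": float(k_dim), "k_deg": float(k_deg)},
    )


def decay_euler_model(rate: float = 1.0) -> HybridModel:
    """Purely deterministic exponential decay y' = −rate·y (degenerate
    partition: no stochastic species, so the hybrid stepper must reduce to
    forward Euler exactly)."""
    return HybridModel(
        species_names=("y",),
        stoch_idx=np.array([], dtype=np.int64),
        det_idx=np.array([0]),
        reactions=(),
        drift=lambda x, p: -p["rate"] * x[..., :1],
        params={"rate": float(rate)},
    )
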