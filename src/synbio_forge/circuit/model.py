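"""Gene-circuit model: topology, kinetic parameters, and the regulatory ODE.

An N-gene circuit is defined by a signed topology matrix ``T`` with
``T[i, j] ∈ {-1, 0, +1}`` meaning gene *j* represses / ignores / activates
gene *i*.  Gene *i* is produced at its maximal rate ``β_i`` times the product
of a Hill term per incoming edge, times the scalar input ``u`` if *i* is the
input target, and degrades linearly at rate ``γ_i``:

    dx_i/dt = β_i · u^{[i = input]} · Π_j hill(x_j, K_ij, n_ij, T_ij) − γ_i x_i

Parameters are optimized in unconstrained space: β, γ, K through their logs
(enforcing positivity) and each Hill coefficient through a smooth squash onto
(1, 8) (preventing numerically explosive exponents).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "N_HILL_LO", "N_HILL_HI",
    "CircuitParams", "GeneCircuit", "StepInput", "Trajectory",
    "hill_term", "circuit_rhs",
    "squash_hill", "unsquash_hill",
]

N_HILL_LO = 1.0
N_HILL_HI = 8.0


def squash_hill(z: np.ndarray) -> np.ndarray:
    """Map an unconstrained optimization variable onto the Hill-coefficient
    interval (1, 8) via a logistic squash."""
    return N_HILL_LO + (N_HILL_HI - N_HILL_LO) / (1.0 + np.exp(-z))


def unsquash_hill(n: np.ndarray) -> np.ndarray:
    s = (np.asarray(n, dtype=float) - N_HILL_LO) / (N_HILL_HI - N_HILL_LO)
    if np.any((s <= 0) | (s >= 1)):
        raise ValueError(f"Hill coefficient must lie strictly in ({N_HILL_LO}, {N_HILL_HI})")
    return np.log(s / (1.0 - s))


def dsquash_hill_dz(z: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-z))
    return (N_HILL_HI - N_HILL_LO) * s * (1.0 - s)


def hill_term(x, K, n, sign):
    """Hill regulation factor in [0, 1].

    Activation (sign=+1): x^n / (K^n + x^n); repression (sign=−1):
    K^n / (K^n + x^n).  At ``x = K`` both equal 1/2 for any n.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill_term requires x >= 0")
    if np.any(np.asarray(K) <= 0):
        raise ValueError("hill_term requires K > 0")
    if np.any(np.asarray(n) < 1):
        raise ValueError("hill_term requires n >= 1")
    xn = x**n
    Kn = np.asarray(K, dtype=float) ** n
    a = xn / (Kn + xn)
    return np.where(np.asarray(sign) > 0, a, 1.0 - a)


@dataclass(frozen=True)
class CircuitParams:
    """Natural-space kinetic parameters.

    beta, gamma: per-gene (concentration/time and 1/time); K, n_hill:
    per-edge matrices (only entries under nonzero topology edges are used).
    """

    beta: np.ndarray  # (n,)
    gamma: np.ndarray  # (n,)
    K: np.ndarray  # (n, n)
    n_hill: np.ndarray  # (n, n)

    def __post_init__(self):
        for name in ("beta", "gamma", "K"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if np.any(self.n_hill < N_HILL_LO) or np.any(self.n_hill > N_HILL_HI):
            raise ValueError(f"n_hill must lie in [{N_HILL_LO}, {N_HILL_HI}]")


def _edges(topology: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nonzero edges (target gene i, regulator gene j) in row-major order."""
    ei, ej = np.nonzero(topology)
    return ei.astype(np.int64), ej.astype(np.int64)


@dataclass(frozen=True)
class GeneCircuit:
    """Topology plus parameters (stored as an unconstrained log-space vector).

    ``log_params`` concatenates [log β (n), log γ (n), log K (per edge),
    z (per edge)] with the edges of the topology in row-major order and the
    Hill coefficient n = squash(z) ∈ (1, 8).
    """

    topology: np.ndarray  # (n, n) in {-1, 0, 1}
    input_target: int
    output_index: int
    log_params: np.ndarray

    def __post_init__(self):
        T = np.asarray(self.topology, dtype=np.int64)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("topology must be a square matrix")
        if not np.isin(T, (-1, 0, 1)).all():
            raise ValueError("topology entries must be in {-1, 0, +1}")
        n = T.shape[0]
        if not (0 <= self.input_target < n and 0 <= self.output_index < n):
            raise ValueError("input_target and output_index must be valid gene indices")
        object.__setattr__(self, "topology", T)
        ei, _ = _edges(T)
        expect = 2 * n + 2 * len(ei)
        lp = np.asarray(self.log_params, dtype=float)
        if lp.shape != (expect,):
            raise ValueError(f"log_params must have length {expect} (2n + 2·edges)")
        object.__setattr__(self, "log_params", lp)

    @property
    def n_genes(self) -> int:
        return self.topology.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.topology))

    @property
    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        return _edges(self.topology)

    @classmethod
    def from_params(cls, topology: np.ndarray, input_target: int, output_index: int,
                    params: CircuitParams) -> "GeneCircuit":
        T = np.asarray(topology, dtype=np.int64)
        ei, ej = _edges(T)
        vec = np.concatenate([
            np.log(params.beta), np.log(params.gamma),
            np.log(params.K[ei, ej]), unsquash_hill(params.n_hill[ei, ej]),
        ])
        return cls(topology=T, input_target=input_target, output_index=output_index,
                   log_params=vec)

    def params(self) -> CircuitParams:
        """Decode the log-space vector back to natural-space parameters.

        K and n_hill entries off the topology's edges are filled with
        placeholders (1.0 and 2.0) and never enter the dynamics.
        """
        n = self.n_genes
        ei, ej = self.edges
        e = len(ei)
        lp = self.log_params
        K = np.ones((n, n))
        nh = np.full((n, n), 2.0)
        K[ei, ej] = np.exp(lp[2 * n:2 * n + e])
        nh[ei, ej] = squash_hill(lp[2 * n + e:])
        return CircuitParams(beta=np.exp(lp[:n]), gamma=np.exp(lp[n:2 * n]), K=K, n_hill=nh)

    def with_log_params(self, log_params: np.ndarray) -> "GeneCircuit":
        return GeneCircuit(self.topology, self.input_target, self.output_index,
                           np.asarray(log_params, dtype=float))


@dataclass(frozen=True)
class StepInput:
    """A step perturbation of the scalar input: u1 before t_step, u2 after."""

    u1: float
    u2: float
    t_step: float = 50.0
    t_end: float = 100.0

    def __post_init__(self):
        if self.u1 <= 0 or self.u2 <= 0:
            raise ValueError("input levels must be > 0")
        if not 0 < self.t_step < self.t_end:
            raise ValueError("need 0 < t_step < t_end")

    def u_at(self, t) -> np.ndarray:
        return np.where(np.asarray(t) < self.t_step, self.u1, self.u2)


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray  # (M,) strictly increasing, includes t_step exactly
    states: np.ndarray  # (M, n_genes)

    def output(self, output_index: int) -> np.ndarray:
        return self.states[:, output_index]


def circuit_rhs(circuit: GeneCircuit, state: np.ndarray, u: float) -> np.ndarray:
    """Reference (pure numpy) evaluation of the circuit ODE right-hand side.

    The integrator uses an equivalent compiled kernel; this function is the
    readable definition and the cross-check oracle.  States are clamped at 0
    inside the Hill terms so that solver undershoot cannot produce NaNs.
    """
    p = circuit.params()
    state = np.asarray(state, dtype=float)
    n = circuit.n_genes
    prod = p.beta.copy()
    prod[circuit.input_target] *= u
    for i in range(n):
        for j in range(n):
            s = circuit.topology[i, j]
            if s != 0:
                prod[i] *= float(hill_term(max(state[j], 0.0), p.K[i, j], p.n_hill[i, j], s))
    return prod - p.gamma * state
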