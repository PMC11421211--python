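"""Gradient-based circuit optimization (Adam on log-space parameters)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..engine import RngKey
from .integrate import IntegrationError, simulate_with_tangents
from .metrics import AdaptationResult, loss_and_gradient_from_tangents
from .model import GeneCircuit, StepInput, dsquash_hill_dz

__all__ = ["OptimizationResult", "loss_gradient", "optimize_circuit", "batch_optimize",
           "random_circuit"]


class Adam:
    """Adam optimizer (β1=0.9, β2=0.999, ε=1e-8) with bias correction."""

    def __init__(self, n_params: int, lr: float, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2, self.eps = b1, b2, eps
        self.m = np.zeros(n_params)
        self.v = np.zeros(n_params)
        self.t = 0

    def update(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass(frozen=True)
class OptimizationResult:
    circuit: GeneCircuit  # best-so-far parameters
    history: np.ndarray  # (steps,) loss after each update's evaluation
    final_metrics: AdaptationResult | None
    improved: bool  # final loss <= initial loss
    failed: bool  # aborted on non-finite loss
    penalized: bool  # last evaluation hit the not-steady penalty path


def _chain_to_z(grad: np.ndarray, circuit: GeneCircuit) -> np.ndarray:
    """Tangents carry d/dn for Hill columns; convert to d/dz = d/dn · dn/dz."""
    n = circuit.n_genes
    e = circuit.n_edges
    out = grad.copy()
    z = circuit.log_params[2 * n + e:]
    out[2 * n + e:] *= dsquash_hill_dz(z)
    return out


def _eval(circuit: GeneCircuit, inp: StepInput, dt: float, s_min: float, w: float):
    traj, S = simulate_with_tangents(circuit, inp, dt=dt)
    y = traj.output(circuit.output_index)
    loss, grad, result, penalized = loss_and_gradient_from_tangents(
        y, S, traj.times, inp, s_min, w)
    return loss, _chain_to_z(grad, circuit), result, penalized


def loss_gradient(circuit: GeneCircuit, inp: StepInput, dt: float = 0.01,
                  s_min: float = 0.5, w: float = 1.0) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. ``circuit.log_params``.

    The gradient is the exact derivative of the discrete simulate → metrics →
    loss composition (forward-mode sensitivities through the RK4 map), so it
    matches central finite differences of the same pipeline.
    """
    loss, grad, _, _ = _eval(circuit, inp, dt, s_min, w)
    return loss, grad


def optimize_circuit(circuit: GeneCircuit, inp: StepInput, steps: int = 500,
                     lr: float = 0.05, dt: float = 0.01, s_min: float = 0.5,
                     w: float = 1.0) -> OptimizationResult:
    """Adam (β1=0.9, β2=0.999, ε=1e-8) on the unconstrained parameter vector.

    Keeps the best parameters seen; a non-finite loss (e.g. the integrator
    blowing up for an extreme parameter draw) aborts the loop and returns the
    best-so-far circuit with ``failed=True``.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    theta = circuit.log_params.copy()
    opt = Adam(len(theta), lr)
    history = np.empty(steps)
    best_loss = np.inf
    best_theta = theta.copy()
    last_metrics: AdaptationResult | None = None
    penalized = False
    failed = False
    for t in range(steps):
        try:
            loss, grad, metrics, penalized = _eval(
                circuit.with_log_params(theta), inp, dt, s_min, w)
        except IntegrationError:
            loss, grad, metrics = np.nan, None, None
        if not np.isfinite(loss):
            history[t:] = np.nan
            failed = True
            break
        history[t] = loss
        if metrics is not None:
            last_metrics = metrics
        if loss < best_loss:
            best_loss = loss
            best_theta = theta.copy()
        if lr > 0.0:
            theta = opt.update(theta, grad)
    improved = bool(np.isfinite(best_loss) and (not np.isfinite(history[0]) or best_loss <= history[0]))
    return OptimizationResult(
        circuit=circuit.with_log_params(best_theta), history=history,
        final_metrics=last_metrics, improved=improved, failed=failed,
        penalized=penalized,
    )


def batch_optimize(circuits: list[GeneCircuit], inp: StepInput, steps: int = 500,
                   lr: float = 0.05, dt: float = 0.01, s_min: float = 0.5,
                   w: float = 1.0) -> list[OptimizationResult]:
    """Element-wise :func:`optimize_circuit` over a batch sharing a topology.

    One circuit failing (flagged in its result) does not abort the others,
    and the output order matches the input order.
    """
    if not circuits:
        raise ValueError("empty batch")
    topo = circuits[0].topology
    for c in circuits[1:]:
        if not np.array_equal(c.topology, topo):
            raise ValueError("batch_optimize requires a shared topology")
    return [optimize_circuit(c, inp, steps=steps, lr=lr, dt=dt, s_min=s_min, w=w)
            for c in circuits]


# initialization ranges (log-uniform).  Rates are drawn so random circuits
# settle well before the default t_step = 50; repression edges start steeper
# than activation edges (cooperative repression), which places a typical
# draw near the regime where the repression path's DC gain can exceed the
# direct path's — the regime where transient (adaptive) responses live.
_INIT_RANGES = {"beta": (0.5, 5.0), "gamma": (0.3, 3.0), "K_rel": (0.5, 2.0),
                "n_act": (1.5, 3.0), "n_rep": (2.0, 5.0), "K_jitter": (0.7, 1.4)}


def random_circuit(topology: np.ndarray, input_target: int, output_index: int,
                   key: RngKey, *, u: float = 1.0, calibrate: bool = True) -> GeneCircuit:
    """Random parameter draw for a fixed topology.

    Rates and Hill coefficients are log-uniform (see ``_INIT_RANGES``).  Each
    edge's half-saturation K is placed at its regulator's *operating point*:
    first at the regulator's unregulated scale β/γ, then (``calibrate=True``)
    refined twice against a short pre-step simulation at input level ``u`` so
    that every edge starts near half-saturation, where it is maximally
    responsive and its gradient signal is strongest.
    """
    from .integrate import IntegrationError, simulate_circuit
    from .model import CircuitParams

    topology = np.asarray(topology, dtype=np.int64)
    n = topology.shape[0]
    rng = key.generator()

    def logu(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))

    beta = logu(*_INIT_RANGES["beta"], n)
    gamma = logu(*_INIT_RANGES["gamma"], n)
    n_hill = np.where(topology < 0, logu(*_INIT_RANGES["n_rep"], (n, n)),
                      logu(*_INIT_RANGES["n_act"], (n, n)))
    scale = beta / gamma
    K = scale[None, :] * logu(*_INIT_RANGES["K_rel"], (n, n))
    jitter = logu(*_INIT_RANGES["K_jitter"], (n, n))
    circuit = GeneCircuit.from_params(topology, input_target, output_index,
                                      CircuitParams(beta=beta, gamma=gamma, K=K,
                                                    n_hill=n_hill))
    if not calibrate or circuit.n_edges == 0:
        return circuit
    probe = StepInput(u1=u, u2=1.5 * u, t_step=25.0, t_end=30.0)
    for _ in range(2):
        try:
            traj = simulate_circuit(circuit, probe, dt=0.05)
        except IntegrationError:
            break
        x_op = np.maximum(traj.states[round(25.0 / 0.05)], 1e-6)
        circuit = GeneCircuit.from_params(
            topology, input_target, output_index,
            CircuitParams(beta=beta, gamma=gamma, K=x_op[None, :] * jitter,
                          n_hill=n_hill))
    return circuit
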