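"""Fixed-step RK4 integration of gene circuits, with forward sensitivities.

The solver is a classical 4th-order Runge–Kutta scheme on a fixed grid that
contains the input step time exactly (the input is piecewise constant per
step, so no stage straddles the discontinuity).  Gradients are obtained by
analytic forward-mode sensitivity propagation through the *discrete* RK4
map: the tangent matrix S = ∂x/∂θ is advanced alongside the state with the
exact Jacobians of each stage, so the result is the exact derivative of the
computed trajectory (the quantity a finite-difference check converges to),
not an approximation of the continuous sensitivity ODE.

Tangent columns are ordered [log β (n), log γ (n), log K (edge), n (edge)];
the chain rule from the raw Hill coefficient n to its unconstrained squash
variable z is applied by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import GeneCircuit, StepInput, Trajectory

__all__ = ["IntegrationError", "simulate_circuit", "simulate_with_tangents", "grid_steps"]


class IntegrationError(RuntimeError):
    """The state became non-finite during integration."""


@njit(cache=True)
def _hill(x, K, n, sign):
    """Hill factor with x clamped at 0; sign +1 activation, −1 repression."""
    if x < 0.0:
        x = 0.0
    xn = x**n
    Kn = K**n
    a = xn / (Kn + xn)
    if sign > 0:
        return a
    return 1.0 - a


@njit(cache=True)
def _hill_derivs(x, K, n, sign):
    """(h, dh/dx, K·dh/dK, dh/dn) for one edge, with x clamped at 0."""
    if x < 0.0:
        x = 0.0
    xn = x**n
    Kn = K**n
    denom = Kn + xn
    a = xn / denom
    ax = a * (1.0 - a)
    if sign > 0:
        h = a
        s = 1.0
    else:
        h = 1.0 - a
        s = -1.0
    if x > 0.0:
        dh_dx = s * n * ax / x
        dh_dn = s * ax * np.log(x / K)
    else:
        dh_dx = s / K if n == 1.0 else 0.0
        dh_dn = 0.0
    K_dh_dK = -s * n * ax
    return h, dh_dx, K_dh_dK, dh_dn


@njit(cache=True)
def _rhs(T, beta, gamma, K, nh, input_target, u, x, f):
    n = x.shape[0]
    for i in range(n):
        prod = beta[i]
        if i == input_target:
            prod *= u
        for j in range(n):
            s = T[i, j]
            if s != 0:
                prod *= _hill(x[j], K[i, j], nh[i, j], s)
        f[i] = prod - gamma[i] * x[i]


@njit(cache=True)
def _rhs_jac(T, beta, gamma, K, nh, input_target, u, edge_i, edge_j, x, f, Jx, Jt,
             h_c, dhx_c, KdK_c, dhn_c):
    """RHS plus Jacobians w.r.t. state (Jx, n×n) and parameters (Jt, n×P).

    Parameter columns: [log β | log γ | log K per edge | n per edge].
    The per-edge Hill value and derivatives are evaluated once per call
    (h_c..dhn_c are caller-provided scratch of length E).
    """
    n = x.shape[0]
    E = edge_i.shape[0]
    for i in range(n):
        for j in range(n):
            Jx[i, j] = 0.0
    for i in range(n):
        for c in range(2 * n + 2 * E):
            Jt[i, c] = 0.0
    for e in range(E):
        h_c[e], dhx_c[e], KdK_c[e], dhn_c[e] = _hill_derivs(
            x[edge_j[e]], K[edge_i[e], edge_j[e]], nh[edge_i[e], edge_j[e]],
            T[edge_i[e], edge_j[e]])
    for i in range(n):
        prod = beta[i]
        if i == input_target:
            prod *= u
        for e in range(E):
            if edge_i[e] == i:
                prod *= h_c[e]
        f[i] = prod - gamma[i] * x[i]
        Jx[i, i] -= gamma[i]
        Jt[i, i] = prod  # d/d log beta_i
        Jt[i, n + i] = -gamma[i] * x[i]  # d/d log gamma_i
    for e in range(E):
        i = edge_i[e]
        others = beta[i]
        if i == input_target:
            others *= u
        for e2 in range(E):
            if e2 != e and edge_i[e2] == i:
                others *= h_c[e2]
        Jx[i, edge_j[e]] += others * dhx_c[e]
        Jt[i, 2 * n + e] = others * KdK_c[e]
        Jt[i, 2 * n + E + e] = others * dhn_c[e]


@njit(cache=True)
def _rk4_states(T, beta, gamma, K, nh, input_target, u1, u2, n1, n_total, dt, x0, out):
    """Integrate states only.  Returns the first step index with a non-finite
    state, or -1 on success.  ``out`` has shape (n_total+1, n)."""
    n = x0.shape[0]
    x = x0.copy()
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    xs = np.empty(n)
    out[0] = x
    for step in range(n_total):
        u = u1 if step < n1 else u2
        _rhs(T, beta, gamma, K, nh, input_target, u, x, k1)
        for i in range(n):
            xs[i] = x[i] + 0.5 * dt * k1[i]
        _rhs(T, beta, gamma, K, nh, input_target, u, xs, k2)
        for i in range(n):
            xs[i] = x[i] + 0.5 * dt * k2[i]
        _rhs(T, beta, gamma, K, nh, input_target, u, xs, k3)
        for i in range(n):
            xs[i] = x[i] + dt * k3[i]
        _rhs(T, beta, gamma, K, nh, input_target, u, xs, k4)
        ok = True
        for i in range(n):
            x[i] = x[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if not np.isfinite(x[i]):
                ok = False
        out[step + 1] = x
        if not ok:
            return step + 1
    return -1


@njit(cache=True)
def _rk4_tangents(T, beta, gamma, K, nh, input_target, u1, u2, n1, n_total, dt,
                  x0, edge_i, edge_j, out_y, out_S, output_index):
    """Integrate states and tangents; record the full state and the output
    gene's tangent row (out_S, shape (n_total+1, P)).  Returns the failing
    step index or -1."""
    n = x0.shape[0]
    E = edge_i.shape[0]
    P = 2 * n + 2 * E
    x = x0.copy()
    S = np.zeros((n, P))
    f = np.empty(n)
    Jx = np.empty((n, n))
    Jt = np.empty((n, P))
    kx = np.empty((4, n))
    kS = np.empty((4, n, P))
    xs = np.empty(n)
    Ss = np.empty((n, P))
    h_c = np.empty(E)
    dhx_c = np.empty(E)
    KdK_c = np.empty(E)
    dhn_c = np.empty(E)
    out_y[0] = x
    for p in range(P):
        out_S[0, p] = 0.0
    for step in range(n_total):
        u = u1 if step < n1 else u2
        for stage in range(4):
            if stage == 0:
                for i in range(n):
                    xs[i] = x[i]
                    for p in range(P):
                        Ss[i, p] = S[i, p]
            else:
                c = 0.5 * dt if stage < 3 else dt
                for i in range(n):
                    xs[i] = x[i] + c * kx[stage - 1, i]
                    for p in range(P):
                        Ss[i, p] = S[i, p] + c * kS[stage - 1, i, p]
            _rhs_jac(T, beta, gamma, K, nh, input_target, u, edge_i, edge_j,
                     xs, f, Jx, Jt, h_c, dhx_c, KdK_c, dhn_c)
            for i in range(n):
                kx[stage, i] = f[i]
                for p in range(P):
                    acc = Jt[i, p]
                    for j in range(n):
                        acc += Jx[i, j] * Ss[j, p]
                    kS[stage, i, p] = acc
        ok = True
        for i in range(n):
            x[i] += dt / 6.0 * (kx[0, i] + 2.0 * kx[1, i] + 2.0 * kx[2, i] + kx[3, i])
            if not np.isfinite(x[i]):
                ok = False
            for p in range(P):
                S[i, p] += dt / 6.0 * (kS[0, i, p] + 2.0 * kS[1, i, p]
                                       + 2.0 * kS[2, i, p] + kS[3, i, p])
        out_y[step + 1] = x
        for p in range(P):
            out_S[step + 1, p] = S[output_index, p]
        if not ok:
            return step + 1
    return -1


def grid_steps(inp: StepInput, dt: float) -> tuple[int, int]:
    """(steps before t_step, total steps); requires both on the dt grid."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n1 = round(inp.t_step / dt)
    n_total = round(inp.t_end / dt)
    if abs(n1 * dt - inp.t_step) > 1e-9 * max(1.0, inp.t_step) or n1 < 1:
        raise ValueError(f"t_step={inp.t_step} is not on the dt={dt} grid")
    if abs(n_total * dt - inp.t_end) > 1e-9 * max(1.0, inp.t_end) or n_total <= n1:
        raise ValueError(f"t_end={inp.t_end} is not on the dt={dt} grid")
    return n1, n_total


def _kernel_args(circuit: GeneCircuit):
    p = circuit.params()
    return (circuit.topology, p.beta, p.gamma, p.K, p.n_hill, circuit.input_target)


def simulate_circuit(circuit: GeneCircuit, inp: StepInput, dt: float = 0.01,
                     x0: np.ndarray | None = None) -> Trajectory:
    """Fixed-step RK4 integration over [0, t_end]; the grid includes t_step
    exactly and the input switches from u1 to u2 there."""
    n1, n_total = grid_steps(inp, dt)
    n = circuit.n_genes
    if x0 is None:
        x0 = np.zeros(n)
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("x0 must be >= 0")
    out = np.empty((n_total + 1, n))
    T, beta, gamma, K, nh, tgt = _kernel_args(circuit)
    fail = _rk4_states(T, beta, gamma, K, nh, tgt, inp.u1, inp.u2, n1, n_total, dt, x0, out)
    if fail >= 0:
        raise IntegrationError(f"non-finite state at t={fail * dt:g}")
    times = dt * np.arange(n_total + 1)
    return Trajectory(times=times, states=out)


def simulate_with_tangents(circuit: GeneCircuit, inp: StepInput, dt: float = 0.01,
                           x0: np.ndarray | None = None):
    """As :func:`simulate_circuit`, also returning the output gene's tangent
    d output(t) / d [log β, log γ, log K, n-per-edge] as an (M, P) array.

    Raises :class:`IntegrationError` on non-finite states.
    """
    n1, n_total = grid_steps(inp, dt)
    n = circuit.n_genes
    if x0 is None:
        x0 = np.zeros(n)
    x0 = np.asarray(x0, dtype=float)
    edge_i, edge_j = circuit.edges
    P = 2 * n + 2 * len(edge_i)
    out_y = np.empty((n_total + 1, n))
    out_S = np.empty((n_total + 1, P))
    T, beta, gamma, K, nh, tgt = _kernel_args(circuit)
    fail = _rk4_tangents(T, beta, gamma, K, nh, tgt, inp.u1, inp.u2, n1, n_total, dt,
                         x0, edge_i, edge_j, out_y, out_S, circuit.output_index)
    if fail >= 0:
        raise IntegrationError(f"non-finite state at t={fail * dt:g}")
    times = dt * np.arange(n_total + 1)
    return Trajectory(times=times, states=out_y), out_S
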