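"""Gene-circuit model, solver, metrics, gradients, and optimization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synbio_forge import RngKey, split_key
from synbio_forge.circuit import (
    Adam,
    CircuitParams,
    DegenerateBaselineError,
    GeneCircuit,
    NotSteadyError,
    StepInput,
    Trajectory,
    activation_cascade,
    adaptation_loss,
    adaptation_metrics,
    batch_optimize,
    circuit_rhs,
    hill_term,
    incoherent_feedforward,
    load_topology,
    loss_gradient,
    optimize_circuit,
    random_circuit,
    save_topology,
    simulate_circuit,
    single_gene,
)
from synbio_forge.circuit.metrics import softplus


class TestHillTerm:
    @given(K=st.floats(0.05, 10.0), n=st.floats(1.0, 8.0))
    @settings(max_examples=50, deadline=None)
    def test_half_saturation_is_half_for_any_k_and_n(self, K, n):
        assert hill_term(K, K, n, +1) == pytest.approx(0.5)
        assert hill_term(K, K, n, -1) == pytest.approx(0.5)

    def test_zero_input_limits(self):
        assert hill_term(0.0, 2.0, 3.0, +1) == 0.0
        assert hill_term(0.0, 2.0, 3.0, -1) == 1.0

    def test_hand_value(self):
        # x=3, K=1, n=2: 9/(1+9)
        assert hill_term(3.0, 1.0, 2.0, +1) == pytest.approx(0.9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill_term(-0.1, 1.0, 2.0, +1)
        with pytest.raises(ValueError):
            hill_term(1.0, 0.0, 2.0, +1)

    def test_activation_and_repression_sum_to_one(self):
        x = np.linspace(0, 5, 11)
        total = hill_term(x, 1.3, 2.5, +1) + hill_term(x, 1.3, 2.5, -1)
        np.testing.assert_allclose(total, 1.0)


class TestCircuitRhs:
    def test_pure_decay_when_beta_zero(self, iffl):
        T, tgt, out = iffl
        eps = 1e-12  # parameters must be positive; use a negligible beta
        params = CircuitParams(beta=np.full(3, eps), gamma=np.array([1.0, 2.0, 0.5]),
                               K=np.ones((3, 3)), n_hill=np.full((3, 3), 2.0))
        c = GeneCircuit.from_params(T, tgt, out, params)
        state = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(circuit_rhs(c, state, 1.0),
                                   -params.gamma * state, atol=1e-10)

    def test_unregulated_gene_fixed_point(self, linear_gene):
        # x = beta*u/gamma is a fixed point of dx/dt = beta*u - gamma*x
        rhs = circuit_rhs(linear_gene, np.array([2.0]), u=1.0)
        np.testing.assert_allclose(rhs, 0.0, atol=1e-14)

    def test_iffl_rhs_matches_hand_evaluation(self, iffl):
        T, tgt, out = iffl
        params = CircuitParams(
            beta=np.array([1.0, 2.0, 3.0]), gamma=np.array([0.5, 1.0, 1.5]),
            K=np.full((3, 3), 2.0), n_hill=np.full((3, 3), 2.0))
        c = GeneCircuit.from_params(T, tgt, out, params)
        x = np.array([1.0, 2.0, 0.5])
        u = 1.2
        act = lambda v: v**2 / (4.0 + v**2)
        rep = lambda v: 4.0 / (4.0 + v**2)
        expected = np.array([
            1.0 * u - 0.5 * 1.0,
            2.0 * act(1.0) - 1.0 * 2.0,
            3.0 * act(1.0) * rep(2.0) - 1.5 * 0.5,
        ])
        np.testing.assert_allclose(circuit_rhs(c, x, u), expected, rtol=1e-12)

    def test_kernel_rhs_agrees_with_reference(self, iffl, key):
        """One RK4 micro-step of the compiled kernel reproduces the Euler
        limit of the reference RHS (cross-implementation check)."""
        T, tgt, out = iffl
        c = random_circuit(T, tgt, out, key, calibrate=False)
        x0 = np.array([0.4, 1.1, 0.2])
        dt = 1e-6
        inp = StepInput(u1=1.3, u2=1.5, t_step=5 * dt, t_end=10 * dt)
        traj = simulate_circuit(c, inp, dt=dt, x0=x0)
        fd_rhs = (traj.states[1] - traj.states[0]) / dt
        np.testing.assert_allclose(fd_rhs, circuit_rhs(c, x0, 1.3), rtol=1e-5)


class TestSimulate:
    def test_closed_form_linear_gene(self, linear_gene):
        """beta=2, gamma=1, x0=0: x(1) = 2(1 - e^-1)."""
        inp = StepInput(u1=1.0, u2=1.5, t_step=50.0, t_end=100.0)
        traj = simulate_circuit(linear_gene, inp, dt=0.01)
        assert traj.states[100, 0] == pytest.approx(2 * (1 - np.exp(-1)), abs=1e-8)

    def test_zero_initial_state_with_negligible_beta_stays_zero(self):
        T, tgt, out = single_gene()
        params = CircuitParams(beta=np.array([1e-300]), gamma=np.array([1.0]),
                               K=np.ones((1, 1)), n_hill=np.ones((1, 1)))
        c = GeneCircuit.from_params(T, tgt, out, params)
        traj = simulate_circuit(c, StepInput(1.0, 2.0, 1.0, 2.0), dt=0.01)
        np.testing.assert_allclose(traj.states, 0.0, atol=1e-290)

    def test_grid_contains_t_step_exactly(self, linear_gene):
        traj = simulate_circuit(linear_gene, StepInput(1.0, 2.0, 12.34, 20.0), dt=0.01)
        assert np.isclose(traj.times, 12.34, atol=1e-12).any()

    def test_off_grid_t_step_rejected(self, linear_gene):
        with pytest.raises(ValueError, match="grid"):
            simulate_circuit(linear_gene, StepInput(1.0, 2.0, 0.105, 1.0), dt=0.01)

    def test_rk4_convergence_order(self, linear_gene):
        """Global error vs closed form shrinks at ~4th order in dt."""
        inp = StepInput(u1=1.0, u2=1.5, t_step=0.5, t_end=1.0)
        x_half = 2 * (1 - np.exp(-0.5))
        exact = 3.0 + (x_half - 3.0) * np.exp(-0.5)
        dts = np.array([0.1, 0.05, 0.025])
        errs = [abs(simulate_circuit(linear_gene, inp, dt=dt).states[-1, 0] - exact)
                for dt in dts]
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert slope >= 3.8

    def test_random_circuits_stay_nonnegative(self, iffl, key):
        T, tgt, out = iffl
        inp = StepInput(u1=1.0, u2=1.5, t_step=20.0, t_end=40.0)
        for k in split_key(key, 10):
            c = random_circuit(T, tgt, out, k, calibrate=False)
            traj = simulate_circuit(c, inp, dt=0.01)
            assert traj.states.min() >= -1e-9


def _triangle_trajectory():
    """Synthetic output: O1=1 before the step, peak 1.5 at t=60, O2=1.1."""
    times = np.linspace(0.0, 100.0, 10001)
    y = np.ones_like(times)
    post = times >= 50.0
    y[post] = np.interp(times[post], [50.0, 60.0, 100.0], [1.0, 1.5, 1.1])
    return Trajectory(times=times, states=y[:, None])


class TestMetrics:
    def test_triangle_pulse_hand_values(self):
        res = adaptation_metrics(_triangle_trajectory(), StepInput(1.0, 1.2, 50.0, 100.0), 0)
        assert res.sensitivity == pytest.approx(2.5)
        assert res.precision_error == pytest.approx(0.5)

    def test_flat_output_scores_zero(self):
        times = np.linspace(0.0, 100.0, 1001)
        traj = Trajectory(times=times, states=np.full((1001, 1), 2.0))
        res = adaptation_metrics(traj, StepInput(1.0, 1.5, 50.0, 100.0), 0)
        assert res.sensitivity == 0.0 and res.precision_error == 0.0

    def test_perfect_adaptation_zero_precision_positive_sensitivity(self):
        times = np.linspace(0.0, 100.0, 10001)
        y = np.ones_like(times)
        post = times >= 50.0
        y[post] = 1.0 + 0.8 * np.sin(np.clip((times[post] - 50) / 20, 0, 1) * np.pi) ** 2 \
            * np.exp(-(times[post] - 50) / 10)
        y[-1] = 1.0
        traj = Trajectory(times=times, states=y[:, None])
        res = adaptation_metrics(traj, StepInput(1.0, 1.5, 50.0, 100.0), 0)
        assert res.precision_error == pytest.approx(0.0, abs=1e-9)
        assert res.sensitivity > 0.5

    def test_drifting_baseline_rejected(self):
        times = np.linspace(0.0, 100.0, 1001)
        y = 1.0 + 0.01 * times
        traj = Trajectory(times=times, states=y[:, None])
        with pytest.raises(NotSteadyError):
            adaptation_metrics(traj, StepInput(1.0, 1.5, 50.0, 100.0), 0)

    def test_zero_baseline_rejected(self):
        times = np.linspace(0.0, 100.0, 1001)
        y = np.where(times > 50.0, 1.0, 0.0)  # exactly zero up to and at t_step
        traj = Trajectory(times=times, states=y[:, None])
        with pytest.raises(DegenerateBaselineError):
            adaptation_metrics(traj, StepInput(1.0, 1.5, 50.0, 100.0), 0)

    def test_loss_at_target_sensitivity_is_w_ln2(self):
        assert adaptation_loss(0.5, 0.0, s_min=0.5, w=1.3) == pytest.approx(1.3 * np.log(2))

    def test_loss_monotone_in_precision_error(self):
        pes = np.linspace(0.0, 2.0, 20)
        losses = adaptation_loss(1.0, pes)
        assert (np.diff(losses) > 0).all()

    def test_loss_near_zero_for_ideal_circuit(self):
        assert adaptation_loss(10.0, 0.0) == pytest.approx(0.0, abs=1e-4)

    def test_softplus_matches_naive_form_in_safe_range(self):
        x = np.linspace(-20, 20, 41)
        np.testing.assert_allclose(softplus(x), np.log1p(np.exp(x)), rtol=1e-12)


class TestGradient:
    def _fd_loss(self, circuit, inp, theta):
        """Independent route: public simulate + metrics, no tangents."""
        c = circuit.with_log_params(theta)
        traj = simulate_circuit(c, inp, dt=0.01)
        res = adaptation_metrics(traj, inp, c.output_index)
        return res.loss, res.peak_time

    def test_gradient_matches_central_finite_differences(self, iffl, step_input, key):
        T, tgt, out = iffl
        checked = 0
        for k in split_key(key, 8):
            c = random_circuit(T, tgt, out, k)
            try:
                loss, grad = loss_gradient(c, step_input)
            except Exception:
                continue
            if loss >= 1e3:  # penalty path has no defined gradient
                continue
            theta = c.log_params
            h = 1e-4
            for p in np.argsort(-np.abs(grad))[:6]:  # largest components
                tp, tm = theta.copy(), theta.copy()
                tp[p] += h
                tm[p] -= h
                lp, peak_p = self._fd_loss(c, step_input, tp)
                lm, peak_m = self._fd_loss(c, step_input, tm)
                if peak_p != peak_m:
                    continue  # stencil straddles a peak-relocation kink; FD invalid there
                fd = (lp - lm) / (2 * h)
                if abs(grad[p]) > 1e-8:
                    assert abs(grad[p] - fd) / abs(grad[p]) < 1e-3
            checked += 1
        assert checked >= 5

    def test_disconnected_gene_has_zero_gradient(self, step_input, key):
        """A gene with no path to the output cannot influence the loss."""
        T = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0]])  # gene 1 dangles off-output
        c = random_circuit(T, 0, 2, key, calibrate=False)
        loss, grad = loss_gradient(c, step_input)
        n = 3
        # beta/gamma of gene 1 and the 1<-0 edge parameters are inert
        edge_i, _ = c.edges
        inert = [1, n + 1] + [2 * n + e for e, gi in enumerate(edge_i) if gi == 1] \
            + [2 * n + len(edge_i) + e for e, gi in enumerate(edge_i) if gi == 1]
        np.testing.assert_allclose(grad[inert], 0.0, atol=1e-12)


class TestOptimize:
    def test_adam_minimizes_a_quadratic(self):
        """Convex oracle: Adam drives ||x - target||^2 to its known minimum."""
        target = np.array([3.0, -1.0, 0.5])
        opt = Adam(3, lr=0.1)
        x = np.zeros(3)
        for _ in range(200):
            x = opt.update(x, 2 * (x - target))
        np.testing.assert_allclose(x, target, atol=1e-2)

    def test_zero_learning_rate_changes_nothing(self, iffl, step_input, key):
        T, tgt, out = iffl
        c = random_circuit(T, tgt, out, key)
        r = optimize_circuit(c, step_input, steps=5, lr=0.0)
        np.testing.assert_array_equal(r.circuit.log_params, c.log_params)
        finite = r.history[np.isfinite(r.history)]
        assert np.ptp(finite) == 0.0

    def test_history_length_and_improvement_flag(self, iffl, step_input, key):
        T, tgt, out = iffl
        c = random_circuit(T, tgt, out, key.child(5))
        r = optimize_circuit(c, step_input, steps=40, lr=0.05)
        assert len(r.history) == 40
        assert r.improved or r.failed

    def test_batch_equals_loop_and_order_independence(self, iffl, step_input, key):
        T, tgt, out = iffl
        circuits = [random_circuit(T, tgt, out, k) for k in split_key(key, 3)]
        batch = batch_optimize(circuits, step_input, steps=8, lr=0.05)
        loop = [optimize_circuit(c, step_input, steps=8, lr=0.05) for c in circuits]
        for b, s in zip(batch, loop):
            np.testing.assert_array_equal(b.history, s.history)
            np.testing.assert_array_equal(b.circuit.log_params, s.circuit.log_params)
        perm = batch_optimize(circuits[::-1], step_input, steps=8, lr=0.05)
        np.testing.assert_array_equal(perm[0].history, batch[2].history)

    def test_activation_cascade_cannot_learn_adaptation(self, step_input, key):
        """A monotone all-activation cascade has no mechanism for a transient
        peak, so the same optimization budget that makes the incoherent
        feedforward loop adapt produces no adapting cascades."""
        T, tgt, out = activation_cascade()
        successes = 0
        for k in split_key(key, 8):
            c = random_circuit(T, tgt, out, k)
            r = optimize_circuit(c, step_input, steps=500, lr=0.05)
            m = r.final_metrics
            if m is not None and m.precision_error < 0.1 and m.sensitivity > 0.5:
                successes += 1
        assert successes == 0

    def test_mixed_topologies_rejected(self, iffl, step_input, key):
        T, tgt, out = iffl
        Tc, tc, oc = activation_cascade()
        with pytest.raises(ValueError, match="topology"):
            batch_optimize([random_circuit(T, tgt, out, key),
                            random_circuit(Tc, tc, oc, key)], step_input, steps=2)


class TestTopologyIO:
    def test_round_trip(self, tmp_path, iffl):
        T, tgt, out = iffl
        path = tmp_path / "topo.txt"
        save_topology(path, T, tgt, out)
        T2, tgt2, out2 = load_topology(path)
        np.testing.assert_array_equal(T, T2)
        assert (tgt, out) == (tgt2, out2)

    def test_truncated_file_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("3\n0 0 0\n")
        with pytest.raises(ValueError):
            load_topology(path)
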