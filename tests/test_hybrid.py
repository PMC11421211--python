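"""Hybrid tau-leaping/Euler simulator: contracts and statistical oracles."""

import numpy as np
import pytest

from synbio_forge import RngKey, split_key
from synbio_forge.hybrid import (
    HybridModel,
    HybridState,
    ModelDefinitionError,
    Reaction,
    birth_death_model,
    birth_death_x0,
    bundled_cell_model,
    bundled_initial_state,
    decay_euler_model,
    dimerization_model,
    simulate_batch,
    simulate_hybrid,
    ssa_exact,
    tau_leap_step,
    time_average,
)
from synbio_forge.hybrid.modelfile import ModelFileError, load_model


class TestModelValidation:
    def test_partition_must_cover_and_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            HybridModel(("a", "b"), np.array([0, 1]), np.array([1]), (),
                        lambda x, p: np.zeros(x.shape[:-1] + (1,)), {})
        with pytest.raises(ValueError, match="cover"):
            HybridModel(("a", "b"), np.array([0]), np.array([], dtype=int), (),
                        lambda x, p: np.zeros(x.shape[:-1] + (0,)), {})

    def test_reaction_on_deterministic_species_rejected(self):
        rxn = Reaction("bad", {"b": 1}, lambda x, p: x[..., 0])
        with pytest.raises(ValueError, match="non-stochastic"):
            HybridModel(("a", "b"), np.array([0]), np.array([1]), (rxn,),
                        lambda x, p: np.zeros(x.shape[:-1] + (1,)), {})

    def test_negative_propensity_names_the_reaction(self, key):
        rxn = Reaction("backwards", {"X": 1}, lambda x, p: -np.ones(x.shape[:-1]))
        m = HybridModel(("X",), np.array([0]), np.array([], dtype=int), (rxn,),
                        lambda x, p: np.zeros(x.shape[:-1] + (0,)), {})
        state = HybridState(counts=np.array([1.0]), levels=np.array([]))
        with pytest.raises(ModelDefinitionError, match="backwards"):
            tau_leap_step(m, state, 0.1, key)


class TestTauLeapStep:
    def test_null_dynamics_only_advances_time(self, key):
        m = birth_death_model(k=50.0, gamma=1.0)
        m = HybridModel(m.species_names, m.stoch_idx, m.det_idx,
                        (Reaction("off", {"X": 1}, lambda x, p: np.zeros(x.shape[:-1])),),
                        m.drift, m.params)
        s0 = HybridState(counts=np.array([7.0]), levels=np.array([]), t=1.0)
        s1 = tau_leap_step(m, s0, 0.5, key)
        assert s1.counts[0] == 7.0 and s1.t == 1.5

    def test_pure_birth_poisson_mean(self, key):
        """Total births over M steps at constant rate a has mean a*M*tau."""
        m = birth_death_model(k=80.0, gamma=0.0)
        x0 = HybridState(counts=np.array([0.0]), levels=np.array([]))
        batch = simulate_batch(m, x0, 0.05, 0.005, 2000, key)  # 10 steps each
        finals = batch.states[:, -1, 0]
        expected = 80.0 * 0.05
        se = np.sqrt(expected / 2000)  # Poisson variance = mean
        assert abs(finals.mean() - expected) < 4 * se

    def test_deterministic_partition_is_exact_forward_euler(self, key):
        m = decay_euler_model(rate=1.0)
        x0 = HybridState(counts=np.array([]), levels=np.array([1.0]))
        traj = simulate_hybrid(m, x0, 1.0, 0.001, key)
        y = 1.0
        for _ in range(1000):
            y -= y * 0.001
        assert traj.states[-1, 0] == pytest.approx(y, abs=1e-14)

    def test_counts_never_negative_even_with_overdraw(self, key):
        """A huge death propensity cannot push clamped counts below zero."""
        m = birth_death_model(k=0.0, gamma=100.0)
        x0 = HybridState(counts=np.array([3.0]), levels=np.array([]))
        traj = simulate_hybrid(m, x0, 1.0, 0.1, key)
        assert traj.states.min() >= 0.0


class TestSimulate:
    def test_t_end_equal_tau_is_one_step(self, key):
        m = birth_death_model()
        traj = simulate_hybrid(m, birth_death_x0(), 0.01, 0.01, key)
        assert len(traj.times) == 2

    def test_same_key_reproduces_bitwise(self, key):
        m = birth_death_model()
        a = simulate_hybrid(m, birth_death_x0(), 2.0, 0.01, key)
        b = simulate_hybrid(m, birth_death_x0(), 2.0, 0.01, key)
        np.testing.assert_array_equal(a.states, b.states)

    def test_manual_steps_match_simulate(self, key):
        """simulate_hybrid is exactly repeated tau_leap_step with per-step
        child keys."""
        m = dimerization_model()
        state = HybridState(counts=np.array([40.0, 5.0]), levels=np.array([]))
        for i, ck in enumerate(split_key(key, 5)):
            state = tau_leap_step(m, state, 0.01, ck)
        traj = simulate_hybrid(m, HybridState(counts=np.array([40.0, 5.0]),
                                              levels=np.array([])), 0.05, 0.01, key)
        np.testing.assert_array_equal(traj.states[-1, :2], state.counts)

    def test_batch_equals_loop_bitwise(self, key):
        m = dimerization_model()
        x0 = HybridState(counts=np.array([40.0, 5.0]), levels=np.array([]))
        batch = simulate_batch(m, x0, 0.5, 0.01, 5, key)
        for i, ck in enumerate(split_key(key, 5)):
            single = simulate_hybrid(m, x0, 0.5, 0.01, ck)
            np.testing.assert_array_equal(batch.states[i], single.states)

    def test_replicates_are_prefix_stable_across_batch_sizes(self, key):
        m = birth_death_model()
        small = simulate_batch(m, birth_death_x0(), 0.2, 0.01, 4, key)
        large = simulate_batch(m, birth_death_x0(), 0.2, 0.01, 8, key)
        np.testing.assert_array_equal(small.states, large.states[:4])

    def test_record_stride_subsamples_the_grid(self, key):
        m = birth_death_model()
        full = simulate_hybrid(m, birth_death_x0(), 0.1, 0.01, key)
        thin = simulate_hybrid(m, birth_death_x0(), 0.1, 0.01, key, record_stride=5)
        np.testing.assert_array_equal(thin.times, full.times[::5])
        np.testing.assert_array_equal(thin.states, full.states[::5])

    def test_diverging_deterministic_level_is_flagged_not_raised(self, key):
        m = decay_euler_model(rate=-60.0)  # exponential growth, Euler overflows
        x0 = HybridState(counts=np.array([]), levels=np.array([1.0]))
        batch = simulate_batch(m, x0, 60.0, 0.1, 2, key)
        assert batch.failed.all()
        assert np.isfinite(batch.failure_times).all()


class TestStatistics:
    def test_birth_death_stationary_mean(self, key):
        """Linear birth-death: stationary law Poisson(k/gamma), mean 50."""
        m = birth_death_model(k=50.0, gamma=1.0)
        batch = simulate_batch(m, birth_death_x0(), 40.0, 0.001, 4, key,
                               record_stride=20)
        x = batch.states[:, batch.times >= 10.0, 0]
        per_rep = x.mean(axis=1)
        se = per_rep.std(ddof=1) / np.sqrt(len(per_rep))
        assert abs(per_rep.mean() - 50.0) < 4 * se + 1.0

    def test_ssa_absorbing_state_halts(self, key):
        m = birth_death_model(k=0.0, gamma=1.0)
        x0 = HybridState(counts=np.array([0.0]), levels=np.array([]))
        traj = ssa_exact(m, x0, 10.0, key)
        assert len(traj.times) == 1
        np.testing.assert_array_equal(time_average(traj), [0.0])

    def test_ssa_birth_death_stationary_mean(self, key):
        m = birth_death_model(k=20.0, gamma=1.0)
        x0 = HybridState(counts=np.array([20.0]), levels=np.array([]))
        means = [time_average(ssa_exact(m, x0, 60.0, k), t_start=10.0)[0]
                 for k in split_key(key, 4)]
        se = np.std(means, ddof=1) / 2
        assert abs(np.mean(means) - 20.0) < 4 * se + 0.5

    def test_tau_leap_bias_grows_with_tau(self, key):
        """Clamping and first-order splitting bias the dimerization model;
        the deviation from the fine-tau reference grows monotonically in tau."""
        m = dimerization_model(k_in=40.0, k_dim=0.05, k_deg=0.5)
        x0 = HybridState(counts=np.array([20.0, 10.0]), levels=np.array([]))

        def stationary_monomer(tau):
            batch = simulate_batch(m, x0, 30.0, tau, 8, key, record_stride=max(1, int(0.05 / tau)))
            return batch.states[:, batch.times >= 10.0, 0].mean()

        ref = stationary_monomer(0.001)
        errs = [abs(stationary_monomer(tau) - ref) for tau in (0.01, 0.04)]
        assert errs[1] > errs[0]


class TestBundledCellModel:
    def test_partition_is_11_stochastic_6_deterministic(self):
        m = bundled_cell_model()
        assert len(m.stoch_idx) == 11
        assert len(m.det_idx) == 6

    def test_fused_propensities_match_reaction_rules(self, key):
        m = bundled_cell_model()
        rng = key.generator()
        x0 = bundled_initial_state().full(m)
        states = x0[None, :] * rng.uniform(0.5, 1.5, size=(20, m.n_species))
        fused = m.propensity_fn(states, m.params)
        manual = np.stack([r.propensity(states, m.params) for r in m.reactions], axis=-1)
        np.testing.assert_allclose(fused, manual, rtol=1e-12)

    def test_short_run_keeps_positive_expression(self, key):
        """With nutrient and no antibiotic, circuit proteins hold a positive
        quasi-steady band."""
        traj = simulate_hybrid(bundled_cell_model(), bundled_initial_state(),
                               15.0, 2e-3, key, record_stride=50)
        assert not traj.failed
        last = traj.states[traj.times >= 11.25]
        names = traj.species_names
        for i, name in enumerate(names):
            if name.startswith("p_"):
                assert last[:, i].mean() > 0, name

    def test_circuit_load_competes_for_ribosomal_output(self, key):
        """Doubling a circuit gene's transcription lowers time-averaged
        ribosomal protein (resource competition, sign only)."""
        base = bundled_cell_model()
        loaded = bundled_cell_model(k_tx_c1=2 * base.params["k_tx_c1"])
        x0 = bundled_initial_state()
        a = simulate_hybrid(base, x0, 20.0, 2e-3, key, record_stride=100)
        b = simulate_hybrid(loaded, x0, 20.0, 2e-3, key, record_stride=100)
        i_rib = base.species_names.index("p_rib")
        sel = a.times >= 10.0
        assert b.states[sel, i_rib].mean() < a.states[sel, i_rib].mean()

    def test_unknown_parameter_override_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            bundled_cell_model(k_nonsense=1.0)

    def test_antibiotic_depresses_ribosomes(self, key):
        drugged = bundled_cell_model(ab_ext=2.0)
        x0 = bundled_initial_state()
        a = simulate_hybrid(bundled_cell_model(), x0, 10.0, 2e-3, key, record_stride=100)
        b = simulate_hybrid(drugged, x0, 10.0, 2e-3, key, record_stride=100)
        i_rib = a.species_names.index("p_rib")
        assert b.states[-1, i_rib] < a.states[-1, i_rib]


class TestModelFile:
    def test_fixture_round_trip(self, tmp_path, key):
        from synbio_forge.io import make_fixtures

        (path,) = make_fixtures("cell", 0, tmp_path)
        model, x0 = load_model(path)
        assert len(model.stoch_idx) == 3 and len(model.det_idx) == 2
        traj = simulate_hybrid(model, x0, 1.0, 0.01, key)
        assert not traj.failed

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("species:\n  - {name: A, kind: stochastic}\nbogus: 1\n")
        with pytest.raises(ModelFileError, match="bogus"):
            load_model(p)

    def test_reaction_on_unknown_species_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text(
            "species:\n  - {name: A, kind: stochastic}\n"
            "reactions:\n  - {stoich: {B: 1}, rate: {law: constant, k: 1.0}}\n")
        with pytest.raises(ModelFileError, match="B"):
            load_model(p)

    def test_mass_action_order_two_is_combinatorial(self, tmp_path, key):
        p = tmp_path / "m.yaml"
        p.write_text(
            "species:\n  - {name: A, kind: stochastic}\n"
            "reactions:\n  - {name: dim, stoich: {A: -2}, "
            "rate: {law: mass_action, k: 1.0, reactants: {A: 2}}}\n"
            "initial: {A: 10}\n")
        model, x0 = load_model(p)
        a = model.propensities(x0.full(model))
        assert a[0] == pytest.approx(10 * 9 / 2)
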