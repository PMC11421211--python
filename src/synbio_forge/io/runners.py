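"""Engine runners behind the CLI: config in, result directory out.

Each runner derives all randomness from the config's root seed, logs stage
names to the run record, and writes tables through :func:`write_results`
so reruns with identical configs are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ..engine import RngKey, split_key
from .config import RunConfig
from .results import RunRecord, write_results

__all__ = ["run_config", "parse_policy"]

log = logging.getLogger("synbio_forge")


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        log.addHandler(h)


def parse_policy(text: str):
    """'truncation:0.1' / 'tournament:3' / 'uniform' → a selection policy."""
    from ..nk import Tournament, Truncation, Uniform

    name, _, arg = text.partition(":")
    if name == "truncation":
        return Truncation(float(arg) if arg else 0.1)
    if name == "tournament":
        return Tournament(int(arg) if arg else 2)
    if name == "uniform":
        return Uniform()
    raise ValueError(f"unknown selection policy {text!r}")


def _run_circuit_optimize(cfg: RunConfig, record: RunRecord, key: RngKey):
    from ..circuit import (batch_optimize, incoherent_feedforward, activation_cascade,
                           load_topology, random_circuit, simulate_circuit, StepInput)

    p = cfg.params
    if p.topology == "iffl":
        topo, tgt, out_idx = incoherent_feedforward()
    elif p.topology == "cascade":
        topo, tgt, out_idx = activation_cascade()
    else:
        topo, tgt, out_idx = load_topology(p.topology)
    inp = StepInput(u1=p.u1, u2=p.u2, t_step=p.t_step, t_end=p.t_end)
    record.log("random_circuit")
    circuits = [random_circuit(topo, tgt, out_idx, k, u=p.u1)
                for k in split_key(key, p.n_circuits)]
    record.log("batch_optimize")
    results = batch_optimize(circuits, inp, steps=p.steps, lr=p.lr, dt=p.dt,
                             s_min=p.s_min, w=p.w)
    hist = pd.DataFrame([
        {"circuit": i, "step": s, "loss": r.history[s]}
        for i, r in enumerate(results) for s in range(len(r.history))
    ])
    summary = {"circuits": []}
    best_i, best_loss = 0, np.inf
    for i, r in enumerate(results):
        m = r.final_metrics
        entry = {
            "circuit": i, "failed": r.failed, "improved": r.improved,
            "penalized": r.penalized,
            "final_loss": float(np.nanmin(r.history)) if np.isfinite(r.history).any() else None,
            "log_params": r.circuit.log_params.tolist(),
        }
        if m is not None:
            entry.update(sensitivity=m.sensitivity, precision_error=m.precision_error,
                         O1=m.O1, O_peak=m.O_peak, O2=m.O2)
        summary["circuits"].append(entry)
        if entry["final_loss"] is not None and entry["final_loss"] < best_loss:
            best_i, best_loss = i, entry["final_loss"]
    record.log("simulate_circuit")
    traj = simulate_circuit(results[best_i].circuit, inp, dt=p.dt)
    traj_df = pd.DataFrame(traj.states, columns=[f"gene_{g}" for g in range(topo.shape[0])])
    traj_df.insert(0, "time", traj.times)
    summary["best_circuit"] = best_i
    return {"loss_history": hist, "best_trajectory": traj_df}, summary


def _run_cell_sim(cfg: RunConfig, record: RunRecord, key: RngKey):
    from ..hybrid import bundled_cell_model, bundled_initial_state, simulate_batch
    from ..hybrid.modelfile import load_model

    p = cfg.params
    if p.model == "bundled":
        model, x0 = bundled_cell_model(), bundled_initial_state()
    else:
        model, x0 = load_model(p.model)
    record.log("simulate_batch")
    batch = simulate_batch(model, x0, p.t_end, p.tau, p.n_traj, key,
                           record_stride=p.record_stride)
    reps, M, D = batch.states.shape
    df = pd.DataFrame(batch.states.reshape(reps * M, D), columns=list(model.species_names))
    df.insert(0, "time", np.tile(batch.times, reps))
    df.insert(0, "replicate", np.repeat(np.arange(reps), M))
    import hashlib

    model_id = hashlib.sha256(
        repr((model.species_names, tuple(sorted(model.params.items())),
              tuple(r.name for r in model.reactions))).encode()).hexdigest()[:16]
    summary = {
        "n_traj": reps, "tau": p.tau, "t_end": p.t_end, "model": p.model,
        "model_hash": model_id,
        "n_stochastic": int(len(model.stoch_idx)), "n_deterministic": int(len(model.det_idx)),
        "failed_replicates": batch.failed.nonzero()[0].tolist(),
    }
    return {"trajectories": df}, summary


def _run_direvo(cfg: RunConfig, record: RunRecord, key: RngKey):
    from ..nk import EvolveConfig, evolve, make_landscape

    p = cfg.params
    policy = parse_policy(p.policy)
    econf = EvolveConfig(P=p.pop, G=p.genes, mu=p.mu, policy=policy,
                         generations=p.generations,
                         steps_per_iteration=p.steps_per_iteration)
    record.log("evolve")
    rows = []
    finals = []
    for rep, rep_key in enumerate(split_key(key, p.replicates)):
        if p.fixed_landscape:
            land = make_landscape(p.N, p.K, p.A, seed=cfg.seed, adjacent=p.adjacent)
            ekey = rep_key
        else:
            land = make_landscape(p.N, p.K, p.A, seed=int(rep_key.child(0).word0 % 2**31),
                                  adjacent=p.adjacent)
            ekey = rep_key.child(1)
        trace = evolve(land, econf, ekey)
        finals.append(trace.best[-1])
        for g in range(len(trace.best)):
            rows.append({"policy": str(policy), "replicate": rep, "generation": g,
                         "best": trace.best[g], "mean": trace.mean[g], "min": trace.min[g]})
    df = pd.DataFrame(rows)
    finals = np.asarray(finals)
    summary = {
        "policy": str(policy), "replicates": p.replicates,
        "final_best_mean": float(finals.mean()),
        "final_best_se": float(finals.std(ddof=1) / np.sqrt(len(finals))) if len(finals) > 1 else 0.0,
    }
    return {"evolution": df}, summary


_RUNNERS = {
    "circuit-optimize": _run_circuit_optimize,
    "cell-sim": _run_cell_sim,
    "direvo": _run_direvo,
}


def run_config(cfg: RunConfig, *, force: bool = False) -> dict:
    """Execute one validated run configuration; returns the output manifest."""
    out_dir = Path(cfg.out_dir)
    _setup_logging(out_dir)
    record = RunRecord(config=cfg.echo(), root_seed=cfg.seed)
    key = RngKey.from_seed(cfg.seed)
    log.info("engine=%s seed=%d out=%s", cfg.engine, cfg.seed, out_dir)
    tables, summary = _RUNNERS[cfg.engine](cfg, record, key)
    summary = {"engine": cfg.engine, "root_seed": cfg.seed, **summary}
    record.log("write_results")
    manifest = write_results(record, tables, out_dir, summary, force=force)
    log.info("wrote %d files to %s", len(manifest["files"]), out_dir)
    return manifest
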