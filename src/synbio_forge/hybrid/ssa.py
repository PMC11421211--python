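"""Statistically exact Gillespie (direct-method) reference simulator.

Used as the independent oracle for validating tau-leaping on small models:
the stochastic partition is simulated event by event with the deterministic
levels frozen at their initial values.  Not intended for large models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..engine import RngKey
from .model import HybridModel, HybridState

__all__ = ["SSATrajectory", "ssa_exact", "time_average"]


@dataclass(frozen=True)
class SSATrajectory:
    """Piecewise-constant jump trajectory: counts[i] holds on [times[i], times[i+1])."""

    times: np.ndarray  # (M,) event times, times[0] = t0
    counts: np.ndarray  # (M, n_stoch)
    t_end: float
    species_names: tuple[str, ...]


def ssa_exact(
    model: HybridModel,
    x0: HybridState,
    t_end: float,
    key: RngKey,
    *,
    max_events: int | None = None,
) -> SSATrajectory:
    """Exact next-reaction sampling of the stochastic partition.

    Deterministic levels are frozen at ``x0.levels``.  When the total
    propensity reaches zero the state is absorbing and the trajectory halts
    at the current time (its last state extends to ``t_end``).
    """
    if model.n_reactions < 1:
        raise ValueError("model needs at least one reaction")
    rng = key.generator()
    full = x0.full(model)
    t = float(x0.t)
    horizon = t + t_end
    times = [t]
    counts = [full[model.stoch_idx].copy()]
    S = model.stoich_matrix
    n_events = 0
    while t < horizon:
        a = np.asarray(model.propensities(full), dtype=float)
        model.validate_propensities(a, t)
        total = a.sum()
        if total <= 0.0:
            break  # absorbing state
        t = t + rng.exponential(1.0 / total)
        if t >= horizon:
            break
        r = int(np.searchsorted(np.cumsum(a), rng.uniform(0.0, total), side="right"))
        r = min(r, len(a) - 1)
        full[model.stoch_idx] += S[r]
        times.append(t)
        counts.append(full[model.stoch_idx].copy())
        n_events += 1
        if max_events is not None and n_events >= max_events:
            break
    return SSATrajectory(
        times=np.asarray(times), counts=np.asarray(counts, dtype=float),
        t_end=min(t, horizon) if max_events and n_events >= (max_events or 0) else horizon,
        species_names=tuple(model.species_names[i] for i in model.stoch_idx),
    )


def time_average(traj: SSATrajectory, t_start: float | None = None) -> np.ndarray:
    """Time-weighted mean counts over [t_start, t_end] of a jump trajectory."""
    t0 = traj.times[0] if t_start is None else t_start
    edges = np.append(traj.times, traj.t_end)
    lo = np.maximum(edges[:-1], t0)
    hi = np.maximum(edges[1:], t0)
    w = hi - lo
    total = w.sum()
    if total <= 0:
        raise ValueError("empty averaging window")
    return (w[:, None] * traj.counts).sum(axis=0) / total
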