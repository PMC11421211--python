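"""Runtime-scaling harness: wall-clock time vs number of trajectories.

Re-runs the batched cell-model experiment for a sweep of batch sizes and
tabulates runtime on a log-log scale.  Timings are informational only — they
depend on the host — but the *shape* (sublinear scaling of the batched
implementation) is the point of the sweep.
"""

from __future__ import annotations

import time

import pandas as pd

from ..engine import RngKey
from .cell_model import bundled_cell_model, bundled_initial_state
from .simulate import simulate_batch

__all__ = ["scaling_sweep"]

import numpy as np


def scaling_sweep(
    key: RngKey,
    n_traj_values: tuple[int, ...] = (1, 3, 12, 48),
    t_end: float = 1.0,
    tau: float = 1e-4,
) -> pd.DataFrame:
    """Simulate ``t_end`` minutes of the bundled cell model for each batch
    size and return a table with wall-clock seconds and their log10s."""
    model = bundled_cell_model()
    x0 = bundled_initial_state()
    rows = []
    for n in n_traj_values:
        t0 = time.perf_counter()
        batch = simulate_batch(model, x0, t_end, tau, n, key, record_stride=10**9)
        seconds = time.perf_counter() - t0
        rows.append({
            "n_traj": n, "seconds": seconds,
            "log10_n_traj": np.log10(n), "log10_seconds": np.log10(seconds),
            "failed": int(batch.failed.sum()),
        })
    return pd.DataFrame(rows)
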