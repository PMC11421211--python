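"""Named three-node topologies and the plain-text topology file dialect.

File dialect (whitespace separated, ``#`` comments)::

    # n genes, then n rows of {-1,0,1}, then input/output gene indices
    3
    0 0 0
    1 0 0
    1 -1 0
    input 0
    output 2

Row i lists the regulators of gene i: entry (i, j) is the sign of gene j's
action on gene i.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["incoherent_feedforward", "activation_cascade", "single_gene",
           "load_topology", "save_topology"]


def incoherent_feedforward() -> tuple[np.ndarray, int, int]:
    """Input activates gene 0; gene 0 activates both the output (gene 2) and
    a repressor (gene 1) of the output — the canonical adaptation-capable
    type-1 incoherent feedforward loop.  Returns (topology, input, output)."""
    T = np.array([
        [0, 0, 0],
        [1, 0, 0],
        [1, -1, 0],
    ])
    return T, 0, 2


def activation_cascade() -> tuple[np.ndarray, int, int]:
    """Input → gene 0 → gene 1 → gene 2, all activating: a monotone cascade
    with no adaptation mechanism."""
    T = np.array([
        [0, 0, 0],
        [1, 0, 0],
        [0, 1, 0],
    ])
    return T, 0, 2


def single_gene() -> tuple[np.ndarray, int, int]:
    """One unregulated input-driven gene (the closed-form linear test model)."""
    return np.zeros((1, 1), dtype=np.int64), 0, 0


def load_topology(path: str | Path) -> tuple[np.ndarray, int, int]:
    tokens: list[list[str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            tokens.append(line.split())
    if not tokens:
        raise ValueError(f"empty topology file: {path}")
    n = int(tokens[0][0])
    if len(tokens) < n + 3:
        raise ValueError("topology file truncated")
    T = np.array([[int(v) for v in tokens[1 + i]] for i in range(n)])
    if T.shape != (n, n):
        raise ValueError("topology matrix has wrong shape")
    tail = {row[0]: int(row[1]) for row in tokens[1 + n:]}
    if set(tail) != {"input", "output"}:
        raise ValueError("topology file must end with 'input I' and 'output J' lines")
    return T, tail["input"], tail["output"]


def save_topology(path: str | Path, topology: np.ndarray, input_target: int,
                  output_index: int) -> None:
    T = np.asarray(topology, dtype=int)
    lines = [str(T.shape[0])]
    lines += [" ".join(str(v) for v in row) for row in T]
    lines += [f"input {input_target}", f"output {output_index}", ""]
    Path(path).write_text("\n".join(lines))
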