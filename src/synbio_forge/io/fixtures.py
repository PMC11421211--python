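"""Seeded fixture generation: small end-to-end exercisable inputs."""

from __future__ import annotations

from pathlib import Path

from ..circuit.topologies import incoherent_feedforward, save_topology

__all__ = ["make_fixtures"]

_TOY_CELL_MODEL = """\
# Toy 5-species expression model: mRNA/protein/complex are discrete,
# a resource pool and a signal are deterministic.
species:
  - {{name: M, kind: stochastic}}
  - {{name: P, kind: stochastic}}
  - {{name: C, kind: stochastic}}
  - {{name: R, kind: deterministic}}
  - {{name: S, kind: deterministic}}
params:
  k_tx: {k_tx}
  d_m: 0.5
  k_tl: 0.05
  d_p: 0.1
  k_bind: 0.002
  r_in: 0.05
  r_out: 0.1
reactions:
  - name: transcription
    stoich: {{M: 1}}
    rate: {{law: hill_activation, k: k_tx, K: 0.5, n: 2, species: R}}
  - name: mrna_decay
    stoich: {{M: -1}}
    rate: {{law: mass_action, k: d_m, reactants: {{M: 1}}}}
  - name: translation
    stoich: {{P: 1}}
    rate: {{law: mass_action, k: k_tl, reactants: {{M: 1}}}}
  - name: protein_decay
    stoich: {{P: -1}}
    rate: {{law: mass_action, k: d_p, reactants: {{P: 1}}}}
  - name: dimerization
    stoich: {{P: -2, C: 1}}
    rate: {{law: mass_action, k: k_bind, reactants: {{P: 2}}}}
drift:
  R:
    - {{law: constant, k: r_in}}
    - {{law: linear, k: -0.1, species: R}}
  S:
    - {{law: linear, k: -0.01, species: S}}
initial:
  M: 20
  P: 10
  R: 0.5
  S: 1.0
"""

_NK_SPEC = """\
# Small NK landscape spec, regenerable from (N, K, A, seed)
N: 8
K: 2
A: 2
seed: {seed}
adjacent: false
"""


def make_fixtures(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Write small seeded input files for one engine.

    ``circuit`` → a 3-node incoherent-feedforward topology file;
    ``cell`` → a 5-species toy hybrid model file (3 stochastic + 2
    deterministic); ``nk`` → an (N=8, K=2) landscape spec.  Each fixture is
    exercisable end-to-end in well under a minute.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "circuit":
        path = out / "topology_iffl.txt"
        save_topology(path, *incoherent_feedforward())
        return [path]
    if kind == "cell":
        path = out / "toy_cell_model.yaml"
        # seed perturbs one rate so distinct fixture sets are distinguishable
        path.write_text(_TOY_CELL_MODEL.format(k_tx=10.0 + (seed % 5)))
        return [path]
    if kind == "nk":
        path = out / "nk_landscape.yaml"
        path.write_text(_NK_SPEC.format(seed=seed))
        return [path]
    raise ValueError(f"unknown fixture kind {kind!r} (expected circuit, cell, or nk)")
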