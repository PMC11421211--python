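# synbio-forge

Batched, seed-reproducible simulators for three recurring model-based
design tasks in synthetic biology:

1. **Gene-circuit optimization** (`synbio_forge.circuit`) — simulate an
   N-gene regulatory network under a step input and tune its kinetic
   parameters by gradient descent until the output *adapts*: it responds
   transiently, then returns near its pre-step level.
2. **Hybrid stochastic cell simulation** (`synbio_forge.hybrid`) — fixed-step
   tau-leaping for discrete molecular species combined with Euler updates
   for fast/high-copy variables, with a bundled resource-aware cell model
   (11 stochastic + 6 deterministic variables) in which synthetic circuit
   genes compete with host genes for ribosomes, energy and charged tRNA.
3. **Directed evolution on NK landscapes** (`synbio_forge.nk`) — populations
   of multi-gene cells evolving under configurable mutation and selection
   policies on tunably rugged fitness landscapes, with brute-force oracles
   for small instances.

The engines share two execution contracts: *splittable random keys* (every
replicate's stream is a deterministic function of the root seed and its
index, so batched execution is bitwise identical to a loop of scalar runs)
and *fixed-format output* (fixed-seed reruns write byte-identical tables).

## The models in brief

**Circuits.** With topology T ∈ {−1,0,+1}^{N×N} (repression/absence/
activation of gene i by gene j),

    dx_i/dt = β_i · u^[i=input] · Π_j hill(x_j; K_ij, n_ij, T_ij) − γ_i x_i,

integrated by fixed-step RK4. A step u1→u2 is scored by sensitivity
S = (|O_peak−O1|/O1)/(|Δu|/u1) and precision error
P = (|O2−O1|/O1)/(|Δu|/u1); the smooth loss P² + softplus(0.5 − S) is
minimized with Adam using gradients obtained by exact forward-mode
sensitivity propagation through the discrete solver (verified against
central finite differences to <1e-3 relative).

**Hybrid stepping.** Per step of size τ each reaction r fires
Poisson(a_r·τ) times (counts clamped at 0) while deterministic levels take
one Euler step; both use the step-start state. Statistical correctness is
anchored on the linear birth–death process (stationary Poisson(k/γ)) and
an exact Gillespie reference implementation.

**NK landscapes.** Site i of a length-N gene contributes a fitness
component f_i(s_i, s_{neighbors(i)}) drawn i.i.d. Uniform(0,1); gene
fitness is the mean component. K = 0 is separable and single-peaked;
K = N−1 approaches the house-of-cards limit with 2^N/(N+1) expected local
optima (binary alphabet) — both verified by exhaustive enumeration.

## Worked example

Optimize one randomly initialized incoherent feedforward loop (input
activates gene 0; gene 0 activates the reporter gene 2 and its repressor
gene 1) for adaptation to a 50% input step:

```python
import numpy as np
from synbio_forge import RngKey
from synbio_forge.circuit import (StepInput, incoherent_feedforward, optimize_circuit,
                                  random_circuit, simulate_circuit, adaptation_metrics)

key = RngKey.from_seed(0)
topology, input_gene, output_gene = incoherent_feedforward()
inp = StepInput(u1=1.0, u2=1.5, t_step=50.0, t_end=100.0)

circuit = random_circuit(topology, input_gene, output_gene, key)
before = adaptation_metrics(simulate_circuit(circuit, inp), inp, output_gene)
result = optimize_circuit(circuit, inp, steps=500, lr=0.05)
after = result.final_metrics

print(f"loss        {before.loss:8.4f} -> {result.history[np.isfinite(result.history)].min():8.4f}")
print(f"sensitivity {before.sensitivity:8.4f} -> {after.sensitivity:8.4f}")
print(f"precision   {before.precision_error:8.4f} -> {after.precision_error:8.4f}")
```

prints

```
loss          0.9267 ->   0.0111
sensitivity   0.4642 ->   5.2163
precision     0.4642 ->   0.0813
```

i.e. the optimized circuit's output overshoots by ~5× the relative input
change (a strong transient response) but settles within ~8% of its
pre-step level (near-perfect adaptation), where the initial circuit simply
tracked the input. Across 20 random starts, typically a majority (9–14,
depending on the root seed) reach precision error < 0.1 with sensitivity
> 0.5 within the same 500-step budget.

## Command line

```bash
synbio-forge circuit-optimize --topology iffl --n-circuits 8 --steps 500 --seed 1 --out runs/opt
synbio-forge cell-sim --model bundled --t-end 1.0 --tau 1e-4 --n-traj 48 --seed 1 --out runs/cells
synbio-forge direvo --pop 100 --mu 0.5 --policy truncation:0.1 --generations 50 \
    --replicates 20 --seed 1 --out runs/evo
synbio-forge make-fixtures --out fixtures   # small seeded example inputs
synbio-forge scaling-harness --out scaling  # runtime-vs-batch-size sweep (informational)
```

Every subcommand accepts `--config FILE` (YAML, schema-checked, unknown
keys rejected) with flags taking precedence, records the root seed in its
run record, and writes a manifest of content hashes; rerunning with the
same seed reproduces every table byte-for-byte.

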