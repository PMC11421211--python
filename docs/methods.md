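# Methods

This note records the models implemented by synbio-forge, the assumptions
and defaults behind them, the numerical choices that matter, and what the
test suite does and does not establish.

## Reproducible randomness

All stochastic operations take an explicit splittable key; there is no
global RNG state. A key is 128 bits of material plus the seed path that
produced it. Child keys are derived counter-style — child *i* of a parent is
a fixed hash (splitmix64 mixing) of the parent words and *i* — so child *i*
is the same regardless of how many siblings are requested. Draws come from
numpy's counter-based Philox generator keyed on the key value. Consequences
used throughout:

- replicate *i* of a batch is bitwise identical to running replicate *i*
  alone (batch-equals-loop), and to replicate *i* of any larger batch
  (prefix stability);
- a run is fully determined by (configuration, root seed), so fixed-seed
  CLI reruns produce byte-identical result tables (all CSV floats are
  written with one fixed `%.12g` format).

The hot simulation loop re-keys a single Philox bit generator in place
rather than constructing a fresh generator per step; this is draw-for-draw
identical to fresh construction and about an order of magnitude faster.

## Gene-circuit optimization

**Model.** An N-gene circuit with signed topology T (T[i,j] ∈ {−1,0,+1}) has

    dx_i/dt = β_i · u^[i = input target] · Π_j hill(x_j; K_ij, n_ij, T_ij) − γ_i x_i

with activation `x^n/(K^n+x^n)` and repression `K^n/(K^n+x^n)` combined
multiplicatively, and a scalar input u entering as a multiplicative factor
on the input gene's production. Units are arbitrary concentration/time.
The perturbation is a step u1 → u2 at t_step.

**Metrics.** With O1 the pre-step output steady state, O_peak the largest
post-step deviation (earliest tie wins) and O2 the output at the horizon:

    sensitivity     = (|O_peak − O1|/O1) / (|u2 − u1|/u1)
    precision_error = (|O2 − O1|/O1) / (|u2 − u1|/u1)

The pre-step steady state is checked (relative output drift < 1e-4 over the
last 10% of the pre-step window); inside optimization a failing circuit
scores a flat penalty loss of 1e3 instead of raising, so one bad batch
member cannot abort the rest. The training loss is

    loss = precision_error² + w · softplus(s_min − sensitivity)

with defaults w = 1, s_min = 0.5: smooth everywhere, driving the
steady-state shift to zero while requiring a minimum transient response.

**Solver.** Fixed-step classical RK4 (default dt = 0.01, t_step = 50,
t_end = 100) on a grid that contains t_step exactly; the input is constant
within each step so no stage straddles the discontinuity. A fixed-step
scheme was chosen deliberately: gradients are then exact derivatives of the
discrete map rather than approximations contaminated by step-size control.
Measured convergence order on the closed-form linear gene is ≈ 4. States
are clamped at zero inside Hill terms so solver undershoot (bounded by
~1e-9 at the default dt) cannot produce NaNs.

**Gradients.** Forward-mode sensitivity propagation: the tangent matrix
S = ∂x/∂θ is advanced through every RK4 stage with analytic Jacobians of
the right-hand side. Parameters are optimized unconstrained: log β, log γ,
log K (positivity) and a logistic squash of the Hill coefficient onto
(1, 8) (bounding the exponent keeps x^n well-conditioned). The resulting
gradient matches central finite differences of the full simulate → metrics
→ loss pipeline to better than 1e-3 relative (typically 1e-6) wherever the
loss is differentiable; the peak-location argmax makes the loss piecewise
smooth, and finite-difference comparisons skip stencils that straddle a
peak relocation.

**Optimizer.** Adam (β1 = 0.9, β2 = 0.999, ε = 1e-8), default lr = 0.05,
500 steps, tracking the best parameters seen; a non-finite loss aborts that
circuit with a failure flag.

**Initialization (a genuinely open design point).** Random circuits draw
β ∈ [0.5, 5], γ ∈ [0.3, 3], activation Hill coefficients in [1.5, 3] and
repression in [2, 5] (all log-uniform), and each edge's K is placed at its
regulator's *operating point*: first at the unregulated scale β/γ, then
refined twice against a short pre-step simulation, with ×[0.7, 1.4] jitter.
Rationale: a monotone step response has O_peak = O2 exactly, which makes
the sensitivity and precision gradients collinear; gradient flow then
stalls on a flat manifold where 2·pe = σ(s_min − pe) regardless of
topology. Escaping requires the initial response to carry a transient
(interior) peak, which in the incoherent feedforward loop happens when the
repression path's DC gain rivals the direct path's. Half-saturated,
steeper-than-activation repression edges put most random draws in that
responsive regime; with this initialization roughly 45–70% of random IFFL
starts (9–14 of 20 across root seeds, a majority for most seeds) reach
precision_error < 0.1 with sensitivity > 0.5 within 500 Adam steps, while
the same budget on an activation
cascade — which has no mechanism for a transient peak — does not produce
adapting circuits. We read "does not adapt" as failing the joint criterion
(low precision error *with* appreciable sensitivity); a saturated cascade
can trivially flatten its response, but that is loss of responsiveness,
not adaptation.

## Hybrid tau-leaping / Euler simulation

**Scheme.** Species are partitioned into stochastic (integer counts) and
deterministic (continuous levels) sets; reactions touch only stochastic
species, while propensities and the deterministic drift may read the full
state. One step of size τ fires each reaction Poisson(a_r·τ) times and
advances the deterministic levels by one forward-Euler increment, both
evaluated at the step-start state (explicit first-order splitting, no
midpoint correction). Counts are clamped at zero after each leap — the
simplest standard safeguard; on toy models its bias is < 1% at the default
τ and grows monotonically with τ (tested). Reaction order within a step is
fixed by model definition order; each step consumes one child key.

**Validation.** The linear birth–death process (stationary law
Poisson(k/γ)) anchors the statistics: tau-leap stationary means match the
analytic value within 4 SE and agree with an exact Gillespie (direct
method) reference within 2% in the regime τ·a_max < 0.01, where a_max is
the largest single-reaction propensity encountered. Degenerate partitions
reduce exactly to forward Euler (no stochastic species) and to pure
tau-leaping (no deterministic species).

**Bundled cell model.** A coarse-grained resource-aware host cell with 11
stochastic species (mRNA and protein of metabolic, ribosomal, housekeeping
and two synthetic circuit genes, plus uncharged tRNA) and 6 deterministic
variables (charged tRNA, energy, internal nutrient, the growth-rate
variable, external nutrient density, intracellular antibiotic) — the
deterministic set being the fast or high-copy pools whose fluctuations
average out. Rate laws are schematic: energy-activated transcription,
translation proportional to ribosome count times each gene's share of the
mRNA pool (m_g/(K_R + Σm), the resource-competition term) gated by energy,
charged-tRNA and antibiotic Hill factors; Michaelis–Menten tRNA charging;
mass-action antibiotic binding of ribosomes; dilution of proteins at the
growth rate, which itself relaxes toward a saturating function of total
translational flux (the growth-law feedback that stabilizes the model).
Units: molecule counts and minutes; default τ = 1e-4 min. Parameters
(`DEFAULT_PARAMS`) were chosen for count scales of 10–10³ molecules and a
growth rate near 0.02/min, and the bundled initial state is a relaxed
long-run state so short demonstration runs start near quasi-steady
conditions. The model reproduces the qualitative resource-competition
signature — doubling a circuit gene's transcription rate lowers
time-averaged ribosomal protein — and responds to external nutrient and
antibiotic levels. It is a structural stand-in: its parameter values are
not fitted to any organism, so quantitative outputs (counts, growth rates)
should be read as internally consistent, not as E. coli predictions.

**Runtime harness.** `synbio-forge scaling-harness` repeats the
1-simulated-minute batch for n_traj ∈ {1, 3, 12, 48} and writes a log-log
table of wall-clock times. Timings are host-dependent and carry no
acceptance value; the sweep exists to expose the scaling shape of the
batched implementation.

## NK-landscape directed evolution

**Landscape.** N sites per gene, alphabet size A (default 2), each site's
fitness component depending on its own symbol and K neighbors (drawn
uniformly without replacement; an adjacent-neighborhood mode is a flag),
with i.i.d. Uniform(0,1) tables of size A^(K+1) indexed base-A with the
own site first. Everything regenerates from (N, K, A, seed). Gene fitness
is the mean component; cell fitness the mean over the cell's G genes
(symmetric, replaceable policy point). K = 0 is separable — its optimum is
the sitewise max and its only local optimum — while K = N−1 is the
house-of-cards limit with E[#local optima] = A^N/(N+1) for A = 2, both of
which the brute-force enumerators (A^N ≤ 2^20) verify.

**Evolution.** Populations of P cells evolve by mutate → evaluate →
select. Mutation hits each gene with probability μ, substituting one
uniformly chosen site with one of the A−1 other symbols (at most one site
per gene per round; a `steps_per_iteration` knob runs several mutation
steps per selection round, our reading of an iteration/step distinction
that the framing leaves open). Selection policies: truncation (keep top
⌈qP⌉, ties to the lower index, refill uniformly from survivors),
tournament (best of k uniform draws per slot; an exhaustive test mode
draws the whole population), and uniform resampling as the neutral
control, under which mean fitness is a martingale (tested as a no-trend
check). Policy comparison draws a fresh landscape seed and population seed
per replicate from split keys, so the landscape itself is part of the
averaged-over randomness; a fixed-landscape mode exists as a flag.

## Problem sizes used by the checks

The statistical checks run at sizes chosen to make their Monte-Carlo error
a small fraction of the tolerance being checked: ~1e4 sampled grid points
for the stationary-mean check; ~650 simulated minutes of tau-leaping at
τ = 1e-4 plus ~6000 minutes of SSA for the 2% cross-check (estimator SE
≈ 0.3% of the mean); 50 circuits for the gradient check; 20 optimization
starts; 50 evolution runs and 200 landscapes for the NK expectations.

## Known limitations

- The cell model's rate laws and parameters are schematic; only its
  structure (11/6 partition, resource coupling) and qualitative behavior
  are contracts.
- Tau-leaping uses fixed τ with no critical-reaction handling; models with
  propensities ≫ 1/τ need a smaller τ from the caller.
- Clamping counts at zero biases means slightly at coarse τ (quantified on
  toy models only).
- The adaptation loss is piecewise smooth in the peak location; optimizers
  other than the bundled Adam loop may want the documented kink handling.
- Circuit optimization success rates are reported for the 3-node IFFL
  under the default step input; other topologies/inputs inherit the
  machinery but not the measured rates.
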