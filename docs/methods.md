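# Methods

## Body model and assumptions

The moth is modelled as two rigid segments in the vertical plane — the
head-thorax (mass m₁, length L₁, centroidal inertia I₁) and the abdomen
(m₂, L₂, I₂) — pinned at a joint carrying a torsional spring (stiffness K,
rest angle β₀) and a torsional damper (coefficient C). Generalized
coordinates are the joint position (x, y) and the two segment angles
(θ, φ), both measured counterclockwise from the positive x axis; the
abdomen extends opposite the head-thorax direction, so φ = θ (with β₀ = 0)
is a straight body. The equations of motion are derived from the
Lagrangian:

- mass matrix M(q) couples translation and rotation through the off-joint
  centroids (terms m₁(L₁/2)·trig(θ), m₂(L₂/2)·trig(φ));
- centripetal terms ∝ θ̇², φ̇²;
- generalized forces: wing force of magnitude F in direction θ+α applied
  at a point r_F along the head-thorax axis (its moment about the joint is
  r_F·F·sin α, zero at the default r_F = 0); abdominal torque τ and the
  spring/damper torque, each acting equal-and-opposite on the two
  segments; gravity; and per-segment drag −c_d·v at each centroid
  (quadratic −c_d|v|v available via `drag_law: quadratic`).

Because τ and the joint torques are internal, they cannot change total
linear momentum; this, the system force law m·a_com = F_ext, energy
conservation in the conservative limit, and the ballistic closed form are
the oracles the test suite checks on randomized parameter sets — the
physics tests are deliberately independent of any particular parameter
values.

Assumptions inherited from the problem setting: planar motion, rigid
segments, stroke-averaged constant controls per 20 ms segment (half a
25 Hz wingbeat), no wing aerodynamics or unsteady wake effects, and no
within-stroke force variation.

### Default parameters

The tables that would pin down the reference body are not part of this
repository's inputs, so the shipped defaults are hawkmoth-scale stand-ins
chosen once for physical plausibility and kept fixed:

| parameter | value | rationale |
|---|---|---|
| m₁, m₂ | 1.1, 0.9 g | ~2 g adult, thorax-heavy split |
| L₁, L₂ | 2.0, 2.5 cm | ~4.5 cm body, rounded to 0.1 cm |
| I₁, I₂ | 4e-8, 5e-8 kg·m² | slender-body estimates m·L²/12 |
| K | 1e-3 N·m/rad | abdominal flexion resonance near 10 Hz |
| C | 1e-5 N·m·s/rad | damping ratio ≈ 0.4 at that resonance |
| c_d | 5e-3 N·s/m | drag ≈ 25% of body weight at 1 m/s |
| r_F | 0 | force at the joint → no direct moment |

Sampling ranges for initial conditions and controls are likewise stand-ins
describing near-hover strokes: speeds within ±0.5 m/s, body pitch in
[π/4, 3π/4], angular rates within ±10 rad/s, F ∈ [0, 0.04] N (up to about
twice body weight), α ∈ ±π/4, τ ∈ ±1e-3 N·m (the spring torque at one
radian of flexion). The config loader also accepts cm/g units
(`units: cgs`) with explicit conversion.

## Data generation

Each record is one stroke: initial state sampled uniformly (x = y = 0
always), controls sampled uniformly, integrated for 20 ms with adaptive
Runge–Kutta (RK45, rtol 1e-8, atol 1e-10, 1 ms reporting grid). For
throughput, many strokes are stacked into one ODE system and integrated
jointly; per-component error control keeps each trajectory at the
configured tolerance, and a chunk that fails falls back to per-sample
integration with deterministic replacement draws. Inputs are
(ẋᵢ, ẏᵢ, φᵢ, θᵢ, φ̇ᵢ, θ̇ᵢ, x_f, y_f, φ_f, θ_f); targets are
(F_x, F_y, τ, ẋ_f, ẏ_f, φ̇_f, θ̇_f) with (F_x, F_y) = F(cos α, sin α).
The *dataset* stores the forward map; the *network* learns its inverse.

Inputs and targets are min-max scaled to [−0.5, +0.5] using ranges fitted
on the training split only (the two sides are scaled separately because
they mix forces, angles and rates of disparate units); validation and test
data may fall outside the band. Constant features map to 0. The standard
split is 80:20 with a seeded shuffle; test sets come from an independent
seed with the same ranges.

What the generator does *not* emulate: sensory noise, parameter variation
across individuals, within-stroke unsteadiness, or any correlation
structure between successive strokes. Passing tests therefore demonstrate
properties of the learning/pruning machinery on this idealized plant, not
robustness of the controller on a real animal.

## Network and training

MLP with arctangent hidden activations and identity output (targets live
in [−0.5, 0.5], so no output squashing is needed); Glorot-uniform kernels,
zero biases. Loss is the mean of squared errors over all samples and all
7 outputs jointly. Default optimizer Adam (lr 1e-3) with batch size 128;
RMSprop with larger batches is available. Early stopping monitors the
validation loss when a validation split exists, else a training
subsample, every 100 batches, and stops when no improvement ≥ min-delta
occurs within a patience window of 1000 batches. The shipped default
min-delta is 1e-5: converged losses sit near 1e-3–1e-4 on the scaled
targets, where an absolute 0.01 delta would stop training almost
immediately; 0.01 remains selectable in config for full-scale runs where
that convention applies. "Until the loss is minimized" in the sequential
algorithms is operationalized as this early-stopping rule, capped by
`max_epochs`.

Biases are trainable but excluded from pruning and from weight counts;
the kernel-only convention reproduces all four published architecture
sizes exactly (330,512 / 83,656 / 21,856 / 5,956).

## Pruning

Remaining weights at sparsity s follow ⌊(1−s)·N⌋ (validated against the
published 23,135 at 93% of 330,512 and 2,084 at 65% of 5,956). Selection
ranks kernel magnitudes with already-masked entries counted as zero, so
masks are nested along an increasing schedule; ties break by stable
flattened order (layer, row, column) for determinism. The default scope is
**global** ranking across all kernels — per-layer uniformity is then an
emergent property, not a constraint — with `per_layer` available to mirror
constant-sparsity-per-layer toolkits. The default schedule is
15, 25, …, 85, then 90–98 in single steps, fine near the top where
breakdown discriminates.

Masked pruning keeps masked weights bit-exact zero through every batch
(masks multiply both the forward pass and the gradient; the optimizer
state for masked entries stays zero). Manual pruning re-zeroes the current
smallest weights each epoch and lets them regrow in between — retained as
the documented non-persistent baseline.

## Monte Carlo ensembles and analyses

All networks in an ensemble share data, architecture, hyper-parameters and
schedule; network k is initialized with seed base+k, and results are
independent of execution order. Recorded per network: pre-prune loss, loss
at every schedule sparsity (held-out test loss by default; training-
monitor loss when no test set is supplied, mirroring runs without
cross-validation), per-layer remaining counts and first-layer input
connectivity at every sparsity. Analyses: optimal sparsity (largest
schedule level with loss strictly under the threshold, possibly none),
its histogram plus box-plot statistics per level, layer sparsity tables
(mean/variance across networks), and per-input connection counts into the
first hidden layer.

Closed-loop evaluation (`rollout_error`) feeds a requested transition to
the network, converts (F_x, F_y) back to (F, α), simulates the stroke and
reports the Euclidean miss in (x, y, θ, φ). With the dataset's own
controls this loop closes at integrator tolerance (~1e-10), which isolates
network error from simulator error.

## Desk-scale study conditions

The repository's experiments run on one CPU, so the Monte Carlo study is
scaled down: 8 networks of the smallest studied architecture
(10-50-50-50-8-7, 5,956 weights) on 50,000 strokes with a 10,000-stroke
test set, pre-training capped at 25 epochs and each retraining phase at 6
(early stopping usually fires first). These sizes are the package's
default experimental conditions; `configs/full_scale.yaml` describes the
full 1320-network, 10-million-record study for cluster execution.

At this scale the qualitative phenomena are robust: pruning slightly
*improves* the loss at low sparsity, performance breaks down sharply near
the top of the schedule (median loss at 98% sparsity is two orders of
magnitude above the pre-prune median), and under a per-network threshold
of 1.25× its own pre-prune loss the modal optimal sparsity of the small
architecture sits at 65%. Two caveats are inherent to the reduced scale:
absolute losses (~1e-4) are smaller than full-scale ones because the
scaled-down networks are trained on narrower, cleaner conditions, and
layer-wise sparsity uniformity under global pruning emerges only in the
wide hidden layers — the small input/output layers retain
disproportionately many weights unless networks are trained to full-scale
convergence, so outer-layer structure (and input-pruning findings such as
a fully disconnected input) is reported but not asserted at desk scale.

## Numerical choices and degenerate inputs

- Integration: RK45 with rtol 1e-8 / atol 1e-10; halving tolerances moves
  final states by far less than the looser tolerance (tested).
- Scaler: constant features map to 0 on transform and to their minimum on
  inverse; exact round trip otherwise.
- remaining_count floor convention can make achieved sparsity slightly
  exceed the target (e.g. 93.02% for 5,956 weights); records store both.
- Empty rollout case lists yield empty statistics, not errors; failed
  integrations are flagged and excluded with counts everywhere.
- Training uses float64 throughout; determinism claims (same seed + data →
  identical parameters) hold within one precision setting and
  single-threaded execution.

## Known limitations

The plant is an idealized rigid-body proxy; drag is linear by default and
the force application point is a modelling choice (r_F configurable). The
stand-in body parameters and sampling ranges set the difficulty of the
inverse problem, so absolute losses and the precise breakdown level shift
with them — the invariants and the qualitative breakdown structure are the
stable results. Full-scale population statistics (1320 networks, 10M
records) are expressed as configuration, not recomputed here.
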