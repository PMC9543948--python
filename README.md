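# mothprune

Sparse neural inverse control of simulated hawkmoth hovering.

Hovering insects solve a hard control problem: their bodies are
underactuated, nonlinear, two-segment pendulums that must be steered with a
stroke-averaged wing force and an abdominal torque. `mothprune` is a
research tool for asking how *small* a neural controller for this task can
be. It

1. simulates a planar two-segment moth body (head-thorax and abdomen joined
   by a torsional spring and damper) under thrust-vectored control, in 20 ms
   constant-control strokes;
2. generates inverse-problem datasets from those simulations — given the
   initial state and the achieved final state, the targets are the controls
   that produced the transition;
3. trains feed-forward networks (arctangent hidden activations) on the
   inverse map; and
4. **sequentially prunes** the trained networks by weight magnitude, using
   binary masks applied in both the forward pass and the gradient update,
   retraining between pruning steps, to locate the *optimal sparsity*: the
   sparsest network whose loss stays under a performance threshold.
   Monte Carlo ensembles over random weight initializations quantify the
   population statistics of the breakdown.

## The model

**Body.** Generalized coordinates q = (x, y, θ, φ): joint position,
head-thorax angle, abdomen angle (counterclockwise from the +x axis). The
head-thorax centroid sits at the joint + (L₁/2)(cos θ, sin θ), the abdomen
centroid at the joint − (L₂/2)(cos φ, sin φ). The equations of motion

    M(q) q̈ + c(q, q̇) = Q(q, q̇, u)

follow from the Lagrangian, with the joint spring/damper torque
K((φ−θ)−β₀) + C(φ̇−θ̇) and the control torque τ acting equal-and-opposite
on the two segments, gravity and per-segment linear drag at the centroids,
and the wing force of magnitude F applied in direction θ+α. Controls
u = (F, α, τ) are held constant over each 20 ms stroke (half a 25 Hz
wingbeat) and the system is integrated with adaptive Runge–Kutta
(rtol 1e-8 / atol 1e-10).

**Network.** A multilayer perceptron ŷ = A_L σ(…σ(A₁x)…) with σ = arctan,
10 inputs (initial velocities/angles and the requested final pose), 7
outputs (F_x, F_y, τ and the achieved final derivatives), trained with Adam
on the uniformly weighted MSE over all outputs, after min-max scaling every
feature to [−0.5, +0.5] on the training split.

**Pruning.** At each sparsity s in an increasing schedule, the
n = N − ⌊(1−s)·N⌋ smallest-magnitude kernel weights (biases are never
pruned or counted) are masked to zero via binary matrices Mᵢ Hadamard-
multiplied with the weights; masks are bi-directional (forward pass and
gradient), so pruned weights stay bit-exact zero while the network
retrains. Masks built along the schedule are nested. A manual paradigm
(re-zeroing each epoch, allowing regrowth between zeroings) is also
provided for comparison.

## Worked example

```python
from mothprune import datagen, dynamics
from mothprune.model import InverseControlModel

ds = datagen.generate_dataset(20_000, datagen.SampleRanges(),
                              dynamics.BodyParams(), seed=7)
model = InverseControlModel.from_dataset(ds, widths=(10, 50, 50, 50, 8, 7))
res = model.fit(seed=0, max_epochs=10)
print(res.summary())
pruned = res.prune(sparsities=(0.5, 0.8, 0.93), max_epochs=3)
print(pruned.summary())
```

prints

```
Inverse flight-control network
==============================
architecture: 10-50-50-50-8-7 (arctan hidden, identity output)
kernel weights: 5956
seed: 0   optimizer: adam (lr=0.001, batch=128)
untrained loss: 8.272e-02
training loss:  1.666e-03
validation loss: 1.708e-03
```

and, after pruning,

```
sparsity: 93.02% (416 weights remaining)

step  target   achieved   loss        per-layer remaining
    50%    50.00%  1.570e-03  [294, 1196, 1206, 236, 46]
    80%    80.00%  2.991e-03  [173, 431, 415, 137, 35]
    93%    93.02%  1.260e-02  [83, 136, 118, 49, 30]
```

Training cuts the scaled MSE from 8.3e-2 (random weights) to 1.7e-3; at
50% sparsity the pruned network is as good as the dense one (1.6e-3), while
forcing 93% of this already-small architecture to zero degrades the loss
roughly tenfold — the breakdown the package exists to measure. Longer
training and more data sharpen all of these numbers.

The Monte Carlo layer does the same across many seeds:

```python
from mothprune.config import load_config
cfg = load_config("configs/default.yaml")          # 12 networks, desk scale
# configs/full_scale.yaml holds the 1320-network / 10M-record study
```

or from the shell:

```bash
mothprune simulate --controls 0.02,0,0 --out traj.csv
mothprune gen-data --config configs/default.yaml --out data.h5
mothprune train    --config configs/default.yaml --data data.h5 --out ckpt.npz
mothprune prune    --config configs/default.yaml --data data.h5 --checkpoint ckpt.npz
mothprune ensemble --config configs/default.yaml --n 12 --out results/
mothprune analyze  --results results/ --threshold 1e-3
mothprune rollout  --config configs/default.yaml --data data.h5 --checkpoint ckpt.npz
```

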