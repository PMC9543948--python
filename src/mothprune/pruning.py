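"""Sequential magnitude-based pruning with retraining.

Two paradigms:

* **Manual pruning** — at every epoch the ``n`` smallest-magnitude kernel
  weights are set to zero and an epoch of gradient steps follows; zeroed
  weights may regrow between zeroings, so the sparsity is only enforced at
  the zeroing instants.
* **Masked pruning** — a binary mask congruent to each kernel is built once
  per sparsity level (Hadamard product in the forward pass *and* the
  gradient update) and kept fixed while the network retrains, so pruned
  weights stay bit-exact zero throughout.

Magnitude selection ranks the kernel entries by |w| with already-masked
entries counted as magnitude zero, which makes masks nested along an
increasing sparsity schedule.  The remaining-weight convention is
``remaining = floor((1 - s) * N)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetParams, TrainConfig, TrainHistory, evaluate, forward, train

__all__ = [
    "MaskSet",
    "PruneSchedule",
    "PruneRecord",
    "remaining_count",
    "select_mask",
    "masked_forward",
    "achieved_sparsity",
    "manual_prune_run",
    "masked_prune_run",
    "DEFAULT_SCHEDULE",
]

# fine steps near the top because breakdown discriminates 93/94/95%
DEFAULT_SCHEDULE = (0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.80, 0.85,
                    0.90, 0.91, 0.92, 0.93, 0.94, 0.95, 0.96, 0.97, 0.98)


@dataclass
class MaskSet:
    """Binary matrices congruent to the kernel matrices (biases unmasked)."""

    matrices: list[np.ndarray]

    def __post_init__(self) -> None:
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        for m in self.matrices:
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("mask entries must be 0 or 1")

    @classmethod
    def ones_like(cls, params: NetParams) -> "MaskSet":
        return cls([np.ones_like(w) for w in params.weights])

    def copy(self) -> "MaskSet":
        return MaskSet([m.copy() for m in self.matrices])

    @property
    def total_entries(self) -> int:
        return int(sum(m.size for m in self.matrices))

    @property
    def ones_count(self) -> int:
        return int(sum(m.sum() for m in self.matrices))

    def per_layer_remaining(self) -> list[int]:
        return [int(m.sum()) for m in self.matrices]


@dataclass(frozen=True)
class PruneSchedule:
    """Strictly increasing sparsity fractions in [0, 1)."""

    sparsities: tuple[float, ...] = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        s = tuple(float(v) for v in self.sparsities)
        object.__setattr__(self, "sparsities", s)
        if any(not 0 <= v < 1 for v in s):
            raise ValueError("sparsities must lie in [0, 1)")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("sparsities must be strictly increasing")

    def __iter__(self):
        return iter(self.sparsities)

    def __len__(self):
        return len(self.sparsities)


@dataclass
class PruneRecord:
    """Bookkeeping for one schedule step."""

    target_sparsity: float
    achieved_sparsity: float
    loss: float
    per_layer_remaining: list[int]
    retrain_batches: int


def remaining_count(N: int, s: float) -> int:
    """Weights remaining at sparsity ``s``: floor((1 - s) * N)."""
    if N < 0:
        raise ValueError("N must be non-negative")
    if not 0 <= s < 1:
        raise ValueError("sparsity must lie in [0, 1)")
    return int(np.floor((1.0 - s) * N))


def achieved_sparsity(masks: MaskSet) -> float:
    """1 - ones / total over all kernel entries."""
    return 1.0 - masks.ones_count / masks.total_entries


def select_mask(params: NetParams, s: float, scope: str = "global",
                current: MaskSet | None = None) -> MaskSet:
    """Mask zeroing the smallest-|w| kernel entries to reach sparsity ``s``.

    Entries already masked out in ``current`` count as magnitude zero and
    are therefore always re-selected, so masks built along an increasing
    schedule are nested.  Ties are broken by stable flattened order
    (layer index, row, column).
    """
    if scope not in ("global", "per_layer"):
        raise ValueError("scope must be 'global' or 'per_layer'")
    if current is not None and s < achieved_sparsity(current) - 1e-12:
        raise ValueError("requested sparsity below the current achieved sparsity")

    eff = [np.abs(w) for w in params.weights]
    if current is not None:
        eff = [e * m for e, m in zip(eff, current.matrices)]

    masks = [np.ones_like(w) for w in params.weights]
    if scope == "global":
        flat = np.concatenate([e.ravel() for e in eff])
        N = flat.size
        n_prune = N - remaining_count(N, s)
        order = np.argsort(flat, kind="stable")
        kill = order[:n_prune]
        flat_mask = np.ones(N)
        flat_mask[kill] = 0.0
        offset = 0
        for i, w in enumerate(params.weights):
            masks[i] = flat_mask[offset:offset + w.size].reshape(w.shape)
            offset += w.size
    else:
        for i, e in enumerate(eff):
            Ni = e.size
            n_prune = Ni - remaining_count(Ni, s)
            order = np.argsort(e.ravel(), kind="stable")
            flat_mask = np.ones(Ni)
            flat_mask[order[:n_prune]] = 0.0
            masks[i] = flat_mask.reshape(e.shape)
    return MaskSet(masks)


def masked_forward(params: NetParams, masks: MaskSet,
                   inputs: np.ndarray) -> np.ndarray:
    """Forward pass with kernels replaced by their Hadamard-masked versions."""
    if [m.shape for m in masks.matrices] != [w.shape for w in params.weights]:
        raise ValueError("mask shapes incongruent with kernel shapes")
    return forward(params, inputs, masks)


def _zero_smallest(params: NetParams, n_prune: int) -> None:
    """In place: zero the n_prune smallest-|w| kernel entries (global rank)."""
    flat = np.concatenate([np.abs(w).ravel() for w in params.weights])
    order = np.argsort(flat, kind="stable")
    kill = np.zeros(flat.size, dtype=bool)
    kill[order[:n_prune]] = True
    offset = 0
    for w in params.weights:
        sel = kill[offset:offset + w.size].reshape(w.shape)
        w[sel] = 0.0
        offset += w.size


def manual_prune_run(params: NetParams, train_inputs, train_targets,
                     schedule: PruneSchedule, config: TrainConfig,
                     val_inputs=None, val_targets=None,
                     ) -> tuple[NetParams, list[PruneRecord]]:
    """Sequential pruning by re-zeroing before every retraining epoch.

    For each sparsity: each epoch re-zeroes the current ``n`` smallest
    kernel weights globally, then takes one epoch of gradient steps; the
    cycle repeats until the early-stopping rule (on the post-zeroing loss)
    fires.  Zeroed weights may regrow within the epoch — this is the
    documented non-persistence of the manual paradigm.
    """
    from .network import _EarlyStopper, _Optimizer  # shared machinery

    X = np.asarray(train_inputs, float)
    Y = np.asarray(train_targets, float)
    if val_inputs is not None:
        mon_X, mon_Y = np.asarray(val_inputs, float), np.asarray(val_targets, float)
    else:
        k = min(X.shape[0], config.monitor_subsample)
        mon_X, mon_Y = X[:k], Y[:k]
    params = params.copy()
    N = sum(w.size for w in params.weights)
    rng = np.random.default_rng(config.seed)
    records: list[PruneRecord] = []
    batches_per_epoch = int(np.ceil(X.shape[0] / config.batch_size))

    from .network import gradients

    for s in schedule:
        n_prune = N - remaining_count(N, s)
        opt = _Optimizer(config, params)
        stopper = _EarlyStopper(config.min_delta, config.patience)
        batch = 0
        loss = np.inf
        for _epoch in range(config.max_epochs):
            _zero_smallest(params, n_prune)
            loss = evaluate(params, None, mon_X, mon_Y)
            if stopper.update(batch, loss):
                break
            order = rng.permutation(X.shape[0])
            for start in range(0, X.shape[0], config.batch_size):
                idx = order[start:start + config.batch_size]
                gW, gb = gradients(params, X[idx], Y[idx], None)
                opt.step(params, gW, gb)
                batch += 1
        # final zeroing so the returned params honour the sparsity
        _zero_smallest(params, n_prune)
        loss = evaluate(params, None, mon_X, mon_Y)
        per_layer = [int(np.count_nonzero(w)) for w in params.weights]
        records.append(PruneRecord(
            target_sparsity=s,
            achieved_sparsity=1.0 - sum(per_layer) / N,
            loss=loss, per_layer_remaining=per_layer, retrain_batches=batch))
    return params, records


def masked_prune_run(params: NetParams, train_inputs, train_targets,
                     schedule: PruneSchedule, config: TrainConfig,
                     scope: str = "global", val_inputs=None, val_targets=None,
                     batch_callback=None,
                     ) -> tuple[NetParams, MaskSet, list[PruneRecord]]:
    """Sequential pruning with persistent bi-directional binary masks.

    For each sparsity in order: build the (nested) mask from the current
    weights, then retrain the masked network until early stopping fires.
    Masked entries are bit-exact zero at every step after masking.
    """
    params = params.copy()
    masks = MaskSet.ones_like(params)
    records: list[PruneRecord] = []
    for s in schedule:
        masks = select_mask(params, s, scope=scope, current=masks)
        params, history = train(params, masks, train_inputs, train_targets,
                                val_inputs, val_targets, config,
                                batch_callback=batch_callback)
        records.append(PruneRecord(
            target_sparsity=s,
            achieved_sparsity=achieved_sparsity(masks),
            loss=history.final_loss,
            per_layer_remaining=masks.per_layer_remaining(),
            retrain_batches=history.batches[-1]))
    return params, masks, records
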