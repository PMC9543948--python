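"""High-level Model/Results API for the inverse-control problem.

Follows the familiar two-object pattern: :class:`InverseControlModel` is
built from data (a :class:`~mothprune.datagen.Dataset` or a DataFrame) and
holds the architecture and scalers; ``fit()`` trains the network and
returns an :class:`InverseControlResults` carrying the trained parameters,
loss history and diagnostics, with ``summary()``, ``predict()``,
``prune()`` and closed-loop evaluation hanging off the results object.

Example
-------
>>> from mothprune import datagen, dynamics
>>> from mothprune.model import InverseControlModel
>>> ds = datagen.generate_dataset(2000, datagen.SampleRanges(),
...                               dynamics.BodyParams(), seed=7)
>>> model = InverseControlModel.from_dataset(ds, widths=(10, 32, 32, 8, 7))
>>> res = model.fit(max_epochs=5)
>>> pruned = res.prune(sparsities=(0.5, 0.9))
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import datagen
from .datagen import Dataset, apply_scaler, fit_scaler, invert_scaler
from .network import (
    Architecture,
    NetParams,
    TrainConfig,
    TrainHistory,
    count_kernel_weights,
    evaluate,
    forward,
    init_params,
    train,
)
from .pruning import (
    MaskSet,
    PruneRecord,
    PruneSchedule,
    achieved_sparsity,
    masked_prune_run,
)

__all__ = ["InverseControlModel", "InverseControlResults", "PrunedResults"]


class InverseControlModel:
    """Inverse-dynamics network model built from simulated stroke data.

    Parameters
    ----------
    train_inputs, train_targets : arrays of unscaled records
    val_inputs, val_targets : optional held-out split (same units)
    widths : layer widths, input to output
    scale : fit min-max scalers on the training split and train on
        [-0.5, 0.5]-scaled data (the standard preparation)
    """

    def __init__(self, train_inputs, train_targets, val_inputs=None,
                 val_targets=None, widths=(10, 400, 400, 400, 16, 7),
                 scale: bool = True):
        self.arch = Architecture(widths=tuple(widths))
        X = np.asarray(train_inputs, dtype=float)
        Y = np.asarray(train_targets, dtype=float)
        if scale:
            self.input_scaler = fit_scaler(X)
            self.target_scaler = fit_scaler(Y)
            self.X = apply_scaler(X, self.input_scaler)
            self.Y = apply_scaler(Y, self.target_scaler)
            self.vX = (apply_scaler(np.asarray(val_inputs, float), self.input_scaler)
                       if val_inputs is not None else None)
            self.vY = (apply_scaler(np.asarray(val_targets, float), self.target_scaler)
                       if val_targets is not None else None)
        else:
            self.input_scaler = self.target_scaler = None
            self.X, self.Y = X, Y
            self.vX = np.asarray(val_inputs, float) if val_inputs is not None else None
            self.vY = np.asarray(val_targets, float) if val_targets is not None else None

    @classmethod
    def from_dataset(cls, dataset: Dataset, split: float | None = 0.8,
                     split_seed: int = 0, **kwargs) -> "InverseControlModel":
        """Build from a generated Dataset, with the standard 80:20 split."""
        if split is None:
            return cls(dataset.inputs, dataset.targets, **kwargs)
        tr, va = datagen.split_dataset(dataset, fraction=split, seed=split_seed)
        return cls(tr.inputs, tr.targets, va.inputs, va.targets, **kwargs)

    @classmethod
    def from_dataframe(cls, df, split: float | None = 0.8, split_seed: int = 0,
                       **kwargs) -> "InverseControlModel":
        """Build from a DataFrame with the canonical input/target columns."""
        ds = Dataset(df[list(datagen.INPUT_NAMES)].to_numpy(),
                     df[list(datagen.TARGET_NAMES)].to_numpy())
        return cls.from_dataset(ds, split=split, split_seed=split_seed, **kwargs)

    @property
    def n_weights(self) -> int:
        return count_kernel_weights(self.arch)

    def fit(self, seed: int = 0, config: TrainConfig | None = None,
            **config_overrides) -> "InverseControlResults":
        """Train from a fresh Glorot initialization; returns Results."""
        cfg = (config or TrainConfig(seed=seed)).replace(**config_overrides)
        params = init_params(self.arch, seed)
        untrained_loss = evaluate(params, None, self.X, self.Y)
        trained, history = train(params, None, self.X, self.Y,
                                 self.vX, self.vY, cfg)
        return InverseControlResults(model=self, params=trained, config=cfg,
                                     history=history, seed=seed,
                                     untrained_loss=untrained_loss)


@dataclass
class InverseControlResults:
    """Trained-network results: parameters, history, diagnostics."""

    model: InverseControlModel
    params: NetParams
    config: TrainConfig
    history: TrainHistory
    seed: int
    untrained_loss: float
    masks: MaskSet | None = None
    prune_records: list[PruneRecord] = field(default_factory=list)

    @property
    def train_loss(self) -> float:
        return evaluate(self.params, self.masks, self.model.X, self.model.Y)

    @property
    def val_loss(self) -> float | None:
        if self.model.vX is None:
            return None
        return evaluate(self.params, self.masks, self.model.vX, self.model.vY)

    @property
    def sparsity(self) -> float:
        return 0.0 if self.masks is None else achieved_sparsity(self.masks)

    def predict(self, inputs, unscaled: bool = True) -> np.ndarray:
        """Predict targets; handles scaling when the model was scaled."""
        x = np.asarray(inputs, dtype=float)
        if unscaled and self.model.input_scaler is not None:
            x = apply_scaler(x, self.model.input_scaler)
        out = forward(self.params, x, self.masks)
        if unscaled and self.model.target_scaler is not None:
            out = invert_scaler(out, self.model.target_scaler)
        return out

    def prune(self, sparsities=None, schedule: PruneSchedule | None = None,
              scope: str = "global", config: TrainConfig | None = None,
              **config_overrides) -> "PrunedResults":
        """Sequential masked pruning with retraining; returns new Results."""
        sched = schedule or PruneSchedule(tuple(sparsities))
        cfg = (config or self.config).replace(**config_overrides)
        params, masks, records = masked_prune_run(
            self.params, self.model.X, self.model.Y, sched, cfg, scope=scope,
            val_inputs=self.model.vX, val_targets=self.model.vY)
        return PrunedResults(model=self.model, params=params, config=cfg,
                             history=self.history, seed=self.seed,
                             untrained_loss=self.untrained_loss, masks=masks,
                             prune_records=records)

    def residuals(self, test_inputs, test_targets):
        """Per-output residual table (actual - prediction), unscaled units."""
        from .ensemble import residual_summary

        X = apply_scaler(np.asarray(test_inputs, float), self.model.input_scaler)
        Y = apply_scaler(np.asarray(test_targets, float), self.model.target_scaler)
        return residual_summary(self.params, self.masks, X, Y,
                                self.model.target_scaler)

    def rollout(self, body_params, cases, **kwargs):
        """Closed-loop stroke evaluation; see :func:`mothprune.ensemble.rollout_error`."""
        from .ensemble import rollout_error

        return rollout_error(self.params, self.masks, self.model.input_scaler,
                             self.model.target_scaler, body_params, cases,
                             **kwargs)

    def summary(self) -> str:
        arch = self.params.arch
        lines = [
            "Inverse flight-control network",
            "==============================",
            f"architecture: {'-'.join(map(str, arch.widths))} "
            f"(arctan hidden, identity output)",
            f"kernel weights: {count_kernel_weights(arch)}",
            f"seed: {self.seed}   optimizer: {self.config.optimizer} "
            f"(lr={self.config.learning_rate:g}, batch={self.config.batch_size})",
            f"untrained loss: {self.untrained_loss:.3e}",
            f"training loss:  {self.train_loss:.3e}",
        ]
        if self.val_loss is not None:
            lines.append(f"validation loss: {self.val_loss:.3e}")
        if self.masks is not None:
            lines.append(f"sparsity: {self.sparsity:.2%} "
                         f"({self.masks.ones_count} weights remaining)")
            lines.append("")
            lines.append("step  target   achieved   loss        per-layer remaining")
            for r in self.prune_records:
                lines.append(
                    f"  {r.target_sparsity:5.0%} {r.achieved_sparsity:9.2%}  "
                    f"{r.loss:.3e}  {r.per_layer_remaining}")
        return "\n".join(lines)


class PrunedResults(InverseControlResults):
    """Results of sequential masked pruning (masks always present)."""

    def layer_table(self):
        from .ensemble import layer_sparsity_table

        return layer_sparsity_table(self.masks)

    def input_connectivity(self) -> np.ndarray:
        from .ensemble import input_connectivity

        return input_connectivity(self.masks.matrices[0])
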