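"""Schema-validated run configuration.

A run is described by one YAML file with nested blocks — ``body``,
``solver``, ``ranges``, ``dataset``, ``architecture``, ``training``,
``pruning``, ``ensemble``, ``output`` — every field defaulted, unknown keys
rejected before any compute.  The validated config converts into the typed
objects the library modules consume.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .datagen import SampleRanges
from .dynamics import BodyParams, SolverOptions
from .ensemble import EnsembleConfig
from .network import Architecture, TrainConfig
from .pruning import DEFAULT_SCHEDULE, PruneSchedule

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BodyBlock(_Block):
    m1: float = 1.1e-3
    m2: float = 0.9e-3
    L1: float = 2.0e-2
    L2: float = 2.5e-2
    I1: float = 4.0e-8
    I2: float = 5.0e-8
    K: float = 1.0e-3
    C: float = 1.0e-5
    beta0: float = 0.0
    cd1: float = 5.0e-3
    cd2: float = 5.0e-3
    g: float = 9.81
    rF: float = 0.0
    drag_law: str = "linear"
    units: str = "si"  # "si" or "cgs" (cm / g input, converted on load)

    @field_validator("units")
    @classmethod
    def _units_ok(cls, v):
        if v not in ("si", "cgs"):
            raise ValueError("units must be 'si' or 'cgs'")
        return v

    def to_params(self) -> BodyParams:
        d = self.model_dump()
        units = d.pop("units")
        if units == "cgs":
            # cm -> m, g -> kg, g cm^2 -> kg m^2, dyn-based joint constants
            d["m1"] *= 1e-3
            d["m2"] *= 1e-3
            d["L1"] *= 1e-2
            d["L2"] *= 1e-2
            d["rF"] *= 1e-2
            d["I1"] *= 1e-7
            d["I2"] *= 1e-7
            d["K"] *= 1e-7
            d["C"] *= 1e-7
            d["cd1"] *= 1e-3
            d["cd2"] *= 1e-3
            d["g"] *= 1e-2
        return BodyParams(**d)


class SolverBlock(_Block):
    method: str = "RK45"
    rtol: float = 1e-8
    atol: float = 1e-10
    report_dt: float = 1e-3

    def to_options(self) -> SolverOptions:
        return SolverOptions(**self.model_dump())


class RangesBlock(_Block):
    xdot0: tuple[float, float] = (-0.5, 0.5)
    ydot0: tuple[float, float] = (-0.5, 0.5)
    theta0: tuple[float, float] = (float(np.pi / 4), float(3 * np.pi / 4))
    phi0: tuple[float, float] = (float(np.pi / 4), float(3 * np.pi / 4))
    thetadot0: tuple[float, float] = (-10.0, 10.0)
    phidot0: tuple[float, float] = (-10.0, 10.0)
    F: tuple[float, float] = (0.0, 0.04)
    alpha: tuple[float, float] = (float(-np.pi / 4), float(np.pi / 4))
    tau: tuple[float, float] = (-1.0e-3, 1.0e-3)

    def to_ranges(self) -> SampleRanges:
        return SampleRanges(**{k: tuple(v) for k, v in self.model_dump().items()})


class DatasetBlock(_Block):
    n_train: int = 50_000
    n_test: int = 10_000
    seed: int = 0
    test_seed: int = 10_000_019  # independent stream for the test set
    split_fraction: float = 0.8
    split_seed: int = 0
    duration: float = 0.02


class ArchitectureBlock(_Block):
    widths: list[int] = Field(default_factory=lambda: [10, 400, 400, 400, 16, 7])
    hidden_activation: str = "arctan"

    def to_arch(self) -> Architecture:
        return Architecture(widths=tuple(self.widths),
                            hidden_activation=self.hidden_activation)


class TrainingBlock(_Block):
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 50
    min_delta: float = 1e-5
    patience: int = 1000
    eval_every: int = 100
    seed: int = 0

    def to_config(self) -> TrainConfig:
        return TrainConfig(**self.model_dump())


class PruningBlock(_Block):
    sparsities: list[float] = Field(default_factory=lambda: list(DEFAULT_SCHEDULE))
    scope: str = "global"

    def to_schedule(self) -> PruneSchedule:
        return PruneSchedule(tuple(self.sparsities))


class EnsembleBlock(_Block):
    n_networks: int = 12
    base_seed: int = 0
    threshold: float = 1e-3


class OutputBlock(_Block):
    directory: str = "results"
    dataset_format: str = "hdf5"  # "hdf5" | "npz"


class RunConfig(_Block):
    body: BodyBlock = Field(default_factory=BodyBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    ranges: RangesBlock = Field(default_factory=RangesBlock)
    dataset: DatasetBlock = Field(default_factory=DatasetBlock)
    architecture: ArchitectureBlock = Field(default_factory=ArchitectureBlock)
    training: TrainingBlock = Field(default_factory=TrainingBlock)
    pruning: PruningBlock = Field(default_factory=PruningBlock)
    ensemble: EnsembleBlock = Field(default_factory=EnsembleBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)

    def ensemble_config(self) -> EnsembleConfig:
        return EnsembleConfig(
            n_networks=self.ensemble.n_networks,
            base_seed=self.ensemble.base_seed,
            arch=self.architecture.to_arch(),
            train_config=self.training.to_config(),
            schedule=self.pruning.to_schedule(),
            threshold=self.ensemble.threshold,
            scope=self.pruning.scope,
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full validated configuration."""
    payload = json.dumps(config.model_dump(), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
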