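"""Synthetic training data for the inverse problem of hovering flight.

Each record is one simulated 20 ms stroke: initial velocities/angles and the
achieved final pose form the 10 network inputs, and the controls that
produced the stroke (with the force converted to Cartesian components) plus
the achieved final derivatives form the 7 targets.  The network therefore
learns the *inverse* map — the dataset itself is generated by the forward
model.  All trajectories start at the origin, so initial (x, y) carry no
information and are excluded from the inputs.

Feature order is fixed package-wide::

    inputs  = (xdot_i, ydot_i, phi_i, theta_i, phidot_i, thetadot_i,
               x_f, y_f, phi_f, theta_f)
    targets = (F_x, F_y, tau, xdot_f, ydot_f, phidot_f, thetadot_f)
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .dynamics import (
    BodyParams,
    Controls,
    SolverOptions,
    State,
    simulate_batch_final,
)

__all__ = [
    "INPUT_NAMES",
    "TARGET_NAMES",
    "SampleRanges",
    "TrainingRecord",
    "Dataset",
    "ScalerParams",
    "sample_conditions",
    "controls_to_cartesian",
    "cartesian_to_controls",
    "generate_dataset",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "split_dataset",
]

logger = logging.getLogger(__name__)

INPUT_NAMES = (
    "xdot_i", "ydot_i", "phi_i", "theta_i", "phidot_i", "thetadot_i",
    "x_f", "y_f", "phi_f", "theta_f",
)
TARGET_NAMES = ("F_x", "F_y", "tau", "xdot_f", "ydot_f", "phidot_f", "thetadot_f")

_SAMPLED_VARS = ("xdot0", "ydot0", "theta0", "phi0", "thetadot0", "phidot0",
                 "F", "alpha", "tau")


@dataclass(frozen=True)
class SampleRanges:
    """Inclusive uniform-sampling bounds per variable, SI units.

    Defaults are hawkmoth-scale stand-ins for near-hover strokes: joint
    speeds within 0.5 m/s, body pitch around vertical, wing force up to
    about twice body weight, abdominal torque on the order of the spring
    torque at one radian of flexion.
    """

    xdot0: tuple[float, float] = (-0.5, 0.5)
    ydot0: tuple[float, float] = (-0.5, 0.5)
    theta0: tuple[float, float] = (np.pi / 4, 3 * np.pi / 4)
    phi0: tuple[float, float] = (np.pi / 4, 3 * np.pi / 4)
    thetadot0: tuple[float, float] = (-10.0, 10.0)
    phidot0: tuple[float, float] = (-10.0, 10.0)
    F: tuple[float, float] = (0.0, 0.04)
    alpha: tuple[float, float] = (-np.pi / 4, np.pi / 4)
    tau: tuple[float, float] = (-1.0e-3, 1.0e-3)

    def __post_init__(self) -> None:
        for name in _SAMPLED_VARS:
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"SampleRanges.{name}: need finite lower <= upper")
        if self.F[0] < 0:
            raise ValueError("SampleRanges.F lower bound must be >= 0")

    def as_dict(self) -> dict:
        return {k: list(getattr(self, k)) for k in _SAMPLED_VARS}


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature min/max fitted on the training split (inputs and targets)."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "minimum", np.asarray(self.minimum, dtype=float))
        object.__setattr__(self, "maximum", np.asarray(self.maximum, dtype=float))
        if self.minimum.shape != self.maximum.shape:
            raise ValueError("min/max shape mismatch")
        if np.any(self.maximum < self.minimum):
            raise ValueError("per-feature max must be >= min")

    @property
    def n_features(self) -> int:
        return self.minimum.size


@dataclass(frozen=True)
class TrainingRecord:
    """One stroke's paired vectors: 10 inputs, 7 targets.

    The initial position is implicitly the origin and excluded from the
    inputs; see the module docstring for the feature order.
    """

    inputs: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", np.asarray(self.inputs, float))
        object.__setattr__(self, "targets", np.asarray(self.targets, float))
        if self.inputs.shape != (10,) or self.targets.shape != (7,):
            raise ValueError("a record is 10 inputs and 7 targets")


@dataclass
class Dataset:
    """Paired input/target matrices with regeneration metadata."""

    inputs: np.ndarray   # (n, 10)
    targets: np.ndarray  # (n, 7)
    seed: int | None = None
    ranges: SampleRanges | None = None
    body_hash: str | None = None

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError("inputs and targets must have equal row counts")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def record(self, i: int) -> TrainingRecord:
        return TrainingRecord(self.inputs[i], self.targets[i])

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.inputs, columns=list(INPUT_NAMES))
        for j, name in enumerate(TARGET_NAMES):
            df[name] = self.targets[:, j]
        return df


def body_params_hash(params: BodyParams) -> str:
    payload = json.dumps(asdict(params), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def sample_conditions(n: int, ranges: SampleRanges, seed: int):
    """Draw ``n`` independent uniform (State, Controls) pairs, x = y = 0.

    Returns the raw arrays ``(states0, controls)`` with shapes (n, 8) and
    (n, 3); use :func:`conditions_as_objects` for typed views.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = {name: rng.uniform(*getattr(ranges, name), size=n)
             for name in _SAMPLED_VARS}
    zeros = np.zeros(n)
    states0 = np.column_stack([
        zeros, zeros, draws["theta0"], draws["phi0"],
        draws["xdot0"], draws["ydot0"], draws["thetadot0"], draws["phidot0"],
    ])
    controls = np.column_stack([draws["F"], draws["alpha"], draws["tau"]])
    return states0, controls


def conditions_as_objects(states0: np.ndarray, controls: np.ndarray):
    return [(State.from_array(s), Controls(*u)) for s, u in zip(states0, controls)]


def controls_to_cartesian(F, alpha):
    """(F, alpha) -> (F_x, F_y) = (F cos(alpha), F sin(alpha))."""
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("force magnitude must be non-negative")
    return F * np.cos(alpha), F * np.sin(alpha)


def cartesian_to_controls(Fx, Fy):
    """Inverse map: (F_x, F_y) -> (F, alpha)."""
    return np.hypot(Fx, Fy), np.arctan2(Fy, Fx)


def generate_dataset(n: int, ranges: SampleRanges, params: BodyParams,
                     seed: int, duration: float = 0.02,
                     options: SolverOptions | None = None,
                     chunk_size: int = 4096) -> Dataset:
    """Simulate ``n`` strokes and assemble the inverse-problem dataset.

    Strokes are integrated in chunks as one stacked ODE system for speed.
    A sample whose integration fails is dropped and replaced by a fresh
    draw (from a deterministic continuation of the seed stream) so the
    record count is preserved.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    states0, controls = sample_conditions(n, ranges, seed)

    finals = np.empty((n, 8))
    retry_seed = np.random.default_rng(seed).integers(0, 2**31 - 1)
    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        try:
            finals[sl] = simulate_batch_final(states0[sl], controls[sl], params,
                                              duration, options)
        except RuntimeError:
            # fall back to per-sample integration so one bad draw cannot
            # poison the whole chunk
            for i in range(sl.start, sl.stop):
                finals[i], states0[i], controls[i] = _simulate_with_retry(
                    states0[i], controls[i], ranges, params, duration,
                    options, retry_seed + i)

    Fx, Fy = controls_to_cartesian(controls[:, 0], controls[:, 1])
    # inputs: initial velocities/angles + achieved final pose
    inputs = np.column_stack([
        states0[:, 4], states0[:, 5],          # xdot_i, ydot_i
        states0[:, 3], states0[:, 2],          # phi_i, theta_i
        states0[:, 7], states0[:, 6],          # phidot_i, thetadot_i
        finals[:, 0], finals[:, 1],            # x_f, y_f
        finals[:, 3], finals[:, 2],            # phi_f, theta_f
    ])
    targets = np.column_stack([
        Fx, Fy, controls[:, 2],
        finals[:, 4], finals[:, 5],            # xdot_f, ydot_f
        finals[:, 7], finals[:, 6],            # phidot_f, thetadot_f
    ])
    return Dataset(inputs=inputs, targets=targets, seed=seed, ranges=ranges,
                   body_hash=body_params_hash(params))


def _simulate_with_retry(state0, control, ranges, params, duration, options,
                         seed, max_tries: int = 8):
    from .dynamics import simulate_segment

    s, u = state0, control
    for attempt in range(max_tries):
        try:
            traj = simulate_segment(State.from_array(s), Controls(*u), params,
                                    duration, options)
            return traj.states[-1], s, u
        except RuntimeError:
            logger.warning("integration failed for a sample; redrawing")
            s2, u2 = sample_conditions(1, ranges, int(seed) + attempt + 1)
            s, u = s2[0], u2[0]
    raise RuntimeError("could not integrate a replacement sample")


def fit_scaler(values: np.ndarray) -> ScalerParams:
    """Per-feature min/max of the training split."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 records")
    return ScalerParams(minimum=values.min(axis=0), maximum=values.max(axis=0))


def apply_scaler(values: np.ndarray, scaler: ScalerParams) -> np.ndarray:
    """Min-max transform to [-0.5, +0.5] on the fitted range.

    Values outside the training range map outside the band, which is the
    intended behaviour for validation/test data.  Constant features
    (max == min) map to 0.0.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != scaler.n_features:
        raise ValueError("feature dimensionality mismatch")
    span = scaler.maximum - scaler.minimum
    safe = np.where(span > 0, span, 1.0)
    out = (values - scaler.minimum) / safe - 0.5
    return np.where(span > 0, out, 0.0)


def invert_scaler(scaled: np.ndarray, scaler: ScalerParams) -> np.ndarray:
    """Exact inverse of :func:`apply_scaler` (constant features return min)."""
    scaled = np.asarray(scaled, dtype=float)
    if scaled.shape[-1] != scaler.n_features:
        raise ValueError("feature dimensionality mismatch")
    span = scaler.maximum - scaler.minimum
    return np.where(span > 0, (scaled + 0.5) * span + scaler.minimum,
                    scaler.minimum)


def split_dataset(dataset: Dataset, fraction: float = 0.8,
                  seed: int = 0) -> tuple[Dataset, Dataset]:
    """Seeded random partition into (train, validation) of sizes
    ``floor(fraction * n)`` and the remainder."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(fraction * n))
    tr, va = perm[:n_train], perm[n_train:]
    mk = lambda idx: Dataset(dataset.inputs[idx], dataset.targets[idx],
                             seed=dataset.seed, ranges=dataset.ranges,
                             body_hash=dataset.body_hash)
    return mk(tr), mk(va)
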