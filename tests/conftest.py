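import numpy as np
import pytest

from mothprune import datagen, dynamics
from mothprune.datagen import SampleRanges, apply_scaler, fit_scaler
from mothprune.dynamics import BodyParams
from mothprune.model import InverseControlModel
from mothprune.network import Architecture, TrainConfig


@pytest.fixture(scope="session")
def body_params() -> BodyParams:
    return BodyParams()


@pytest.fixture(scope="session")
def ranges() -> SampleRanges:
    return SampleRanges()


@pytest.fixture(scope="session")
def small_dataset(ranges, body_params):
    """2000 simulated strokes shared across the unit tests."""
    return datagen.generate_dataset(2000, ranges, body_params, seed=42)


@pytest.fixture(scope="session")
def scaled_small(small_dataset):
    in_sc = fit_scaler(small_dataset.inputs)
    tg_sc = fit_scaler(small_dataset.targets)
    return {
        "X": apply_scaler(small_dataset.inputs, in_sc),
        "Y": apply_scaler(small_dataset.targets, tg_sc),
        "input_scaler": in_sc,
        "target_scaler": tg_sc,
        "dataset": small_dataset,
    }


@pytest.fixture(scope="session")
def tiny_trained(small_dataset):
    """A briefly trained small model on the shared dataset."""
    model = InverseControlModel.from_dataset(small_dataset,
                                             widths=(10, 24, 24, 8, 7))
    return model.fit(seed=0, max_epochs=8, patience=10_000)


def random_body_params(rng: np.random.Generator, **overrides) -> BodyParams:
    """Randomized but physically valid parameter sets for invariant tests."""
    base = dict(
        m1=rng.uniform(0.5e-3, 2e-3),
        m2=rng.uniform(0.5e-3, 2e-3),
        L1=rng.uniform(1e-2, 3e-2),
        L2=rng.uniform(1e-2, 3e-2),
        I1=rng.uniform(1e-8, 1e-7),
        I2=rng.uniform(1e-8, 1e-7),
        K=rng.uniform(0, 2e-3),
        C=rng.uniform(0, 2e-5),
        beta0=rng.uniform(-0.3, 0.3),
        cd1=rng.uniform(0, 1e-2),
        cd2=rng.uniform(0, 1e-2),
        g=9.81,
        rF=0.0,
    )
    base.update(overrides)
    if "rF" not in overrides:
        base["rF"] = rng.uniform(0, base["L1"])
    return BodyParams(**base)


def random_state(rng: np.random.Generator) -> dynamics.State:
    return dynamics.State(
        x=rng.uniform(-0.01, 0.01), y=rng.uniform(-0.01, 0.01),
        theta=rng.uniform(-np.pi, np.pi), phi=rng.uniform(-np.pi, np.pi),
        xdot=rng.uniform(-0.5, 0.5), ydot=rng.uniform(-0.5, 0.5),
        thetadot=rng.uniform(-10, 10), phidot=rng.uniform(-10, 10))


def random_controls(rng: np.random.Generator) -> dynamics.Controls:
    return dynamics.Controls(F=rng.uniform(0, 0.05),
                             alpha=rng.uniform(-np.pi, np.pi),
                             tau=rng.uniform(-2e-3, 2e-3))
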