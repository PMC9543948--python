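"""Dataset and checkpoint persistence: HDF5 (default) with NPZ fallback.

Datasets store named arrays ``inputs``/``targets`` plus regeneration
metadata as attributes; checkpoints store the architecture, kernels,
biases, masks, scaler parameters and a config hash with a format version,
so loading and re-saving is byte-stable and resuming against a different
configuration fails loudly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datagen import Dataset, SampleRanges, ScalerParams
from .network import Architecture, NetParams
from .pruning import MaskSet

__all__ = [
    "save_dataset",
    "load_dataset",
    "export_dataset_csv",
    "save_checkpoint",
    "load_checkpoint",
    "FORMAT_VERSION",
]

FORMAT_VERSION = 1


def _dataset_meta(dataset: Dataset) -> str:
    return json.dumps({
        "seed": dataset.seed,
        "ranges": dataset.ranges.as_dict() if dataset.ranges else None,
        "body_hash": dataset.body_hash,
        "version": FORMAT_VERSION,
    })


def _dataset_from_meta(inputs, targets, meta_json: str) -> Dataset:
    meta = json.loads(meta_json)
    if meta.get("version", 0) > FORMAT_VERSION:
        raise ValueError(
            f"dataset written by a newer format (v{meta['version']})")
    ranges = (SampleRanges(**{k: tuple(v) for k, v in meta["ranges"].items()})
              if meta.get("ranges") else None)
    return Dataset(inputs=inputs, targets=targets, seed=meta.get("seed"),
                   ranges=ranges, body_hash=meta.get("body_hash"))


def save_dataset(dataset: Dataset, path, fmt: str | None = None) -> None:
    """Write a dataset as HDF5 (.h5/.hdf5) or NPZ (.npz), inferred from suffix."""
    path = Path(path)
    fmt = fmt or ("npz" if path.suffix == ".npz" else "hdf5")
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("inputs", data=dataset.inputs)
            f.create_dataset("targets", data=dataset.targets)
            f.attrs["meta"] = _dataset_meta(dataset)
    elif fmt == "npz":
        np.savez(path, inputs=dataset.inputs, targets=dataset.targets,
                 meta=np.array(_dataset_meta(dataset)))
    else:
        raise ValueError(f"unknown dataset format {fmt!r}")


def load_dataset(path) -> Dataset:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return _dataset_from_meta(z["inputs"], z["targets"], str(z["meta"]))
    import h5py

    try:
        with h5py.File(path, "r") as f:
            return _dataset_from_meta(f["inputs"][...], f["targets"][...],
                                      f.attrs["meta"])
    except OSError as exc:
        raise ValueError(f"corrupt or unreadable dataset file {path}: {exc}")


def export_dataset_csv(dataset: Dataset, path) -> None:
    """CSV export with the canonical 10-input/7-output header names."""
    dataset.to_dataframe().to_csv(path, index=False)


def save_checkpoint(path, params: NetParams, masks: MaskSet | None = None,
                    input_scaler: ScalerParams | None = None,
                    target_scaler: ScalerParams | None = None,
                    history=None, config_hash: str | None = None) -> None:
    """Write a training checkpoint as NPZ with JSON metadata."""
    arrays: dict[str, np.ndarray] = {}
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        arrays[f"weight_{i}"] = w
        arrays[f"bias_{i}"] = b
    if masks is not None:
        for i, m in enumerate(masks.matrices):
            arrays[f"mask_{i}"] = m
    if input_scaler is not None:
        arrays["input_min"] = input_scaler.minimum
        arrays["input_max"] = input_scaler.maximum
    if target_scaler is not None:
        arrays["target_min"] = target_scaler.minimum
        arrays["target_max"] = target_scaler.maximum
    meta = {
        "version": FORMAT_VERSION,
        "widths": list(params.arch.widths),
        "hidden_activation": params.arch.hidden_activation,
        "n_layers": params.arch.n_layers,
        "has_masks": masks is not None,
        "config_hash": config_hash,
        "history": ({"batches": list(history.batches),
                     "losses": list(history.losses)} if history else None),
    }
    arrays["meta"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path, expect_config_hash: str | None = None):
    """Load a checkpoint; returns dict with params, masks, scalers, meta."""
    try:
        z = np.load(path, allow_pickle=False)
    except (OSError, ValueError) as exc:
        raise ValueError(f"corrupt or unreadable checkpoint {path}: {exc}")
    with z:
        meta = json.loads(str(z["meta"]))
        if meta.get("version", 0) > FORMAT_VERSION:
            raise ValueError(
                f"checkpoint written by a newer format (v{meta['version']})")
        if (expect_config_hash is not None and meta.get("config_hash")
                and meta["config_hash"] != expect_config_hash):
            raise ValueError(
                "checkpoint config hash mismatch: "
                f"{meta['config_hash']} != {expect_config_hash}")
        arch = Architecture(widths=tuple(meta["widths"]),
                            hidden_activation=meta["hidden_activation"])
        n = arch.n_layers
        params = NetParams([z[f"weight_{i}"] for i in range(n)],
                           [z[f"bias_{i}"] for i in range(n)], arch)
        masks = (MaskSet([z[f"mask_{i}"] for i in range(n)])
                 if meta["has_masks"] else None)
        in_sc = (ScalerParams(z["input_min"], z["input_max"])
                 if "input_min" in z else None)
        tg_sc = (ScalerParams(z["target_min"], z["target_max"])
                 if "target_min" in z else None)
    return {"params": params, "masks": masks, "input_scaler": in_sc,
            "target_scaler": tg_sc, "meta": meta}
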