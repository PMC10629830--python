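"""HDF5 containers for clip sets and model checkpoints."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .model import HierarchicalModel, StackSpec, StackWeights
from .video import Clip, ClipSet

__all__ = ["save_clipset", "load_clipset", "save_model", "load_model"]


def save_clipset(path, clipset: ClipSet):
    """One dataset of shape (n, y, x, t) plus a JSON manifest of metadata."""
    data = np.stack([c.data for c in clipset.clips])
    manifest = {
        "provenance": clipset.provenance,
        "meta": _jsonable(clipset.meta),
        "clips": [
            {
                "frame_rate": c.frame_rate,
                "normalized": bool(c.normalized),
                "meta": _jsonable(c.meta),
            }
            for c in clipset.clips
        ],
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("clips", data=data)
        f.attrs["manifest"] = json.dumps(manifest)


def load_clipset(path) -> ClipSet:
    with h5py.File(path, "r") as f:
        data = f["clips"][()]
        manifest = json.loads(f.attrs["manifest"])
    clips = [
        Clip(data=data[i], frame_rate=m["frame_rate"],
             normalized=m["normalized"], meta=m["meta"])
        for i, m in enumerate(manifest["clips"])
    ]
    return ClipSet(clips, provenance=manifest["provenance"],
                   meta=manifest["meta"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def save_model(path, model: HierarchicalModel, seed=None):
    """One group per stack: W, M, b, c, the spec, and the training log."""
    import numpy as _np

    with h5py.File(path, "w") as f:
        f.attrs["n_stacks"] = model.n_stacks
        f.attrs["objective"] = model.objective
        f.attrs["numpy_version"] = _np.__version__
        if seed is not None:
            f.attrs["seed"] = seed
        for z, (spec, wts) in enumerate(zip(model.specs, model.weights), 1):
            g = f.create_group(f"stack{z}")
            g.create_dataset("W", data=wts.w)
            g.create_dataset("b", data=wts.b)
            g.create_dataset("M", data=wts.m)
            g.create_dataset("c", data=wts.c)
            g.attrs["spec"] = json.dumps(
                {
                    "index": spec.index,
                    "input_shape": list(spec.input_shape),
                    "conv_units": spec.conv_units,
                    "kernel": list(spec.kernel),
                    "stride": list(spec.stride),
                    "learning_rate": spec.learning_rate,
                    "l1_strength": spec.l1_strength,
                }
            )
            if z - 1 < len(model.logs) and model.logs[z - 1]:
                log = model.logs[z - 1]
                if "train_loss" in log:
                    g.create_dataset("train_loss", data=np.asarray(log["train_loss"]))
                if log.get("val_mse"):
                    g.create_dataset("val_mse", data=np.asarray(log["val_mse"]))


def load_model(path) -> HierarchicalModel:
    specs, weights, logs = [], [], []
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_stacks"])
        objective = f.attrs.get("objective", "prediction")
        for z in range(1, n + 1):
            g = f[f"stack{z}"]
            d = json.loads(g.attrs["spec"])
            specs.append(
                StackSpec(
                    index=d["index"],
                    input_shape=tuple(d["input_shape"]),
                    conv_units=d["conv_units"],
                    kernel=tuple(d["kernel"]),
                    stride=tuple(d["stride"]),
                    learning_rate=d["learning_rate"],
                    l1_strength=d["l1_strength"],
                )
            )
            weights.append(
                StackWeights(w=g["W"][()], b=g["b"][()], m=g["M"][()], c=g["c"][()])
            )
            log = {}
            if "train_loss" in g:
                log["train_loss"] = g["train_loss"][()].tolist()
            if "val_mse" in g:
                log["val_mse"] = g["val_mse"][()].tolist()
            logs.append(log)
    return HierarchicalModel(specs=specs, weights=weights, logs=logs,
                             objective=str(objective))
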