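"""Versioned weight checkpoints.

A checkpoint is an ``.npz`` archive holding every named parameter tensor
plus a JSON header (``__meta__``) that records the format version, model
class, hyperparameter spec, parameter shapes, and any auxiliary arrays
(e.g. the normalization statistics the controller needs at inference time).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .model import CnnLstmMha, ModelSpec

FORMAT_VERSION = 1

__all__ = ["save_checkpoint", "load_checkpoint", "FORMAT_VERSION"]


def save_checkpoint(path, model, extras: dict[str, np.ndarray] | None = None,
                    meta: dict | None = None) -> None:
    """Write model parameters (and optional auxiliary arrays) to ``path``."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for name, tensor in model.params.items():
        arrays[f"param/{name}"] = tensor.data
    extras = extras or {}
    for name, arr in extras.items():
        arrays[f"extra/{name}"] = np.asarray(arr)
    header = {
        "format_version": FORMAT_VERSION,
        "model_class": type(model).__name__,
        "spec": model.spec.to_dict() if hasattr(model, "spec") else {},
        "param_shapes": {n: list(t.data.shape) for n, t in model.params.items()},
        "extra_names": sorted(extras),
        "meta": meta or {},
    }
    arrays["__meta__"] = np.frombuffer(
        json.dumps(header, sort_keys=True).encode("utf-8"), dtype=np.uint8
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[CnnLstmMha, dict[str, np.ndarray], dict]:
    """Rebuild a :class:`CnnLstmMha` from a checkpoint.

    Returns ``(model, extras, meta)``.
    """
    with np.load(Path(path)) as npz:
        header = json.loads(bytes(npz["__meta__"]).decode("utf-8"))
        if header["format_version"] > FORMAT_VERSION:
            raise ValueError(
                f"checkpoint format {header['format_version']} is newer than "
                f"supported version {FORMAT_VERSION}"
            )
        if header["model_class"] != "CnnLstmMha":
            raise ValueError(f"unsupported model class {header['model_class']!r}")
        model = CnnLstmMha(ModelSpec(**header["spec"]))
        for name, shape in header["param_shapes"].items():
            arr = npz[f"param/{name}"]
            if list(arr.shape) != shape:
                raise ValueError(f"shape mismatch for parameter {name}")
            model.params[name] = Tensor(arr, requires_grad=True)
        extras = {n: np.array(npz[f"extra/{n}"]) for n in header["extra_names"]}
    return model, extras, header["meta"]
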