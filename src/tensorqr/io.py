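"""Dataset / model / tensor serialization.

Datasets travel as HDF5 (datasets ``y``, ``X``, ``Z`` with ``dims`` and ``n``
attributes).  Fitted models are split into a JSON file for scalars and
metadata plus an HDF5 file for the core and factor matrices.  Small tensors
are also readable from delimited text: one mode-1 slice per block, blocks
separated by blank lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .estimator import Dataset, QRModel
from .tensor_core import TuckerFactorization

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_model",
    "load_model",
    "read_tensor_txt",
    "write_tensor_txt",
]


def save_dataset(path, dataset: Dataset, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("y", data=dataset.y)
        f.create_dataset("X", data=dataset.X)
        f.create_dataset("Z", data=dataset.Z)
        f.attrs["dims"] = np.asarray(dataset.dims)
        f.attrs["n"] = dataset.n
        if meta:
            f.attrs["meta"] = json.dumps(meta)


def load_dataset(path) -> Dataset:
    with h5py.File(path, "r") as f:
        y = f["y"][...]
        X = f["X"][...]
        Z = f["Z"][...]
        dims = tuple(int(d) for d in f.attrs["dims"])
    if tuple(Z.shape[1:]) != dims:
        raise ValueError(f"alignment error: declared dims {dims} vs stored {Z.shape[1:]}")
    return Dataset(y, X, Z)


def save_model(stem, model: QRModel, meta: dict | None = None) -> None:
    """Write ``<stem>.json`` (scalars/metadata) and ``<stem>.h5`` (components)."""
    stem = Path(stem)
    payload = {
        "alpha": model.alpha,
        "beta": model.beta.tolist(),
        "tau": model.tau,
        "rank": list(model.effect.rank),
        "dims": list(model.effect.dims),
        "meta": meta or {},
    }
    stem.with_suffix(".json").write_text(json.dumps(payload, indent=2))
    with h5py.File(stem.with_suffix(".h5"), "w") as f:
        f.create_dataset("core", data=model.effect.core)
        for j, g in enumerate(model.effect.factors):
            f.create_dataset(f"factor{j}", data=g)


def load_model(stem) -> QRModel:
    stem = Path(stem)
    payload = json.loads(stem.with_suffix(".json").read_text())
    with h5py.File(stem.with_suffix(".h5"), "r") as f:
        core = f["core"][...]
        factors = [f[f"factor{j}"][...] for j in range(core.ndim)]
    return QRModel(
        payload["alpha"],
        np.asarray(payload["beta"]),
        TuckerFactorization(core, factors),
        payload["tau"],
    )


def write_tensor_txt(path, a: np.ndarray) -> None:
    """Delimited-text tensor: one mode-1 slice per block, blank-line separated.

    Block ``m`` holds ``A[:, :, ..., flat index m]`` as a whitespace-delimited
    p1 × p2 matrix (remaining modes flattened mode-3-fastest); an order-2
    tensor is a single block.  A header line records the dims.
    """
    a = np.asarray(a, dtype=float)
    dims = a.shape
    mat = a.reshape(dims[0], dims[1] if a.ndim > 1 else 1, -1, order="F")
    lines = ["# dims: " + " ".join(str(d) for d in dims)]
    for m in range(mat.shape[2]):
        for row in mat[:, :, m]:
            lines.append(" ".join(format(v, ".17g") for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_tensor_txt(path) -> np.ndarray:
    text = Path(path).read_text().strip().splitlines()
    if not text or not text[0].startswith("# dims:"):
        raise ValueError("tensor text file must start with a '# dims:' header")
    dims = tuple(int(t) for t in text[0].split(":", 1)[1].split())
    blocks, cur = [], []
    for line in text[1:]:
        if line.strip() == "":
            if cur:
                blocks.append(np.array([[float(v) for v in r.split()] for r in cur]))
                cur = []
        else:
            cur.append(line)
    if cur:
        blocks.append(np.array([[float(v) for v in r.split()] for r in cur]))
    stacked = np.stack(blocks, axis=2) if blocks else np.zeros(dims)
    return stacked.reshape(dims, order="F")
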