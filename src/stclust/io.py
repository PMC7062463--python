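"""Containers and serialization.

Recordings (stimulus movie + per-cell spike counts) travel in a single
HDF5 file; fitted models are serialized as a directory bundle with a
JSON manifest and flat ``.npy`` arrays so every number round-trips at
full precision.

Container schema::

    /stimulus            T x rows x cols  (float, or int8 with a
                         ``scale`` attribute for binary noise)
    /spikes/<cell_id>    length-T integer counts
    attrs: bin_width_s, pixel_size_um, seed, contrast
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np

from .model import OutputNonlinearity, SpikeCounts, SubunitBank, SubunitModel
from .population import PopulationModel

__all__ = [
    "write_container",
    "read_container",
    "write_model",
    "read_model",
]

_REQUIRED_ATTRS = ("bin_width_s", "pixel_size_um", "seed", "contrast")
_BUNDLE_VERSION = 1


def write_container(path, stimulus: np.ndarray, spikes: dict, *,
                    bin_width_s: float, pixel_size_um: float = float("nan"),
                    seed: int = -1, contrast: float = float("nan"),
                    scale: float | None = None) -> None:
    """Write a recording container (T x rows x cols stimulus + spikes)."""
    stimulus = np.asarray(stimulus)
    if stimulus.ndim != 3:
        raise ValueError("stimulus must be T x rows x cols")
    with h5py.File(path, "w") as f:
        if scale is not None:
            quant = np.rint(stimulus / scale).astype(np.int8)
            ds = f.create_dataset("stimulus", data=quant)
            ds.attrs["scale"] = scale
        else:
            f.create_dataset("stimulus", data=stimulus.astype(np.float64))
        grp = f.create_group("spikes")
        for cell, y in spikes.items():
            y = np.asarray(y.counts if isinstance(y, SpikeCounts) else y)
            if y.shape[0] != stimulus.shape[0]:
                raise ValueError(f"spike vector for cell {cell!r} does not "
                                 f"match stimulus length")
            grp.create_dataset(str(cell), data=y.astype(np.int64))
        f.attrs["bin_width_s"] = bin_width_s
        f.attrs["pixel_size_um"] = pixel_size_um
        f.attrs["seed"] = seed
        f.attrs["contrast"] = contrast


def read_container(path):
    """Read and validate a recording container.

    Returns
    -------
    raw : T x D float stimulus frames (int8 storage is rescaled)
    grid_shape : (rows, cols)
    spikes : dict cell_id -> SpikeCounts
    meta : dict of file attributes
    """
    with h5py.File(path, "r") as f:
        if "stimulus" not in f:
            raise ValueError(f"{path}: missing dataset /stimulus")
        stim = f["stimulus"]
        data = stim[()]
        if "scale" in stim.attrs:
            data = data.astype(float) * float(stim.attrs["scale"])
        else:
            data = data.astype(float)
        T = data.shape[0]
        grid_shape = data.shape[1:]
        missing = [a for a in _REQUIRED_ATTRS if a not in f.attrs]
        if missing:
            raise ValueError(f"{path}: missing attributes {missing}")
        meta = {a: f.attrs[a] for a in f.attrs}
        if "spikes" not in f:
            raise ValueError(f"{path}: missing group /spikes")
        spikes = {}
        bw = float(meta["bin_width_s"])
        for cell in f["spikes"]:
            y = f["spikes"][cell][()]
            if y.shape[0] != T:
                raise ValueError(f"{path}: /spikes/{cell} has length "
                                 f"{y.shape[0]}, stimulus has {T} frames")
            spikes[cell] = SpikeCounts(y, bin_width=bw)
        extra = [k for k in f if k not in ("stimulus", "spikes")]
        if extra:
            warnings.warn(f"{path}: ignoring unknown datasets {extra}")
    return data.reshape(T, -1), tuple(grid_shape), spikes, meta


def write_model(bundle_dir, model) -> None:
    """Serialize a SubunitModel or PopulationModel as a directory bundle."""
    path = Path(bundle_dir)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"version": _BUNDLE_VERSION}
    if isinstance(model, PopulationModel):
        manifest.update(kind="population", n_subunits=model.n_subunits,
                        n_cells=model.n_cells, grid_shape=model.grid_shape,
                        nonlinearities=[[nl.a, nl.b]
                                        for nl in model.nonlinearities])
        np.save(path / "K.npy", model.K)
        np.save(path / "W.npy", model.W)
    elif isinstance(model, SubunitModel):
        manifest.update(kind="single", n_subunits=model.bank.n_subunits,
                        a=model.nonlinearity.a, b=model.nonlinearity.b,
                        grid_shape=model.grid_shape, bin_width=model.bin_width)
        np.save(path / "K.npy", model.bank.K)
        np.save(path / "w.npy", model.bank.w)
        if model.time_course is not None:
            np.save(path / "time_course.npy", model.time_course)
    else:
        raise TypeError("expected SubunitModel or PopulationModel")

    def plain(obj):
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        return obj

    manifest = {k: plain(v) for k, v in manifest.items()}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_model(bundle_dir):
    """Load a model bundle, checking version and array shapes."""
    path = Path(bundle_dir)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("version") != _BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {manifest.get('version')}")
    grid_shape = manifest.get("grid_shape")
    grid_shape = tuple(grid_shape) if grid_shape else None
    if manifest["kind"] == "population":
        K = np.load(path / "K.npy")
        W = np.load(path / "W.npy")
        if K.shape[0] != manifest["n_subunits"] or W.shape != (
                manifest["n_cells"], manifest["n_subunits"]):
            raise ValueError("bundle arrays disagree with manifest shapes")
        nls = [OutputNonlinearity(a, b)
               for a, b in manifest.get("nonlinearities", [])]
        return PopulationModel(K=K, W=W, nonlinearities=nls,
                               grid_shape=grid_shape)
    K = np.load(path / "K.npy")
    w = np.load(path / "w.npy")
    if K.shape[0] != manifest["n_subunits"] or w.shape[0] != K.shape[0]:
        raise ValueError("bundle arrays disagree with manifest shapes")
    tc_path = path / "time_course.npy"
    tc = np.load(tc_path) if tc_path.exists() else None
    return SubunitModel(bank=SubunitBank(K, w),
                        nonlinearity=OutputNonlinearity(manifest["a"],
                                                        manifest["b"]),
                        time_course=tc, grid_shape=grid_shape,
                        bin_width=manifest.get("bin_width", 1.0 / 120.0))
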