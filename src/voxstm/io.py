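"""File I/O: WAV audio, HDF5 feature/mask containers, CSV tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .filterbank import FilterbankSpec

__all__ = [
    "read_wav",
    "write_wav",
    "save_features",
    "load_features",
    "save_masks",
    "load_masks",
]


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a WAV file as float samples in [-1, 1] (stereo downmixed)."""
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit PCM is unsigned
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - info.max / 2) / (info.max / 2)
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return data, int(sr)


def write_wav(path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write mono 16-bit PCM."""
    w = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(sample_rate), (w * 32767.0).astype(np.int16))


def _spec_to_attrs(spec: FilterbankSpec) -> str:
    return json.dumps(asdict(spec))


def _spec_from_attrs(s: str) -> FilterbankSpec:
    d = json.loads(s)
    d["scales"] = tuple(d["scales"])
    d["rate_magnitudes"] = tuple(d["rate_magnitudes"])
    return FilterbankSpec(**d)


def save_features(path, features: np.ndarray, meta: pd.DataFrame, spec: FilterbankSpec) -> None:
    """Write per-frame STM features and aligned frame metadata to HDF5.

    Layout: dataset ``features`` (n_frames x n_features), axis vectors
    (``channel_centers``, ``scales``, ``rates``), one dataset per metadata
    column under ``meta/``, and the filterbank provenance as a JSON
    attribute.
    """
    if len(meta) != features.shape[0]:
        raise ValueError("metadata rows must match feature rows")
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=np.asarray(features, dtype=np.float32))
        f.create_dataset("channel_centers", data=spec.channel_centers)
        f.create_dataset("scales", data=np.asarray(spec.scales, dtype=float))
        f.create_dataset("rates", data=spec.signed_rates)
        g = f.create_group("meta")
        for col in meta.columns:
            vals = meta[col].to_numpy()
            if vals.dtype.kind in ("O", "U"):
                vals = vals.astype(h5py.string_dtype())
            g.create_dataset(col, data=vals)
        f.attrs["filterbank_spec"] = _spec_to_attrs(spec)


def load_features(path) -> tuple[np.ndarray, pd.DataFrame, FilterbankSpec]:
    with h5py.File(path, "r") as f:
        features = f["features"][()].astype(float)
        meta = {}
        for col in f["meta"]:
            v = f["meta"][col][()]
            if v.dtype.kind in ("S", "O"):
                v = np.array([x.decode() if isinstance(x, bytes) else x for x in v])
            meta[col] = v
        spec = _spec_from_attrs(f.attrs["filterbank_spec"])
    return features, pd.DataFrame(meta), spec


def save_masks(path, masks: dict, spec: FilterbankSpec, extra_attrs: dict | None = None) -> None:
    """Write interpretation masks to HDF5.

    `masks` maps a string key (e.g. ``"participant_003"``) to either a
    1-D mask vector or a 2-D (n_replicates x n_features) array of
    per-classifier replicate masks.
    """
    with h5py.File(path, "w") as f:
        for key, m in masks.items():
            f.create_dataset(str(key), data=np.asarray(m, dtype=np.float32))
        f.attrs["filterbank_spec"] = _spec_to_attrs(spec)
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v


def load_masks(path) -> tuple[dict, FilterbankSpec]:
    with h5py.File(path, "r") as f:
        masks = {k: f[k][()].astype(float) for k in f.keys()}
        spec = _spec_from_attrs(f.attrs["filterbank_spec"])
    return masks, spec


def hash_file(path, algo: str = "sha256") -> str:
    """Content digest of a file; HDF5 files are digested by dataset payload
    (and sorted attributes) rather than raw bytes, so that rewritten files
    with identical content compare equal."""
    import hashlib

    h = hashlib.new(algo)
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            def visit(name, obj):
                if isinstance(obj, h5py.Dataset):
                    h.update(name.encode())
                    data = obj[()]
                    arr = np.asarray(data)
                    if arr.dtype.kind == "O":  # variable-length strings
                        for item in arr.ravel():
                            h.update(item if isinstance(item, bytes) else str(item).encode())
                    else:
                        h.update(np.ascontiguousarray(arr).tobytes())
            f.visititems(visit)
            for k in sorted(f.attrs):
                h.update(str(k).encode())
                h.update(str(f.attrs[k]).encode())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()
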