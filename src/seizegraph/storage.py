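"""HDF5-backed stores for generated clips and feature tensors.

Each store is one ``.h5`` file plus a JSON sidecar (same path with
``.json``) holding the generating configuration and provenance, so every
artifact is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

__all__ = ["save_clip_store", "load_clip_store",
           "save_feature_store", "load_feature_store",
           "write_sidecar", "read_sidecar", "file_fingerprint"]


def file_fingerprint(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_sidecar(path, payload: dict) -> None:
    Path(str(path) + ".json").write_text(json.dumps(payload, indent=2,
                                                    sort_keys=True))


def read_sidecar(path) -> dict:
    return json.loads(Path(str(path) + ".json").read_text())


def save_clip_store(path, clips, meta: dict | None = None) -> None:
    """Raw clips + annotations in one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["n_clips"] = len(clips)
        f.attrs["sample_rate"] = clips[0].sample_rate
        f.attrs["channel_names"] = json.dumps(list(clips[0].channel_names))
        data = np.stack([c.samples for c in clips])
        f.create_dataset("samples", data=data)
        f.create_dataset("labels", data=np.array([c.label for c in clips]))
        iv = [json.dumps(c.seizure_intervals) for c in clips]
        f.create_dataset("intervals", data=np.array(iv, dtype=object),
                         dtype=h5py.string_dtype())
    write_sidecar(path, meta or {})


def load_clip_store(path):
    from .synthetic import SyntheticClip
    with h5py.File(path, "r") as f:
        names = tuple(json.loads(f.attrs["channel_names"]))
        rate = float(f.attrs["sample_rate"])
        samples = f["samples"][:]
        labels = f["labels"][:]
        intervals = [json.loads(s) for s in f["intervals"].asstr()[:]]
    return [SyntheticClip(samples=samples[i],
                          seizure_intervals=[tuple(t) for t in intervals[i]],
                          label=int(labels[i]), sample_rate=rate,
                          channel_names=names)
            for i in range(len(labels))]


def save_feature_store(path, X: np.ndarray, y: np.ndarray,
                       stats=None, meta: dict | None = None) -> None:
    """Feature tensors (clips, N, C, T), labels, optional train stats."""
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=X)
        f.create_dataset("y", data=y)
        if stats is not None:
            f.create_dataset("norm_mean", data=stats.mean)
            f.create_dataset("norm_sd", data=stats.sd)
            f.attrs["n_training_clips"] = stats.n_training_clips
    write_sidecar(path, meta or {})


def load_feature_store(path):
    from .preprocess import NormalizationStats
    with h5py.File(path, "r") as f:
        X = f["X"][:]
        y = f["y"][:]
        stats = None
        if "norm_mean" in f:
            stats = NormalizationStats(
                mean=f["norm_mean"][:], sd=f["norm_sd"][:],
                n_training_clips=int(f.attrs.get("n_training_clips", 0)))
    return X, y, stats
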