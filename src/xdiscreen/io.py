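"""HDF5 / TIFF / JSON persistence for patterns and map stacks."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .core import DensityMap, DiffractionPattern

__all__ = [
    "save_pattern",
    "load_pattern",
    "save_map_stack",
    "load_map_stack",
    "save_pattern_tiff",
    "load_pattern_tiff",
]


def save_pattern(path, p: DiffractionPattern, ground_truth: DensityMap | None = None) -> None:
    """Write a pattern to HDF5 (/counts, /valid, /q_step [um^-1])."""
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=p.counts)
        f.create_dataset("valid", data=p.valid)
        f.create_dataset("q_step", data=p.q_step)
        if ground_truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("values", data=ground_truth.values)
            g.create_dataset("pixel_size_nm", data=ground_truth.pixel_size)


def load_pattern(path):
    """Read a pattern (and ground truth, if present) from HDF5."""
    with h5py.File(path, "r") as f:
        p = DiffractionPattern(counts=f["counts"][()], valid=f["valid"][()],
                               q_step=float(f["q_step"][()]))
        truth = None
        if "ground_truth" in f:
            truth = DensityMap(values=f["ground_truth/values"][()],
                               pixel_size=float(f["ground_truth/pixel_size_nm"][()]))
    return (p, truth) if truth is not None else (p, None)


def save_map_stack(path, maps: list, extra: dict | None = None) -> None:
    """Write a stack of density maps to HDF5 (/maps, /pixel_size_nm, /supports).

    ``extra`` entries (e.g. fourier_errors, seeds, scores) are stored as
    additional datasets.
    """
    real = [m for m in maps if m is not None]
    if not real:
        raise ValueError("no maps to save")
    with h5py.File(path, "w") as f:
        f.create_dataset("maps", data=np.stack([m.values for m in real]))
        f.create_dataset("pixel_size_nm", data=real[0].pixel_size)
        supports = np.stack([
            m.support if m.support is not None else np.ones_like(m.values, dtype=bool)
            for m in real
        ])
        f.create_dataset("supports", data=supports)
        for key, val in (extra or {}).items():
            f.create_dataset(key, data=np.asarray(val))


def load_map_stack(path):
    """Read a map stack from HDF5; returns (list of DensityMap, extras dict)."""
    with h5py.File(path, "r") as f:
        values = f["maps"][()]
        pixel_size = float(f["pixel_size_nm"][()])
        supports = f["supports"][()] if "supports" in f else [None] * len(values)
        extras = {k: f[k][()] for k in f
                  if k not in ("maps", "pixel_size_nm", "supports")}
    maps = [DensityMap(values=v, pixel_size=pixel_size, support=s)
            for v, s in zip(values, supports)]
    return maps, extras


def save_pattern_tiff(path, p: DiffractionPattern) -> None:
    """Write counts as 32-bit float TIFF with a JSON sidecar for q_step/mask."""
    tifffile.imwrite(path, p.counts.astype(np.float32))
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(json.dumps({
        "q_step_um_inv": p.q_step,
        "invalid_pixels": np.argwhere(~p.valid).tolist(),
    }))


def load_pattern_tiff(path) -> DiffractionPattern:
    counts = tifffile.imread(path).astype(float)
    sidecar = json.loads(Path(path).with_suffix(".json").read_text())
    valid = np.ones(counts.shape, dtype=bool)
    for i, j in sidecar["invalid_pixels"]:
        valid[i, j] = False
    counts[~valid] = 0.0
    return DiffractionPattern(counts=counts, valid=valid,
                              q_step=float(sidecar["q_step_um_inv"]))
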