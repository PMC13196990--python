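"""Planar sensor array geometries.

Arrays live in the z = 0 plane, centered on the origin.  Regular grids
record their (nx, ny) shape and pitch so templates can be reshaped and
shifted on the grid; sensor index = iy * nx + ix with x fastest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from neurofields.errors import InvalidParameterError


@dataclass
class SensorArray:
    positions: np.ndarray  # (N, 3) um
    pitch: Optional[Tuple[float, float]] = None
    layout_tag: str = "custom"
    shape: Optional[Tuple[int, int]] = None  # (nx, ny) for grids

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        uniq = np.unique(np.round(self.positions, 9), axis=0)
        if uniq.shape[0] != self.positions.shape[0]:
            raise InvalidParameterError("sensor positions must be unique")

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    @property
    def center(self) -> np.ndarray:
        return self.positions.mean(axis=0)


def make_sensor_grid(nx: int, ny: int, pitch: float) -> SensorArray:
    """Regular nx x ny grid at the given pitch, centered at the origin."""
    if nx < 1 or ny < 1 or pitch <= 0:
        raise InvalidParameterError("grid needs nx, ny >= 1 and pitch > 0")
    xs = (np.arange(nx) - (nx - 1) / 2.0) * pitch
    ys = (np.arange(ny) - (ny - 1) / 2.0) * pitch
    gx, gy = np.meshgrid(xs, ys)  # rows over y, x fastest within a row
    pos = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    return SensorArray(pos, pitch=(pitch, pitch), layout_tag="grid", shape=(nx, ny))


def make_neuropixels_like(
    n_channels: int = 384,
    row_pitch: float = 20.0,
    col_pitch: float = 32.0,
    stagger: float = 16.0,
) -> SensorArray:
    """Two-column checkerboard layout emulating a Neuropixels-style shank.

    Channels are laid out bottom-up in rows of two, with alternate rows
    offset horizontally by ``stagger``.  ``stagger=0`` gives a plain
    two-column grid.  The geometry is parameterized, not hard-coded.
    """
    if n_channels < 2:
        raise InvalidParameterError("need at least 2 channels")
    pos = []
    for ch in range(n_channels):
        row, col = divmod(ch, 2)
        x = (col - 0.5) * col_pitch + (stagger if row % 2 else 0.0)
        y = row * row_pitch
        pos.append((x, y, 0.0))
    pos = np.asarray(pos)
    pos[:, :2] -= pos[:, :2].mean(axis=0)
    return SensorArray(pos, pitch=None, layout_tag="neuropixels_like")


def probe_to_json(array: SensorArray, path, modalities=None) -> None:
    """Export a probe map: channel index -> position (+ modality)."""
    channels = []
    idx = 0
    for mod in (modalities or [None]):
        for i in range(array.n_sensors):
            entry = {"channel": idx, "position": array.positions[i].tolist()}
            if mod is not None:
                entry["modality"] = mod
            channels.append(entry)
            idx += 1
    doc = {
        "layout_tag": array.layout_tag,
        "pitch": list(array.pitch) if array.pitch else None,
        "shape": list(array.shape) if array.shape else None,
        "channels": channels,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def probe_from_json(path) -> SensorArray:
    with open(path) as fh:
        doc = json.load(fh)
    seen = set()
    pos = []
    for ch in doc["channels"]:
        key = tuple(ch["position"])
        if key not in seen:
            seen.add(key)
            pos.append(ch["position"])
    return SensorArray(
        np.asarray(pos),
        pitch=tuple(doc["pitch"]) if doc.get("pitch") else None,
        layout_tag=doc.get("layout_tag", "custom"),
        shape=tuple(doc["shape"]) if doc.get("shape") else None,
    )
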