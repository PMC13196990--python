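"""Spike templates on sensor arrays and the similarity machinery.

A spike template is the (n_sensors x n_times) matrix of one signal type
sampled over the course of a single spike.  Rotation of templates is
performed by resampling the rotated sample cloud back onto the original
sensor positions with inverse-distance-weighted K-nearest-neighbor
interpolation; planar magnetic components additionally mix as vector
components.  The spread template is the rotation average, and the cosine
similarity map compares a base template with the translated spread
template of another cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import h5py
import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from neurofields.arrays import SensorArray
from neurofields.currents import CompartmentCurrents
from neurofields.errors import InvalidParameterError
from neurofields.fields import (
    DEFAULT_SIGMA_E,
    biot_savart_kernel,
    line_source_kernel,
)

SIGNAL_TYPES = ("phi", "Bx", "By", "Bz")

#: paper-default spike window: 224 steps of 31.25 us = 7 ms
DEFAULT_N_T = 224
DEFAULT_DT = 0.03125


@dataclass
class SpikeTemplate:
    values: np.ndarray  # (N_R, N_T)
    sensors: SensorArray
    dt: float
    signal_type: str
    cell_id: Optional[int] = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.signal_type not in SIGNAL_TYPES:
            raise InvalidParameterError(f"unknown signal type {self.signal_type!r}")
        if self.values.shape[0] != self.sensors.n_sensors:
            raise InvalidParameterError("values rows must match sensor count")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))

    def mean_power(self) -> float:
        return float(np.mean(self.values**2))

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("sensor_positions", data=self.sensors.positions)
            f.attrs["dt"] = self.dt
            f.attrs["signal_type"] = self.signal_type
            if self.cell_id is not None:
                f.attrs["cell_id"] = self.cell_id
            if self.sensors.pitch is not None:
                f.attrs["pitch"] = self.sensors.pitch
            if self.sensors.shape is not None:
                f.attrs["shape"] = self.sensors.shape

    @classmethod
    def load(cls, path) -> "SpikeTemplate":
        with h5py.File(path, "r") as f:
            arr = SensorArray(
                f["sensor_positions"][...],
                pitch=tuple(f.attrs["pitch"]) if "pitch" in f.attrs else None,
                shape=tuple(int(v) for v in f.attrs["shape"])
                if "shape" in f.attrs
                else None,
            )
            return cls(
                values=f["values"][...],
                sensors=arr,
                dt=float(f.attrs["dt"]),
                signal_type=str(f.attrs["signal_type"]),
                cell_id=int(f.attrs["cell_id"]) if "cell_id" in f.attrs else None,
            )


@dataclass
class SpreadTemplate:
    """Rotation-averaged template (same shape as the base template)."""

    values: np.ndarray
    sensors: SensorArray
    dt: float
    signal_type: str
    theta_step: float
    cell_id: Optional[int] = None


@dataclass
class SimilarityMap:
    dx: np.ndarray  # displacement grid axes (um)
    dy: np.ndarray
    values: np.ndarray  # (len(dy), len(dx))
    cell_ids: tuple
    signal_type: str


def compute_template(
    c: CompartmentCurrents,
    sensors: SensorArray,
    signal_type: str,
    sigma_e: float = DEFAULT_SIGMA_E,
    cell_id: Optional[int] = None,
) -> SpikeTemplate:
    """Sample one signal type on the array for the whole spike window."""
    if signal_type == "phi":
        w = line_source_kernel(c, sensors.positions, sigma_e)
        values = w @ c.I_m
    elif signal_type in ("Bx", "By", "Bz"):
        k = biot_savart_kernel(c, sensors.positions)
        comp = {"Bx": 0, "By": 1, "Bz": 2}[signal_type]
        values = k[:, comp, :] @ c.I_a
    else:
        raise InvalidParameterError(f"unknown signal type {signal_type!r}")
    return SpikeTemplate(values, sensors, c.dt, signal_type, cell_id)


def _rotation_operator(
    sensors: SensorArray, theta: float, K: int
) -> sparse.csr_matrix:
    """Sparse resampling operator for a rotation by ``theta`` degrees.

    Sensor coordinates are rotated by -theta about the array center
    (equivalent to rotating the source by +theta); the value at each
    original sensor is the inverse-distance weighted mean of the K
    nearest rotated samples, with an exact-match short circuit.
    """
    th = math.radians(theta)
    c, s = math.cos(-th), math.sin(-th)
    xy = sensors.positions[:, :2] - sensors.center[:2]
    rotated = xy @ np.array([[c, s], [-s, c]]).T
    tree = cKDTree(rotated)
    dist, idx = tree.query(xy, k=K)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)

    exact = dist[:, 0] < 1e-9
    safe = np.where(dist < 1e-12, 1.0, dist)
    inv = 1.0 / safe
    weights = inv / inv.sum(axis=1, keepdims=True)
    weights[exact] = 0.0
    weights[exact, 0] = 1.0

    n = sensors.n_sensors
    rows = np.repeat(np.arange(n), K)
    return sparse.csr_matrix(
        (weights.ravel(), (rows, idx.ravel())), shape=(n, n)
    )


def rotate_template(
    t: SpikeTemplate,
    theta: float,
    K: int = 5,
    companion: Optional[SpikeTemplate] = None,
    mode: str = "normalized",
) -> SpikeTemplate:
    """Template of the source rotated by ``theta`` degrees in-plane.

    For planar magnetic components (Bx, By) the ``companion`` template of
    the other planar component is required so the vector components can
    be mixed: (Bx', By') = (cos t Bx - sin t By, sin t Bx + cos t By).
    ``mode="printed"`` divides the interpolated value by K on top of the
    already-normalized weights (the literal printed formula);
    ``"normalized"`` (default) uses the convex combination.
    """
    if mode not in ("normalized", "printed"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    op = _rotation_operator(t.sensors, theta, K)
    scale = (1.0 / K) if mode == "printed" else 1.0

    if t.signal_type in ("phi", "Bz"):
        return SpikeTemplate(
            scale * (op @ t.values), t.sensors, t.dt, t.signal_type, t.cell_id
        )

    if companion is None or companion.signal_type == t.signal_type:
        raise InvalidParameterError(
            "rotating a planar component requires the companion planar template"
        )
    bx_t = t if t.signal_type == "Bx" else companion
    by_t = t if t.signal_type == "By" else companion
    bx = scale * (op @ bx_t.values)
    by = scale * (op @ by_t.values)
    th = math.radians(theta)
    c, s = math.cos(th), math.sin(th)
    mixed = c * bx - s * by if t.signal_type == "Bx" else s * bx + c * by
    return SpikeTemplate(mixed, t.sensors, t.dt, t.signal_type, t.cell_id)


def translate_template(t: SpikeTemplate, delta) -> SpikeTemplate:
    """Shift a grid template by an in-plane displacement, zero-filling.

    ``delta`` must be an integer multiple of the pitch; other values are
    snapped to the nearest grid vector with a warning.
    """
    if t.sensors.shape is None or t.sensors.pitch is None:
        raise InvalidParameterError("translate_template requires a regular grid")
    nx, ny = t.sensors.shape
    px, py = t.sensors.pitch
    fx, fy = delta[0] / px, delta[1] / py
    mx, my = round(fx), round(fy)
    if abs(fx - mx) > 1e-9 or abs(fy - my) > 1e-9:
        warnings.warn(
            f"delta {tuple(delta)} is not a grid vector; snapping to "
            f"({mx * px}, {my * py})",
            stacklevel=2,
        )
    grid = t.values.reshape(ny, nx, -1)
    out = np.zeros_like(grid)
    xs_src = slice(max(0, -mx), min(nx, nx - mx))
    ys_src = slice(max(0, -my), min(ny, ny - my))
    xs_dst = slice(max(0, mx), min(nx, nx + mx))
    ys_dst = slice(max(0, my), min(ny, ny + my))
    out[ys_dst, xs_dst] = grid[ys_src, xs_src]
    return SpikeTemplate(
        out.reshape(t.values.shape), t.sensors, t.dt, t.signal_type, t.cell_id
    )


def spread_template(
    t: SpikeTemplate,
    theta_step: float = 15.0,
    K: int = 5,
    companion: Optional[SpikeTemplate] = None,
    mode: str = "normalized",
) -> SpreadTemplate:
    """Rotation-averaged (swept) template over a full circle."""
    if theta_step <= 0 or 360.0 % theta_step != 0:
        raise InvalidParameterError("360 must be divisible by theta_step")
    n_rot = int(360.0 / theta_step)
    acc = np.zeros_like(t.values)
    for i in range(n_rot):
        acc += rotate_template(t, i * theta_step, K, companion, mode).values
    return SpreadTemplate(
        acc / n_rot, t.sensors, t.dt, t.signal_type, theta_step, t.cell_id
    )


def default_displacement_grid(extent: float = 400.0, step: float = 50.0):
    """Square displacement grid from -extent to +extent at the given step."""
    axis = np.arange(-extent, extent + 0.5 * step, step)
    return axis, axis


def similarity_map(
    t_n: SpikeTemplate,
    t_m: SpikeTemplate,
    displacement_grid=None,
    theta_step: float = 15.0,
    K: int = 5,
    sweep: bool = True,
    companion_m: Optional[SpikeTemplate] = None,
) -> SimilarityMap:
    """Orientation-averaged cosine similarity over a displacement grid.

    The numerator pairs the base template of cell n with the translated
    spread template of cell m; the denominator uses the norms of the base
    template and of the *translated base* template of m.  ``sweep=False``
    replaces the spread with the base template (pure translated cosine).
    """
    if t_n.sensors.n_sensors != t_m.sensors.n_sensors or t_n.dt != t_m.dt:
        raise InvalidParameterError("templates must share array and dt")
    if t_n.norm == 0 or t_m.norm == 0:
        raise InvalidParameterError("zero-norm template")
    if displacement_grid is None:
        displacement_grid = default_displacement_grid()
    dxs, dys = displacement_grid

    if sweep:
        g_m = spread_template(t_m, theta_step, K, companion_m)
        g_vals = g_m.values
    else:
        g_vals = t_m.values
    g_tpl = SpikeTemplate(g_vals, t_m.sensors, t_m.dt, t_m.signal_type, t_m.cell_id)

    base_norm = t_n.norm
    values = np.zeros((len(dys), len(dxs)))
    for iy, dy in enumerate(dys):
        for ix, dx in enumerate(dxs):
            shifted_g = translate_template(g_tpl, (dx, dy)).values
            shifted_m = translate_template(t_m, (dx, dy)).values
            denom = base_norm * np.linalg.norm(shifted_m)
            if denom == 0:
                continue
            values[iy, ix] = float(np.sum(t_n.values * shifted_g)) / denom
    return SimilarityMap(
        dx=np.asarray(dxs, dtype=float),
        dy=np.asarray(dys, dtype=float),
        values=values,
        cell_ids=(t_n.cell_id, t_m.cell_id),
        signal_type=t_n.signal_type,
    )


def effective_radius(
    smap: SimilarityMap,
    gamma: float,
    dx: Optional[float] = None,
    dy: Optional[float] = None,
) -> float:
    """Radius of the disc with area equal to the supra-gamma region.

    ``sqrt(count * dx * dy / pi)`` where count is the number of
    displacement-grid points whose similarity exceeds ``gamma``.
    """
    if not (-1.0 < gamma < 1.0):
        raise InvalidParameterError("gamma must be in (-1, 1)")
    if dx is None:
        dx = float(smap.dx[1] - smap.dx[0]) if smap.dx.size > 1 else 1.0
    if dy is None:
        dy = float(smap.dy[1] - smap.dy[0]) if smap.dy.size > 1 else 1.0
    count = int(np.sum(smap.values > gamma))
    return math.sqrt(count * dx * dy / math.pi)
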