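"""Axial and transmembrane current distributions.

Two current sources are provided:

* the closed-form cylinder model, where the longitudinal and
  transmembrane surface current densities follow from derivatives of a
  prescribed membrane-potential profile, and
* a compartmental traveling-wave scheme that prescribes the
  intracellular potential as a rigidly propagating spatial profile on an
  arbitrary morphology and derives axial/transmembrane currents from
  Kirchhoff's law.

Units: potentials mV, positions um, conductivity S/m, time ms.  With
these choices the compartmental axial conductance works out such that
currents are in nA: ``I[nA] = sigma_i * pi * r^2 / L * dphi[mV]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import h5py
import numpy as np

from neurofields.errors import InvalidParameterError, UndefinedCountError
from neurofields.morphology import Morphology

#: default propagation speed of the prescribed wave (um/ms)
DEFAULT_VELOCITY = 500.0


@dataclass
class APWaveform:
    """Spatial profile of the membrane potential during a spike.

    ``profile`` maps axial position (um) to potential (mV) and must decay
    to zero away from its support.  ``sigma`` and ``amplitude`` are kept
    for parametric (Gaussian) profiles.
    """

    profile: Callable[[np.ndarray], np.ndarray]
    sigma: Optional[float] = None
    amplitude: Optional[float] = None
    velocity: float = DEFAULT_VELOCITY

    def __call__(self, z) -> np.ndarray:
        return self.profile(np.asarray(z, dtype=float))


def gaussian_ap(sigma: float, amplitude: float = 100.0,
                velocity: float = DEFAULT_VELOCITY) -> APWaveform:
    """Gaussian membrane-potential profile: A * exp(-z^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
    s2 = 2.0 * sigma * sigma

    def profile(z):
        return amplitude * np.exp(-np.square(z) / s2)

    return APWaveform(profile=profile, sigma=sigma, amplitude=amplitude,
                      velocity=velocity)


def asymmetric_ap(
    sigma_front: float,
    sigma_tail: float,
    amplitude: float = 100.0,
    velocity: float = DEFAULT_VELOCITY,
) -> APWaveform:
    """Piecewise-Gaussian profile with a sharp front and a slow tail.

    ``sigma_front`` applies ahead of the peak (larger z, reached first by
    an advancing wave), ``sigma_tail`` behind it.  The steep front makes
    the axial-current time course at a fixed position dominantly
    single-signed, which stabilizes peak-sign polarity labeling — the
    shape asymmetry real action potentials have and a symmetric Gaussian
    lacks.
    """
    if sigma_front <= 0 or sigma_tail <= 0:
        raise InvalidParameterError("sigma_front and sigma_tail must be > 0")

    def profile(z):
        z = np.asarray(z, dtype=float)
        s = np.where(z >= 0, sigma_front, sigma_tail)
        return amplitude * np.exp(-np.square(z) / (2.0 * s * s))

    return APWaveform(profile=profile, sigma=max(sigma_front, sigma_tail),
                      amplitude=amplitude, velocity=velocity)


@dataclass
class AxonCurrentProfile:
    """Longitudinal and transmembrane surface current densities on a grid."""

    z: np.ndarray
    i_long: np.ndarray
    i_trans: np.ndarray
    sigma_i: float
    a: float


def analytic_axon_currents(
    wave: APWaveform, sigma_i: float, a: float, z_grid
) -> AxonCurrentProfile:
    """Cylinder-model current densities from the membrane potential.

    The longitudinal component is ``-sigma_i * dphi/dz`` and the
    transmembrane component ``(sigma_i * a / 2) * d2phi/dz2``; both are
    evaluated with second-order central differences on the uniform
    ``z_grid``.
    """
    z = np.asarray(z_grid, dtype=float)
    if z.size < 3:
        raise InvalidParameterError("z_grid needs at least 3 points")
    dz = np.diff(z)
    if not np.allclose(dz, dz[0], rtol=1e-9, atol=1e-12):
        raise InvalidParameterError("z_grid must be uniform")
    h = dz[0]
    phi = wave(z)
    dphi = np.gradient(phi, h)
    d2phi = np.empty_like(phi)
    d2phi[1:-1] = (phi[2:] - 2.0 * phi[1:-1] + phi[:-2]) / (h * h)
    d2phi[0] = d2phi[1]
    d2phi[-1] = d2phi[-2]
    return AxonCurrentProfile(
        z=z,
        i_long=-sigma_i * dphi,
        i_trans=0.5 * sigma_i * a * d2phi,
        sigma_i=sigma_i,
        a=a,
    )


def count_sign_reversals(values, noise_floor: float = 0.01) -> int:
    """Count strict sign changes between consecutive supra-floor samples.

    Samples with magnitude below ``noise_floor * max|values|`` are
    skipped before counting so that float dust near zero crossings does
    not inflate the count.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidParameterError("need at least 2 samples")
    vmax = np.max(np.abs(v))
    kept = v[np.abs(v) >= noise_floor * vmax] if vmax > 0 else np.array([])
    if kept.size == 0:
        raise UndefinedCountError("all samples below the noise floor")
    signs = np.sign(kept)
    return int(np.sum(signs[1:] != signs[:-1]))


@dataclass
class CompartmentCurrents:
    """Per-compartment axial and transmembrane currents over time.

    ``I_a`` and ``I_m`` are (n_compartments, n_times) in nA.
    ``directions`` carry the compartment length as their magnitude; the
    soma's zero-length compartment has a zero direction vector and no
    axial current.  At every time step the transmembrane currents sum to
    zero (Kirchhoff), which the constructor enforces.
    """

    positions: np.ndarray
    directions: np.ndarray
    I_a: np.ndarray
    I_m: np.ndarray
    dt: float
    check_conservation: bool = field(default=True, repr=False)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.I_a = np.atleast_2d(np.asarray(self.I_a, dtype=float))
        self.I_m = np.atleast_2d(np.asarray(self.I_m, dtype=float))
        if self.check_conservation:
            net = np.abs(self.I_m.sum(axis=0))
            scale = np.max(np.abs(self.I_m)) or 1.0
            if np.any(net > 1e-6 * scale):
                raise InvalidParameterError(
                    "transmembrane currents do not sum to zero"
                )

    @property
    def n_compartments(self) -> int:
        return self.positions.shape[0]

    @property
    def n_times(self) -> int:
        return self.I_a.shape[1]

    def net_membrane_current(self) -> np.ndarray:
        return self.I_m.sum(axis=0)

    # -- persistence ------------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=self.positions)
            f.create_dataset("directions", data=self.directions)
            f.create_dataset("I_a", data=self.I_a)
            f.create_dataset("I_m", data=self.I_m)
            f.attrs["dt"] = self.dt

    @classmethod
    def from_hdf5(cls, path) -> "CompartmentCurrents":
        with h5py.File(path, "r") as f:
            return cls(
                positions=f["positions"][...],
                directions=f["directions"][...],
                I_a=f["I_a"][...],
                I_m=f["I_m"][...],
                dt=float(f.attrs["dt"]),
            )


def propagate_ap(
    m: Morphology,
    wave: APWaveform,
    sigma_i: float,
    t_grid,
    center_start: Optional[float] = None,
    attenuation_length: Optional[float] = None,
) -> CompartmentCurrents:
    """Compartment currents from a traveling intracellular wave.

    The intracellular potential is prescribed as
    ``phi_i(s, t) = A(s) * profile(s - center_start - v t)`` where ``s``
    is the path distance from the soma and ``A(s) = exp(-s / lambda)``
    when ``attenuation_length`` (lambda, um) is given, else 1.  Axial
    current on each segment follows from its axial conductance; the
    transmembrane current at each node is the net axial current arriving
    there, so conservation holds exactly by construction.

    Attenuation concentrates signal power near the proximal process (the
    region real cells drive hardest) instead of spreading it uniformly
    along the transit, which matters for polarity-based reconstruction.

    ``center_start`` defaults to ``-2 sigma`` (wave approaching from the
    proximal side at t = 0) when the waveform is parametric, else 0.
    """
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t.size > 1:
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
            raise InvalidParameterError("t_grid must be uniform")
        dt = float(dts[0])
    else:
        dt = 0.0
    if center_start is None:
        center_start = -2.0 * wave.sigma if wave.sigma else 0.0

    n = len(m)
    parents = m.parents
    lengths = m.lengths
    radii = m.radii
    root = int(np.where(parents == -1)[0][0])

    # path distance of each segment's start/end node from the root
    s_end = np.zeros(n)
    for i in range(n):  # segments are stored parent-before-child
        if parents[i] >= 0 and parents[i] > i:
            raise InvalidParameterError("segments must be ordered parent-first")
    s_start = np.zeros(n)
    for i in range(n):
        p = parents[i]
        s_start[i] = 0.0 if p < 0 else s_end[p]
        s_end[i] = s_start[i] + lengths[i]

    # axial conductance per segment (zero-length soma -> no axial current)
    with np.errstate(divide="ignore"):
        g = np.where(lengths > 0, sigma_i * np.pi * radii**2 / np.where(lengths > 0, lengths, 1.0), 0.0)

    center = center_start + wave.velocity * t  # (T,)
    phi_start = wave(s_start[:, None] - center[None, :])  # (N, T)
    phi_end = wave(s_end[:, None] - center[None, :])
    if attenuation_length is not None:
        if attenuation_length <= 0:
            raise InvalidParameterError("attenuation_length must be > 0")
        phi_start = phi_start * np.exp(-s_start / attenuation_length)[:, None]
        phi_end = phi_end * np.exp(-s_end / attenuation_length)[:, None]
    I_a = g[:, None] * (phi_start - phi_end)  # nA, start -> end positive

    # membrane current at the node terminating each segment: arriving
    # axial current minus what its children carry away; the root collects
    # the negated sum of its children's currents.
    child_sum = np.zeros_like(I_a)
    has_parent = parents >= 0
    np.add.at(child_sum, parents[has_parent], I_a[has_parent])
    I_m = I_a - child_sum
    I_m[root] = -child_sum[root]

    return CompartmentCurrents(
        positions=m.midpoints,
        directions=m.ends - m.starts,
        I_a=I_a,
        I_m=I_m,
        dt=dt,
    )
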