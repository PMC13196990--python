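"""Extracellular fields from compartment currents.

Magnetic flux density is computed with the compartmental Biot-Savart
sum over axial currents; electrical potential with the line-source
model over transmembrane currents (reference at infinity).  Both are
linear in the currents, so each exposes a precomputed geometry kernel
that maps current matrices to field matrices.

Unit bookkeeping (positions um, currents nA):

* ``B[pT] = 100 * sum_n I_a,n[nA] * (d_n x r_hat) / |r'|^2[um^2]``
  (this folds mu0/4pi with the unit conversions; a 1 nA infinite wire
  gives 20 pT at 10 um, i.e. mu0*I/(2*pi*rho)).
* ``phi[uV] = (1000 / (4 pi sigma_e)) * sum_n I_m,n[nA] * w_n`` where
  ``w_n`` is 1/R for a point source and the standard line-source log
  term for an extended segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from neurofields.currents import CompartmentCurrents
from neurofields.errors import InvalidParameterError, SingularEvaluationError

#: mu0/(4 pi) in pT * um^2 / (nA * um)
_BIOT_SAVART_PREFACTOR = 100.0
#: minimum allowed source-to-point distance (um)
MIN_STANDOFF = 0.1

DEFAULT_SIGMA_E = 0.3  # S/m
DEFAULT_SIGMA_I = 0.3  # S/m


@dataclass
class FieldSamples:
    """Field values at a set of points over time.

    ``values`` is (n_points, n_times) for scalar signal types and
    (n_points, 3, n_times) for ``Bvec``.
    """

    points: np.ndarray
    values: np.ndarray
    signal_type: str
    sigma_e: Optional[float] = None


@dataclass
class ScalingFit:
    """Least-squares power-law fit of magnitude vs distance."""

    distances: np.ndarray
    magnitudes: np.ndarray
    exponent: float
    fit_window: tuple


def biot_savart_kernel(c: CompartmentCurrents, points) -> np.ndarray:
    """Geometry kernel K with shape (P, 3, N): B = K @ I_a (pT).

    Raises :class:`SingularEvaluationError` if any point lies within
    ``MIN_STANDOFF`` of a compartment midpoint — no silent clamping.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))  # (P, 3)
    mid = c.positions  # (N, 3)
    r = pts[:, None, :] - mid[None, :, :]  # (P, N, 3), source -> point
    dist = np.linalg.norm(r, axis=2)  # (P, N)
    # only compartments that carry current can be singular
    active = np.linalg.norm(c.directions, axis=1) > 0
    if np.any(dist[:, active] < MIN_STANDOFF):
        raise SingularEvaluationError(
            f"evaluation point within {MIN_STANDOFF} um of a source midpoint"
        )
    dist = np.where(dist > 0, dist, np.inf)
    cross = np.cross(np.broadcast_to(c.directions[None, :, :], r.shape), r)
    k = _BIOT_SAVART_PREFACTOR * cross / dist[:, :, None] ** 3  # (P, N, 3)
    return np.transpose(k, (0, 2, 1))  # (P, 3, N)


def biot_savart(c: CompartmentCurrents, points) -> FieldSamples:
    """Vector magnetic field (pT) at each point and time step."""
    k = biot_savart_kernel(c, points)
    values = k @ c.I_a  # (P, 3, T)
    return FieldSamples(
        points=np.atleast_2d(np.asarray(points, dtype=float)),
        values=values,
        signal_type="Bvec",
    )


def line_source_kernel(
    c: CompartmentCurrents, points, sigma_e: float = DEFAULT_SIGMA_E
) -> np.ndarray:
    """Potential kernel W with shape (P, N): phi = W @ I_m (uV).

    Each segment's transmembrane current is spread uniformly along its
    line; zero-length compartments (the soma sphere) fall back to point
    sources.  Reference at infinity.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    starts = c.positions - 0.5 * c.directions
    lengths = np.linalg.norm(c.directions, axis=1)  # (N,)
    n = lengths.size
    p = pts.shape[0]
    w = np.empty((p, n))

    pref = 1000.0 / (4.0 * np.pi * sigma_e)

    point_like = lengths <= 1e-9
    if np.any(point_like):
        d = np.linalg.norm(
            pts[:, None, :] - c.positions[None, point_like, :], axis=2
        )
        if np.any(d < MIN_STANDOFF):
            raise SingularEvaluationError("point within standoff of a point source")
        w[:, point_like] = pref / d

    line = ~point_like
    if np.any(line):
        a = starts[line]  # (M, 3)
        t_hat = c.directions[line] / lengths[line][:, None]
        ll = lengths[line]
        rel = pts[:, None, :] - a[None, :, :]  # (P, M, 3)
        z = np.einsum("pmk,mk->pm", rel, t_hat)  # axial coordinate from start
        rho2 = np.maximum(np.einsum("pmk,pmk->pm", rel, rel) - z * z, 0.0)
        # distance to the finite segment, for the singularity guard
        zc = np.clip(z, 0.0, ll[None, :])
        seg_dist = np.sqrt(rho2 + (z - zc) ** 2)
        if np.any(seg_dist < MIN_STANDOFF):
            raise SingularEvaluationError("point within standoff of a source line")
        rho = np.sqrt(np.maximum(rho2, 1e-18))
        term = np.arcsinh(z / rho) - np.arcsinh((z - ll[None, :]) / rho)
        w[:, line] = pref * term / ll[None, :]

    return w


def line_source_potential(
    c: CompartmentCurrents, points, sigma_e: float = DEFAULT_SIGMA_E
) -> FieldSamples:
    """Extracellular potential (uV) from transmembrane currents."""
    w = line_source_kernel(c, points, sigma_e)
    return FieldSamples(
        points=np.atleast_2d(np.asarray(points, dtype=float)),
        values=w @ c.I_m,
        signal_type="phi",
        sigma_e=sigma_e,
    )


@dataclass
class DipoleResult:
    """Current dipole moment per time step (pA m) with a balance flag."""

    moment: np.ndarray  # (T, 3)
    balanced: bool


def current_dipole(c: CompartmentCurrents, tol: float = 1e-6) -> DipoleResult:
    """p(t) = sum_n I_m,n(t) * position_n, in pA m.

    If the net membrane current exceeds ``tol`` of the maximum |I_m| the
    result is origin-dependent and flagged as unbalanced rather than
    raising.
    """
    net = np.abs(c.I_m.sum(axis=0))
    scale = np.max(np.abs(c.I_m)) or 1.0
    balanced = bool(np.all(net <= tol * scale))
    # nA * um = 1e-3 pA m
    moment = 1e-3 * (c.I_m.T @ c.positions)
    return DipoleResult(moment=moment, balanced=balanced)


def fit_scaling_exponent(distances, magnitudes, fit_window) -> ScalingFit:
    """Power-law exponent n such that magnitude ~ R^-n over the window.

    Least-squares line of log(magnitude) against log(distance) restricted
    to ``fit_window = (r_min, r_max)``; the exponent is the negated slope.
    """
    r = np.asarray(distances, dtype=float)
    mag = np.asarray(magnitudes, dtype=float)
    lo, hi = fit_window
    mask = (r >= lo) & (r <= hi)
    if mask.sum() < 5:
        raise InvalidParameterError("need at least 5 points inside fit_window")
    if np.any(mag[mask] <= 0):
        raise InvalidParameterError("magnitudes must be positive inside fit_window")
    slope = np.polyfit(np.log(r[mask]), np.log(mag[mask]), 1)[0]
    return ScalingFit(
        distances=r, magnitudes=mag, exponent=float(-slope), fit_window=(lo, hi)
    )


def cylinder_scaling_exponents(
    sigma: float = 167.0,
    a: float = 1.0,
    sigma_i: float = DEFAULT_SIGMA_I,
    sigma_e: float = DEFAULT_SIGMA_E,
    amplitude: float = 100.0,
    n_r: int = 40,
    grid_factor: float = 20.0,
) -> dict:
    """Radial decay exponents of the analytic cylinder model.

    Discretizes the longitudinal and transmembrane current densities of
    a Gaussian membrane-potential profile along a straight axon and fits
    log-log slopes over lateral distances 10 sigma .. 100 sigma:

    * ``B``: |B| of the axial (dipole-like) currents, sampled along a
      45-degree radial line (the perpendicular midplane is a symmetry
      null of the antisymmetric current profile);
    * ``phi``: potential of the (quadrupole-like) transmembrane point
      sources, referenced at infinity, along a perpendicular line;
    * ``grad_phi``: magnitude of the potential gradient there.

    Returns a dict of :class:`ScalingFit` keyed by those names.
    """
    from neurofields.currents import (
        CompartmentCurrents,
        analytic_axon_currents,
        gaussian_ap,
    )

    h = sigma / grid_factor
    z = np.arange(-6 * sigma, 6 * sigma + 0.5 * h, h)
    prof = analytic_axon_currents(gaussian_ap(sigma, amplitude), sigma_i, a, z)
    n = z.size
    pos = np.column_stack([z, np.zeros(n), np.zeros(n)])

    r = np.geomspace(10 * sigma, 100 * sigma, n_r)
    window = (r[0], r[-1])

    # magnetic field of the axial currents, off the symmetry plane
    c_long = CompartmentCurrents(
        positions=pos,
        directions=np.tile([h, 0.0, 0.0], (n, 1)),
        I_a=prof.i_long[:, None],
        I_m=np.zeros((n, 1)),
        dt=1.0,
    )
    u = np.array([np.cos(np.pi / 4), np.sin(np.pi / 4), 0.0])
    b = biot_savart(c_long, r[:, None] * u[None, :])
    fit_b = fit_scaling_exponent(
        r, np.linalg.norm(b.values[:, :, 0], axis=1), window
    )

    # potential and gradient of the transmembrane point sources; the
    # residual monopole of the discretized second derivative is removed
    i_m = prof.i_trans[:, None] * h
    i_m = i_m - i_m.mean()
    c_trans = CompartmentCurrents(
        positions=pos,
        directions=np.zeros((n, 3)),
        I_a=np.zeros((n, 1)),
        I_m=i_m,
        dt=1.0,
    )
    pts = np.column_stack([np.zeros_like(r), r, np.zeros_like(r)])
    phi = line_source_potential(c_trans, pts, sigma_e).values[:, 0]
    fit_phi = fit_scaling_exponent(r, np.abs(phi), window)

    # analytic gradient of the point-source sum
    rel = pts[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(rel, axis=2)
    e = (i_m[:, 0][None, :, None] * rel / dist[:, :, None] ** 3).sum(axis=1)
    fit_grad = fit_scaling_exponent(r, np.linalg.norm(e, axis=1), window)

    return {"B": fit_b, "phi": fit_phi, "grad_phi": fit_grad}


def suprathreshold_area(template, fraction: float) -> float:
    """Sensor-plane area (um^2) where the peak |signal| beats the threshold.

    The threshold is ``fraction`` of the global maximum absolute signal
    over all sensors and time steps; each qualifying sensor contributes
    one pitch cell of area.
    """
    if not (0 < fraction <= 1):
        raise InvalidParameterError("fraction must be in (0, 1]")
    pitch = template.sensors.pitch
    if pitch is None:
        raise InvalidParameterError("suprathreshold_area requires a known pitch")
    peaks = np.max(np.abs(template.values), axis=1)
    global_max = peaks.max()
    count = int(np.sum(peaks >= fraction * global_max))
    return count * pitch[0] * pitch[1]
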