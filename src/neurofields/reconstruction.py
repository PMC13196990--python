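"""Polarity-boundary morphology reconstruction from Bz templates.

The normal magnetic field flips sign across a neuron's dominant
process, so the zero set of a classifier separating positive- from
negative-polarity sensors traces that process.  The single-shot
estimator (GNBE) fits an RBF-kernel maximum-margin classifier on sensor
positions vs polarities and extracts the zero level-set of its decision
function.  The refinement pass (CNBE) estimates the axon hillock from
the highest-power sensors, discards sensors behind the hillock (where
opposing dendritic currents invert the polarity pattern), and re-runs
the boundary fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage import measure
from sklearn.svm import SVC

from neurofields.errors import InvalidParameterError, NoBoundaryError
from neurofields.morphology import Morphology
from neurofields.templates import SpikeTemplate


@dataclass
class PolarityLabels:
    positions: np.ndarray  # (M, 2), sensors passing the inclusion rule
    labels: np.ndarray  # (M,), +1 / -1
    power: np.ndarray  # (M,), mean signal power per sensor


@dataclass
class BoundaryEstimate:
    boundary: np.ndarray  # (K, 2) ordered polyline (um)
    grid_x: np.ndarray
    grid_y: np.ndarray
    decision: np.ndarray  # decision values on (len(grid_y), len(grid_x))
    excluded_sensor_mask: Optional[np.ndarray] = None
    hillock_estimate: Optional[np.ndarray] = None
    warnings: list = field(default_factory=list)

    def export_csv(self, path) -> None:
        np.savetxt(path, self.boundary, delimiter=",", header="x_um,y_um", comments="")


def sensor_polarity(t: SpikeTemplate) -> PolarityLabels:
    """Label each sensor by the sign of its absolute-maximum sample.

    Exactly-zero waveforms are excluded.  The mean power of each
    included sensor's waveform is recorded for the CNBE power ranking.
    """
    if t.signal_type != "Bz":
        raise InvalidParameterError("polarity labeling expects a Bz template")
    peaks_idx = np.argmax(np.abs(t.values), axis=1)
    peak_vals = t.values[np.arange(t.values.shape[0]), peaks_idx]
    keep = peak_vals != 0.0
    return PolarityLabels(
        positions=t.sensors.positions[keep, :2],
        labels=np.sign(peak_vals[keep]).astype(int),
        power=np.mean(t.values[keep] ** 2, axis=1),
    )


def _decision_grid(positions: np.ndarray, density: int = 4, bounds=None):
    """Evaluation grid covering the sensor bounding box at density x pitch."""
    if bounds is None:
        x0, y0 = positions.min(axis=0)
        x1, y1 = positions.max(axis=0)
    else:
        (x0, x1), (y0, y1) = bounds
    n_side = max(2, int(round(np.sqrt(positions.shape[0]))))
    gx = np.linspace(x0, x1, density * n_side)
    gy = np.linspace(y0, y1, density * n_side)
    return gx, gy


def gnbe(
    labels: PolarityLabels,
    kernel_scale: Optional[float] = None,
    regularization: float = 1.0,
    grid_density: int = 4,
    grid_bounds=None,
) -> BoundaryEstimate:
    """Single-shot boundary estimate from sensor polarities.

    Fits an RBF-kernel SVM on sensor (x, y) vs polarity labels and
    returns the longest zero-level contour of the decision function on a
    dense grid (``grid_density`` times the sensor density).
    ``kernel_scale`` defaults to twice the typical nearest-neighbor
    spacing of the labeled sensors.
    """
    if labels.positions.shape[0] < 2 or np.unique(labels.labels).size < 2:
        raise NoBoundaryError("both polarities are required to estimate a boundary")
    if kernel_scale is None:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(labels.positions).query(labels.positions, k=2)
        kernel_scale = 2.0 * float(np.median(d[:, 1]))
    gamma = 1.0 / (2.0 * kernel_scale**2)
    svm = SVC(kernel="rbf", C=regularization, gamma=gamma)
    svm.fit(labels.positions, labels.labels)

    gx, gy = _decision_grid(labels.positions, grid_density, grid_bounds)
    mesh = np.column_stack(
        [g.ravel() for g in np.meshgrid(gx, gy)]
    )
    decision = svm.decision_function(mesh).reshape(len(gy), len(gx))

    contours = measure.find_contours(decision, 0.0)
    if not contours:
        raise NoBoundaryError("decision function has no zero level-set on the grid")
    contour = max(contours, key=len)  # rows are (iy, ix) in grid index units
    bx = np.interp(contour[:, 1], np.arange(len(gx)), gx)
    by = np.interp(contour[:, 0], np.arange(len(gy)), gy)
    return BoundaryEstimate(
        boundary=np.column_stack([bx, by]),
        grid_x=gx,
        grid_y=gy,
        decision=decision,
    )


def _weighted_centroid(points: np.ndarray, weights: np.ndarray) -> np.ndarray:
    return (points * weights[:, None]).sum(axis=0) / weights.sum()


def cnbe(
    t: SpikeTemplate,
    first_pass: Optional[BoundaryEstimate] = None,
    kernel_scale: Optional[float] = None,
    regularization: float = 1.0,
    hillock_weight: float = 50.0,
    outlier_distance: float = 50.0,
    cut_offset: float = 10.0,
) -> BoundaryEstimate:
    """Second-pass boundary estimate with near-soma correction.

    Steps: estimate the axon hillock as the power-weighted centroid of
    the 4 highest-power sensors; form 24 more centroids from the sensors
    ranked 5-100 in consecutive groups of 4; snap each to the nearest
    first-pass boundary point; drop outliers whose mean distance to
    their 4 nearest peers exceeds ``outlier_distance``; fit a weighted
    line through the survivors with the hillock at ``hillock_weight``
    times a point's weight; exclude all sensors behind a perpendicular
    cut ``cut_offset`` um behind the hillock; re-run the boundary fit on
    the remainder.  Arrays smaller than 100 sensors use proportionally
    scaled ranks.  If every candidate point is discarded the first pass
    is returned with a warning.
    """
    labels = sensor_polarity(t)
    if first_pass is None:
        first_pass = gnbe(labels, kernel_scale, regularization)
    notes = []

    n = labels.positions.shape[0]
    if n >= 100:
        n_top, n_rest = 4, 96
    else:
        n_top = max(1, int(round(0.04 * n)))
        n_rest = max(4, ((n - n_top) // 4) * 4)
        notes.append(f"only {n} sensors; using top {n_top} + next {n_rest} ranks")
    order = np.argsort(-labels.power)
    top = order[:n_top]
    hillock = _weighted_centroid(labels.positions[top], labels.power[top])

    rest = order[n_top : n_top + n_rest]
    centroids = [
        _weighted_centroid(labels.positions[grp], labels.power[grp])
        for grp in np.array_split(rest, len(rest) // 4)
    ]
    centroids = np.asarray(centroids)

    # snap to the nearest point of the first-pass boundary
    bpts = first_pass.boundary
    d2 = np.sum((centroids[:, None, :] - bpts[None, :, :]) ** 2, axis=2)
    snapped = bpts[np.argmin(d2, axis=1)]

    # outlier removal: mean distance to the 4 nearest peers
    keep = np.ones(len(snapped), dtype=bool)
    if len(snapped) > 4:
        dd = np.sqrt(
            np.sum((snapped[:, None, :] - snapped[None, :, :]) ** 2, axis=2)
        )
        np.fill_diagonal(dd, np.inf)
        mean4 = np.sort(dd, axis=1)[:, :4].mean(axis=1)
        keep = mean4 <= outlier_distance
    survivors = snapped[keep]
    if survivors.shape[0] == 0:
        fp = BoundaryEstimate(
            boundary=first_pass.boundary,
            grid_x=first_pass.grid_x,
            grid_y=first_pass.grid_y,
            decision=first_pass.decision,
            hillock_estimate=hillock,
            warnings=notes + ["all candidate points removed; first pass returned"],
        )
        return fp

    # weighted least-squares line through survivors + strongly-weighted hillock
    pts = np.vstack([survivors, hillock])
    wts = np.concatenate([np.ones(len(survivors)), [hillock_weight]])
    mean = _weighted_centroid(pts, wts)
    cov = ((pts - mean) * wts[:, None]).T @ (pts - mean) / wts.sum()
    axis = np.linalg.eigh(cov)[1][:, -1]  # principal direction

    # orient the axis from the hillock toward the survivors' centroid
    toward = survivors.mean(axis=0) - hillock
    if np.dot(axis, toward) < 0:
        axis = -axis
    cut_point = hillock - cut_offset * axis

    ahead = (labels.positions - cut_point) @ axis >= 0.0
    excluded = ~ahead
    sub = PolarityLabels(
        positions=labels.positions[ahead],
        labels=labels.labels[ahead],
        power=labels.power[ahead],
    )
    # evaluate the second pass over the full array extent so the
    # boundary is not truncated at the exclusion cut
    full_bounds = (
        (labels.positions[:, 0].min(), labels.positions[:, 0].max()),
        (labels.positions[:, 1].min(), labels.positions[:, 1].max()),
    )
    try:
        second = gnbe(sub, kernel_scale, regularization, grid_bounds=full_bounds)
    except NoBoundaryError:
        notes.append("single polarity after exclusion; first pass returned")
        return BoundaryEstimate(
            boundary=first_pass.boundary,
            grid_x=first_pass.grid_x,
            grid_y=first_pass.grid_y,
            decision=first_pass.decision,
            excluded_sensor_mask=excluded,
            hillock_estimate=hillock,
            warnings=notes,
        )
    second.excluded_sensor_mask = excluded
    second.hillock_estimate = hillock
    second.warnings = notes
    return second


def reconstruction_error(
    b: BoundaryEstimate,
    truth: Morphology,
    process_filter: str = "axon",
):
    """Mean distance from dominant-process segment midpoints to the boundary.

    Midpoints are projected to the sensor plane; the distance to the
    boundary is the minimum Euclidean distance to its sampled points.
    Returns ``(mean_error, path_distances, per_segment_errors)`` where
    the path distance is measured from the soma along the tree.
    """
    if b.boundary.size == 0:
        raise InvalidParameterError("empty boundary")
    sel = [
        i
        for i, s in enumerate(truth.segments)
        if process_filter in (None, "all") or s.label == process_filter
    ]
    if not sel:
        raise InvalidParameterError(f"no segments with label {process_filter!r}")

    parents = truth.parents
    lengths = truth.lengths
    path = np.zeros(len(truth))
    for i in range(len(truth)):
        p = parents[i]
        path[i] = (path[p] if p >= 0 else 0.0) + lengths[i]

    mids = truth.midpoints[sel][:, :2]
    d = np.sqrt(
        np.min(
            np.sum((mids[:, None, :] - b.boundary[None, :, :]) ** 2, axis=2),
            axis=1,
        )
    )
    # path distance to the midpoint = distance to segment end minus half length
    mid_path = path[sel] - 0.5 * lengths[sel]
    return float(d.mean()), mid_path, d


def add_template_noise(
    t: SpikeTemplate, snr_db: float, seed: Optional[int] = None
) -> SpikeTemplate:
    """Add white Gaussian noise at a target array-wide average SNR.

    Noise power is the template's mean signal power divided by
    ``10^(snr_db/10)``.  Infinite SNR returns the template unchanged.
    """
    if np.isinf(snr_db):
        return SpikeTemplate(
            t.values.copy(), t.sensors, t.dt, t.signal_type, t.cell_id
        )
    rng = np.random.default_rng(seed)
    noise_power = t.mean_power() / (10.0 ** (snr_db / 10.0))
    noisy = t.values + rng.normal(0.0, np.sqrt(noise_power), size=t.values.shape)
    return SpikeTemplate(noisy, t.sensors, t.dt, t.signal_type, t.cell_id)


def plot_overlay(b: BoundaryEstimate, truth: Morphology, path=None):
    """Simple overlay of the estimated boundary on the true morphology."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for s in truth.segments:
        ax.plot([s.start[0], s.end[0]], [s.start[1], s.end[1]], "k-", lw=1)
    ax.plot(b.boundary[:, 0], b.boundary[:, 1], "r-", lw=1.5, label="boundary")
    if b.hillock_estimate is not None:
        ax.plot(*b.hillock_estimate, "b*", ms=10, label="hillock")
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.legend()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
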