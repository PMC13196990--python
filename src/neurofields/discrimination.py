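"""Channel-matrix separability of neuron populations.

Flattened spike templates of N_C cells are stacked as columns of a
channel matrix; the ratio of its extreme singular values (condition
number) quantifies how well simultaneously active sources can be
separated.  A bootstrap over repeated populations estimates the largest
population an array supports at a given conditioning threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from neurofields.errors import InvalidParameterError
from neurofields.recordings import modality_scale_factors
from neurofields.templates import SpikeTemplate

#: sentinel returned when sigma_min is numerically zero
INF_CONDITION = np.inf


@dataclass
class ChannelMatrix:
    matrix: np.ndarray  # (rows, N_C)
    cell_ids: list
    modalities: list

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]


def build_channel_matrix(
    templates: Sequence[Mapping[str, SpikeTemplate]],
    modalities: Sequence[str],
) -> ChannelMatrix:
    """Stack flattened per-cell templates as columns.

    ``templates[i]`` maps modality -> template for cell i.  Modality
    blocks are power-normalized (phi as reference when present, magnetic
    components sharing a common factor) before stacking, then each cell's
    blocks are concatenated into one column.
    """
    if not templates:
        raise InvalidParameterError("need at least one cell")
    for i, per_mod in enumerate(templates):
        raw = np.concatenate([per_mod[mod].values.ravel() for mod in modalities])
        if not np.any(raw):
            cid = per_mod[modalities[0]].cell_id
            raise InvalidParameterError(
                f"all-zero template for cell {cid if cid is not None else i}"
            )
    pooled = {
        mod: np.concatenate([t[mod].values.ravel() for t in templates])
        for mod in modalities
    }
    factors = modality_scale_factors(pooled)

    columns = []
    cell_ids = []
    for i, per_mod in enumerate(templates):
        blocks = []
        for mod in modalities:
            vals = per_mod[mod].values.ravel()
            blocks.append(factors[mod] * vals)
        col = np.concatenate(blocks)
        if not np.any(col):
            cid = per_mod[modalities[0]].cell_id
            raise InvalidParameterError(
                f"all-zero template for cell {cid if cid is not None else i}"
            )
        columns.append(col)
        cell_ids.append(per_mod[modalities[0]].cell_id)
    return ChannelMatrix(np.column_stack(columns), cell_ids, list(modalities))


def condition_number(cm) -> float:
    """sigma_max / sigma_min of the channel matrix.

    Returns infinity when the smallest singular value is below
    1e-12 of the largest.  Matrices with more columns than rows are
    rejected (underdetermined source separation).
    """
    matrix = cm.matrix if isinstance(cm, ChannelMatrix) else np.asarray(cm, float)
    if matrix.shape[1] > matrix.shape[0]:
        raise InvalidParameterError("more columns (cells) than rows (samples)")
    s = np.linalg.svd(matrix, compute_uv=False)
    if s[-1] < 1e-12 * s[0]:
        return INF_CONDITION
    return float(s[0] / s[-1])


def capacity_estimate(
    samples: Mapping[int, Iterable[float]],
    threshold: float,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> int:
    """Largest supported population at a -log10(condition) threshold.

    For each bootstrap replicate the per-population condition samples are
    resampled with replacement, the mean -log10(condition) curve is
    linearly interpolated across population sizes, and the largest
    integer N_C where the curve still meets ``threshold`` is recorded.
    Returns the median across replicates (0 when the threshold is never
    reached).  Deterministic given ``seed``.
    """
    sizes = sorted(samples)
    if len(sizes) < 2:
        raise InvalidParameterError("need at least 2 distinct population sizes")
    data: Dict[int, np.ndarray] = {}
    for n_c in sizes:
        arr = np.asarray(list(samples[n_c]), dtype=float)
        if arr.size < 5:
            raise InvalidParameterError(
                f"need at least 5 condition samples per size, got {arr.size} at {n_c}"
            )
        data[n_c] = arr

    rng = np.random.default_rng(seed)
    grid = np.arange(sizes[0], sizes[-1] + 1)
    results = np.zeros(n_boot, dtype=int)
    for b in range(n_boot):
        means = []
        for n_c in sizes:
            arr = data[n_c]
            boot = arr[rng.integers(0, arr.size, arr.size)]
            with np.errstate(divide="ignore"):
                means.append(np.mean(-np.log10(boot)))
        curve = np.interp(grid, sizes, means)
        ok = np.nonzero(curve >= threshold)[0]
        results[b] = int(grid[ok[-1]]) if ok.size else 0
    return int(np.median(results))


def population_condition_samples(
    make_population,
    modalities: Sequence[str],
    n_reps: int,
    seed: Optional[int] = None,
) -> List[float]:
    """Condition numbers over repeated random populations.

    ``make_population(rng)`` must return the per-cell template mapping
    accepted by :func:`build_channel_matrix`.  Convenience driver for the
    ordering experiments.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        templates = make_population(rng)
        out.append(condition_number(build_channel_matrix(templates, modalities)))
    return out
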