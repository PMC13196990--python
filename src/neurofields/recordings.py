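"""Ground-truthed multimodal recording synthesis and train matching.

Recordings are assembled by pasting spike templates at Poisson spike
times, equalizing average signal power across modalities (voltage is
the reference and is never rescaled), and adding white Gaussian noise.
Spike-train agreement between a sorter's output and the ground truth is
scored with the accuracy formula TP / (TP + FP + FN) after greedy
one-to-one unit pairing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from neurofields.errors import InvalidParameterError

BOLTZMANN = 1.380649e-23  # J/K

#: modality groups for power normalization: phi is the immutable
#: reference; all magnetic components share one scale factor.
MAGNETIC = ("Bx", "By", "Bz")


@dataclass
class SpikeTrainSet:
    """Sorted spike times per cell (seconds)."""

    trains: List[np.ndarray]
    duration: float
    rates: Optional[np.ndarray] = None
    refractory: float = 2.0  # ms
    seed: Optional[int] = None

    def __post_init__(self):
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        gap = self.refractory * 1e-3
        for i, t in enumerate(self.trains):
            if np.any(np.diff(t) < gap - 1e-12):
                raise InvalidParameterError(f"train {i} violates the refractory gap")

    @property
    def n_cells(self) -> int:
        return len(self.trains)


def poisson_trains(
    n_cells: int,
    duration: float,
    rate_mean: float = 5.0,
    rate_sd: float = 1.0,
    refractory: float = 2.0,
    seed: Optional[int] = None,
    rate_floor: float = 0.1,
) -> SpikeTrainSet:
    """Homogeneous Poisson trains with refractory deletion.

    Each cell's rate is drawn from Normal(rate_mean, rate_sd), truncated
    below at ``rate_floor`` Hz.  Spikes closer than ``refractory`` ms to
    the previously kept spike are deleted (the earlier spike wins).
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    rng = np.random.default_rng(seed)
    rates = np.maximum(rng.normal(rate_mean, rate_sd, size=n_cells), rate_floor)
    gap = refractory * 1e-3
    trains = []
    for rate in rates:
        n_exp = rng.poisson(rate * duration)
        times = np.sort(rng.uniform(0.0, duration, size=n_exp))
        kept = []
        last = -np.inf
        for t in times:
            if t - last >= gap:
                kept.append(t)
                last = t
        trains.append(np.asarray(kept))
    return SpikeTrainSet(trains, duration, rates, refractory, seed)


@dataclass
class Recording:
    data: np.ndarray  # (channels, samples)
    sampling_rate: float  # Hz
    channel_modalities: List[str]
    truth: SpikeTrainSet
    scale_factors: Dict[str, float]
    noise_rms: float
    clipped_spikes: int = 0
    channel_positions: Optional[np.ndarray] = None
    seed: Optional[int] = None
    log: list = field(default_factory=list)

    def export_binary(self, data_path, probe_path) -> None:
        """Flat float32 binary (channel-major) plus a JSON probe map."""
        self.data.astype(np.float32).tofile(data_path)
        doc = {
            "dtype": "float32",
            "order": "channel_major",
            "n_channels": self.data.shape[0],
            "n_samples": self.data.shape[1],
            "sampling_rate": self.sampling_rate,
            "channels": [
                {
                    "channel": i,
                    "modality": self.channel_modalities[i],
                    "position": self.channel_positions[i].tolist()
                    if self.channel_positions is not None
                    else None,
                }
                for i in range(self.data.shape[0])
            ],
        }
        with open(probe_path, "w") as fh:
            json.dump(doc, fh, indent=1)


def modality_scale_factors(power_sources: Mapping[str, np.ndarray]) -> Dict[str, float]:
    """Scale factors that equalize average signal power across modalities.

    The voltage modality (``phi``) is the reference and keeps factor 1.
    All magnetic components receive one common factor chosen so the
    highest-power magnetic component matches the reference power,
    preserving the relative magnitudes of Bx:By:Bz.  Without ``phi`` the
    magnetic components are left untouched (they already share units).
    """
    powers = {}
    for mod, arr in power_sources.items():
        p = float(np.mean(np.square(np.asarray(arr, dtype=float))))
        if p == 0.0:
            raise InvalidParameterError(f"zero-power modality {mod!r}")
        powers[mod] = p

    factors = {mod: 1.0 for mod in powers}
    mags = [m for m in powers if m in MAGNETIC]
    if "phi" in powers and mags:
        p_max = max(powers[m] for m in mags)
        common = float(np.sqrt(powers["phi"] / p_max))
        for m in mags:
            factors[m] = common
    return factors


def normalize_modal_power(arrays: Mapping[str, np.ndarray]):
    """Rescale per-modality arrays to equal average power.

    Returns ``(scaled, factors)``; see :func:`modality_scale_factors`
    for the rules.  Idempotent.
    """
    factors = modality_scale_factors(arrays)
    scaled = {
        mod: factors[mod] * np.asarray(arr, dtype=float)
        for mod, arr in arrays.items()
    }
    return scaled, factors


def assemble_recording(
    templates: Sequence[Mapping[str, "SpikeTemplate"]],
    trains: SpikeTrainSet,
    noise_rms: float,
    seed: Optional[int] = None,
    normalize: bool = True,
) -> Recording:
    """Paste templates at spike times, equalize modal power, add noise.

    ``templates[i]`` maps modality -> SpikeTemplate for cell i; all
    templates must share dt.  Channels are grouped per modality block in
    the order of the first cell's mapping.  Spikes whose template does
    not fit before the end of the recording are truncated and counted.
    """
    if len(templates) != trains.n_cells:
        raise InvalidParameterError("one template mapping per cell required")
    modalities = list(templates[0].keys())
    dts = {t[m].dt for t in templates for m in modalities}
    if len(dts) != 1:
        raise InvalidParameterError("all templates must share dt")
    dt_ms = dts.pop()
    fs = 1000.0 / dt_ms
    n_samples = int(round(trains.duration * fs))

    if normalize:
        pooled = {
            mod: np.concatenate([t[mod].values.ravel() for t in templates])
            for mod in modalities
        }
        factors = modality_scale_factors(pooled)
    else:
        factors = {mod: 1.0 for mod in modalities}

    blocks = []
    channel_modalities: List[str] = []
    positions = []
    clipped = 0
    for mod in modalities:
        n_sensors = templates[0][mod].sensors.n_sensors
        block = np.zeros((n_sensors, n_samples))
        for cell, per_mod in enumerate(templates):
            tpl = factors[mod] * per_mod[mod].values
            width = tpl.shape[1]
            for t_spike in trains.trains[cell]:
                start = int(round(t_spike * fs))
                if start >= n_samples:
                    clipped += 1
                    continue
                stop = min(start + width, n_samples)
                if stop - start < width:
                    clipped += 1
                block[:, start:stop] += tpl[:, : stop - start]
        blocks.append(block)
        channel_modalities.extend([mod] * n_sensors)
        positions.append(templates[0][mod].sensors.positions)

    data = np.vstack(blocks)
    rng = np.random.default_rng(seed)
    if noise_rms > 0:
        data = data + rng.normal(0.0, noise_rms, size=data.shape)
    return Recording(
        data=data,
        sampling_rate=fs,
        channel_modalities=channel_modalities,
        truth=trains,
        scale_factors=factors,
        noise_rms=noise_rms,
        clipped_spikes=clipped,
        channel_positions=np.vstack(positions),
        seed=seed,
    )


def thermal_noise_rms(resistance: float, bandwidth: float, temperature: float = 300.0) -> float:
    """Johnson noise RMS voltage: sqrt(4 k_B T R B)."""
    if resistance < 0 or bandwidth < 0 or temperature < 0:
        raise InvalidParameterError("arguments must be >= 0")
    return float(np.sqrt(4.0 * BOLTZMANN * temperature * resistance * bandwidth))


def rescale_noise_bandwidth(rms: float, band_from: float, band_to: float) -> float:
    """White-noise RMS rescaling: rms * sqrt(band_to / band_from)."""
    if band_from <= 0:
        raise InvalidParameterError("band_from must be > 0")
    return float(rms * np.sqrt(band_to / band_from))


@dataclass
class UnitMatch:
    predicted: int
    truth: int
    tp: int
    fp: int
    fn: int

    @property
    def accuracy(self) -> float:
        denom = self.tp + self.fp + self.fn
        return self.tp / denom if denom else 0.0


@dataclass
class MatchResult:
    pairs: List[UnitMatch]
    overall_accuracy: float
    well_detected: int


def _count_matches(a: np.ndarray, b: np.ndarray, tol_s: float) -> int:
    """One-to-one matched-spike count between two sorted trains."""
    i = j = hits = 0
    while i < a.size and j < b.size:
        d = a[i] - b[j]
        if abs(d) <= tol_s:
            hits += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return hits


def match_spike_trains(
    predicted: SpikeTrainSet, truth: SpikeTrainSet, tolerance: float = 1.0
) -> MatchResult:
    """Greedy one-to-one unit pairing maximizing matched-spike counts.

    ``tolerance`` is in ms.  Per-pair accuracy is TP / (TP + FP + FN);
    units with accuracy > 0.8 are well-detected.  Unpaired predicted
    units count as pure false positives and unpaired truth units as pure
    false negatives in the pooled overall accuracy.
    """
    if tolerance <= 0:
        raise InvalidParameterError("tolerance must be > 0")
    tol_s = tolerance * 1e-3
    counts = np.zeros((predicted.n_cells, truth.n_cells), dtype=int)
    for p in range(predicted.n_cells):
        for q in range(truth.n_cells):
            counts[p, q] = _count_matches(
                predicted.trains[p], truth.trains[q], tol_s
            )

    pairs: List[UnitMatch] = []
    used_p: set = set()
    used_q: set = set()
    order = np.dstack(np.unravel_index(np.argsort(-counts, axis=None), counts.shape))[0]
    for p, q in order:
        if p in used_p or q in used_q or counts[p, q] == 0:
            continue
        used_p.add(p)
        used_q.add(q)
        tp = int(counts[p, q])
        pairs.append(
            UnitMatch(
                predicted=int(p),
                truth=int(q),
                tp=tp,
                fp=int(predicted.trains[p].size - tp),
                fn=int(truth.trains[q].size - tp),
            )
        )

    total_tp = sum(m.tp for m in pairs)
    total_fp = sum(m.fp for m in pairs) + sum(
        predicted.trains[p].size for p in range(predicted.n_cells) if p not in used_p
    )
    total_fn = sum(m.fn for m in pairs) + sum(
        truth.trains[q].size for q in range(truth.n_cells) if q not in used_q
    )
    denom = total_tp + total_fp + total_fn
    overall = total_tp / denom if denom else 0.0
    well = sum(1 for m in pairs if m.accuracy > 0.8)
    return MatchResult(pairs=pairs, overall_accuracy=overall, well_detected=well)
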