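"""Sequence extraction and timing statistics for rate and spiking simulations.

All operations here are pure functions of their inputs: they take recorded
trajectories (unit activities or spike rasters) and return discrete event
sequences, switch-time statistics, dynamic-range ratios, and scores of
learned weight structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SequenceTrace",
    "active_unit_trace",
    "measure_switch_times",
    "dynamic_range",
    "weight_structure_score",
    "sequence_from_spikes",
    "cluster_average_weights",
]


@dataclass(frozen=True)
class SequenceTrace:
    """Discrete record of which unit (or cluster) was active, and when.

    Attributes
    ----------
    onsets : array of event onset times, strictly increasing.
    units : array of active unit/cluster ids, one per event.
    dwells : array of event durations (> 0).
    """

    onsets: np.ndarray
    units: np.ndarray
    dwells: np.ndarray

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=float)
        units = np.asarray(self.units, dtype=int)
        dwells = np.asarray(self.dwells, dtype=float)
        if not (len(onsets) == len(units) == len(dwells)):
            raise ValueError("onsets, units and dwells must have equal length")
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        if np.any(dwells <= 0):
            raise ValueError("dwell durations must be positive")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "units", units)
        object.__setattr__(self, "dwells", dwells)

    @property
    def events(self) -> list[tuple[float, int, float]]:
        """Events as (onset time, unit id, dwell duration) tuples."""
        return list(zip(self.onsets.tolist(), self.units.tolist(), self.dwells.tolist()))

    @property
    def order(self) -> list[int]:
        """Realized sequence of active unit ids."""
        return self.units.tolist()

    @property
    def switch_times(self) -> np.ndarray:
        """Intervals between successive event onsets."""
        return np.diff(self.onsets)

    def __len__(self) -> int:
        return len(self.onsets)

    def cycle_order(self) -> list[int]:
        """Unit ids of one cycle: the longest run before any unit repeats."""
        seen: list[int] = []
        for u in self.units.tolist():
            if u in seen:
                break
            seen.append(u)
        return seen


def _merge_labels(times: np.ndarray, labels: np.ndarray) -> SequenceTrace:
    """Run-length encode a per-sample label array (-1 = no active unit)."""
    onsets, units, dwells = [], [], []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            if labels[start] >= 0:
                t0 = times[start]
                t1 = times[i] if i < len(labels) else times[-1]
                if t1 > t0:
                    onsets.append(t0)
                    units.append(int(labels[start]))
                    dwells.append(t1 - t0)
            start = i
    return SequenceTrace(np.array(onsets), np.array(units, dtype=int), np.array(dwells))


def active_unit_trace(times: np.ndarray, x: np.ndarray, threshold: float = 0.5) -> SequenceTrace:
    """Extract the sequence of active units from an activity trajectory.

    The active unit at each sample is the argmax of ``x`` provided the
    maximum exceeds ``threshold``; otherwise no unit is considered active.
    Ties are broken toward the lowest index.  Consecutive samples with the
    same active unit are merged into single events.

    Parameters
    ----------
    times : (T,) sample times.
    x : (T, N) unit activities.
    threshold : activity level a unit must exceed to count as active.
    """
    times = np.asarray(times, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.size == 0 or len(times) == 0:
        raise ValueError("empty trajectory")
    if x.ndim != 2 or x.shape[0] != len(times):
        raise ValueError("x must be (n_samples, n_units) matching times")
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    winners = np.argmax(x, axis=1)
    peak = x[np.arange(len(times)), winners]
    labels = np.where(peak > threshold, winners, -1)
    return _merge_labels(times, labels)


def measure_switch_times(trace: SequenceTrace) -> tuple[float, np.ndarray]:
    """Mean and per-event unit-to-unit switch intervals.

    Intervals are differences between successive event onsets.  The first
    interval is excluded from the mean as an initial-condition transient
    (it is still returned in the per-event list).
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 events to measure switch times")
    intervals = trace.switch_times
    mean = float(intervals[1:].mean()) if len(intervals) > 1 else float(intervals.mean())
    return mean, intervals


def dynamic_range(period_by_input: Mapping[float, float]) -> float:
    """Ratio of slowest to fastest sequence period across input levels.

    Entries with non-finite or non-positive periods (levels at which no
    valid sequence was obtained) are ignored; at least two valid levels
    are required.
    """
    periods = np.array([p for p in period_by_input.values() if p is not None], dtype=float)
    periods = periods[np.isfinite(periods) & (periods > 0)]
    if len(periods) < 2:
        raise ValueError("need at least two input levels with valid sequences")
    return float(periods.max() / periods.min())


def weight_structure_score(
    W: np.ndarray, reference_order: Sequence[int], cyclic: bool = True
) -> tuple[float, dict[int, int]]:
    """Score how well a weight matrix encodes a reference sequence.

    For each unit j in the reference order the predicted successor is the
    row index of the least-negative off-diagonal entry of column j (the
    unit that receives the weakest inhibition from j).  Accuracy is the
    fraction of units whose predicted successor matches the reference.

    Returns (accuracy, per-column predicted successor map).
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.ndim != 2 or W.shape[1] != n:
        raise ValueError("W must be square")
    order = list(reference_order)
    if any(not 0 <= j < n for j in order):
        raise ValueError("reference order contains unknown unit ids")
    if len(set(order)) != len(order):
        raise ValueError("reference order must not repeat units")
    pairs = list(zip(order[:-1], order[1:]))
    if cyclic and len(order) > 1:
        pairs.append((order[-1], order[0]))
    if not pairs:
        raise ValueError("reference order must contain at least 2 units")
    successor_map: dict[int, int] = {}
    hits = 0
    for j, true_succ in pairs:
        col = W[:, j].copy()
        col[j] = -np.inf
        pred = int(np.argmax(col))
        successor_map[j] = pred
        hits += pred == true_succ
    return hits / len(pairs), successor_map


def sequence_from_spikes(
    spike_times: np.ndarray,
    spike_neurons: np.ndarray,
    membership: np.ndarray,
    bin_width: float = 20.0,
    min_rate: float = 5.0,
    t_start: float | None = None,
    t_stop: float | None = None,
) -> SequenceTrace:
    """Cluster-level activity sequence from a spike raster.

    Per time bin, the winning cluster is the one with the highest
    population firing rate, provided that rate exceeds ``min_rate`` (Hz);
    bins below the floor have no active cluster.  Consecutive bins with
    the same winner are merged into events.

    Parameters
    ----------
    spike_times : spike times in ms.
    spike_neurons : neuron id per spike.
    membership : (n_neurons,) cluster id per neuron.
    bin_width : bin width in ms.
    min_rate : minimum population rate (Hz, per neuron) for a cluster to
        count as active.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    spike_neurons = np.asarray(spike_neurons, dtype=int)
    membership = np.asarray(membership, dtype=int)
    if len(spike_times) == 0:
        raise ValueError("empty spike raster")
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    n_clusters = int(membership.max()) + 1
    sizes = np.bincount(membership, minlength=n_clusters)
    t0 = float(spike_times.min()) if t_start is None else t_start
    t1 = float(spike_times.max()) if t_stop is None else t_stop
    n_bins = max(1, int(np.ceil((t1 - t0) / bin_width)))
    edges = t0 + bin_width * np.arange(n_bins + 1)
    cluster_of_spike = membership[spike_neurons]
    counts, _, _ = np.histogram2d(
        spike_times, cluster_of_spike, bins=[edges, np.arange(n_clusters + 1) - 0.5]
    )
    # population rate in Hz per neuron of the cluster
    rates = counts / np.maximum(sizes, 1) / (bin_width / 1000.0)
    winners = np.argmax(rates, axis=1)
    peak = rates[np.arange(n_bins), winners]
    labels = np.where(peak >= min_rate, winners, -1)
    bin_times = np.append(edges[:-1], edges[-1])
    return _merge_labels(bin_times, labels.astype(int))


def cluster_average_weights(
    W: np.ndarray, membership: np.ndarray, connectivity: np.ndarray | None = None
) -> np.ndarray:
    """Cluster-averaged weight matrix.

    Entry (a, b) is the mean weight over existing synapses from cluster b
    onto cluster a.  If ``connectivity`` is omitted every off-diagonal
    neuron pair is treated as a synapse.  Blocks with no synapses are
    reported as NaN.
    """
    W = np.asarray(W, dtype=float)
    membership = np.asarray(membership, dtype=int)
    n = W.shape[0]
    if len(membership) != n:
        raise ValueError("membership must cover all neurons")
    if connectivity is None:
        connectivity = ~np.eye(n, dtype=bool)
    n_clusters = int(membership.max()) + 1
    out = np.full((n_clusters, n_clusters), np.nan)
    for a in range(n_clusters):
        rows = membership == a
        for b in range(n_clusters):
            cols = membership == b
            mask = connectivity[np.ix_(rows, cols)]
            if mask.any():
                out[a, b] = W[np.ix_(rows, cols)][mask].mean()
    return out
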