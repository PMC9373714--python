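"""Spike, burst and current-peak statistics on recorded traces.

Conventions (config-exposed where the underlying experimental papers leave
them open):

* spikes are upward crossings of a 0 mV threshold with a 2 ms lockout;
* a burst opens when an inter-spike interval (ISI) is <= 40 ms, extends
  while ISIs stay <= 100 ms, closes at the first ISI > 100 ms, and must
  contain at least two spikes;
* the outlier filter keeps values between the 25th and 75th percentiles
  (linear-interpolation percentile definition), inclusive;
* "mean peak potential" is the mean of the local voltage maxima within
  +/- 2 ms of each spike (translation-equivariant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _stats

from .errors import AlignmentError, RangeError

__all__ = [
    "SpikeTrain",
    "BurstSet",
    "PeakStats",
    "detect_spikes",
    "detect_bursts",
    "firing_rate",
    "mean_membrane_potential",
    "mean_peak_potential",
    "peak_stats",
    "iqr_filter",
    "rate_da_regression",
    "current_voltage_correlation",
]

BURST_ONSET_ISI_MS = 40.0
BURST_CONTINUE_ISI_MS = 100.0
PEAK_WINDOW_MS = 2.0
REFRACTORY_MS = 2.0


@dataclass
class SpikeTrain:
    neuron_id: int
    times: np.ndarray          # ms, strictly increasing
    threshold: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or (t.size > 1 and not np.all(np.diff(t) > 0)):
            raise AlignmentError("spike times must be a strictly increasing 1-D array")
        self.times = t

    def __len__(self):
        return self.times.size


@dataclass
class BurstSet:
    """Bursts as (start, end) index pairs into the spike train (inclusive)."""

    bursts: List[Tuple[int, int]]
    onset_isi: float = BURST_ONSET_ISI_MS
    continue_isi: float = BURST_CONTINUE_ISI_MS

    @property
    def count(self) -> int:
        return len(self.bursts)

    def spike_counts(self) -> List[int]:
        return [end - start + 1 for start, end in self.bursts]


@dataclass
class PeakStats:
    peak_frequency: float          # events/s
    mean_peak_amplitude: float     # current units; nan when no events


def detect_spikes(v_trace: np.ndarray, dt_ms: float, threshold: float = 0.0,
                  refractory_ms: float = REFRACTORY_MS,
                  neuron_id: int = 0) -> SpikeTrain:
    """Upward threshold crossings with a refractory lockout."""
    v = np.asarray(v_trace, dtype=float)
    crossings = np.where((v[:-1] < threshold) & (v[1:] >= threshold))[0] + 1
    lockout = max(1, int(round(refractory_ms / dt_ms)))
    kept = []
    last = -lockout - 1
    for idx in crossings:
        if idx - last > lockout:
            kept.append(idx)
            last = idx
    return SpikeTrain(neuron_id=neuron_id,
                      times=np.asarray(kept, dtype=float) * dt_ms,
                      threshold=threshold)


def detect_bursts(train: SpikeTrain,
                  onset_isi: float = BURST_ONSET_ISI_MS,
                  continue_isi: float = BURST_CONTINUE_ISI_MS) -> BurstSet:
    """Scan ISIs with the 40 ms open / 100 ms close rule (>= 2 spikes)."""
    t = train.times
    bursts: List[Tuple[int, int]] = []
    i = 0
    n = t.size
    while i < n - 1:
        if t[i + 1] - t[i] <= onset_isi:
            start = i
            j = i + 1
            while j < n - 1 and t[j + 1] - t[j] <= continue_isi:
                j += 1
            bursts.append((start, j))
            i = j + 1
        else:
            i += 1
    return BurstSet(bursts=bursts, onset_isi=onset_isi, continue_isi=continue_isi)


def firing_rate(train: SpikeTrain, window: Tuple[float, float]) -> float:
    """Spike count inside ``window`` (ms) divided by its duration, in Hz."""
    t_on, t_off = window
    if t_off <= t_on:
        raise RangeError("analysis window must have positive duration")
    n = int(np.sum((train.times >= t_on) & (train.times <= t_off)))
    return n / ((t_off - t_on) / 1000.0)


def mean_membrane_potential(v_trace: np.ndarray) -> float:
    """Arithmetic mean of the membrane potential over the whole trace."""
    return float(np.mean(np.asarray(v_trace, dtype=float)))


def mean_peak_potential(v_trace: np.ndarray, train: SpikeTrain,
                        dt_ms: float, window_ms: float = PEAK_WINDOW_MS) -> float:
    """Mean of per-spike local voltage maxima (nan for an empty train)."""
    if len(train) == 0:
        return math.nan
    v = np.asarray(v_trace, dtype=float)
    half = max(1, int(round(window_ms / dt_ms)))
    peaks = []
    for t in train.times:
        i = int(round(t / dt_ms))
        lo, hi = max(0, i - half), min(v.size, i + half + 1)
        peaks.append(np.max(v[lo:hi]))
    return float(np.mean(peaks))


def peak_stats(current_trace: np.ndarray, train: SpikeTrain, dt_ms: float,
               duration_ms: Optional[float] = None,
               window_ms: float = PEAK_WINDOW_MS) -> PeakStats:
    """Spike-aligned current extrema: peak frequency and mean |amplitude|.

    Each spike contributes the extremum (largest |I|) of the current within
    +/- ``window_ms`` of the spike time; the peak frequency equals the
    spike frequency by construction.
    """
    i_trace = np.asarray(current_trace, dtype=float)
    if duration_ms is None:
        duration_ms = i_trace.size * dt_ms
    if len(train) == 0:
        return PeakStats(peak_frequency=0.0, mean_peak_amplitude=math.nan)
    half = max(1, int(round(window_ms / dt_ms)))
    amps = []
    for t in train.times:
        i = int(round(t / dt_ms))
        lo, hi = max(0, i - half), min(i_trace.size, i + half + 1)
        seg = i_trace[lo:hi]
        amps.append(np.abs(seg).max())
    freq = len(train) / (duration_ms / 1000.0)
    return PeakStats(peak_frequency=freq, mean_peak_amplitude=float(np.mean(amps)))


def iqr_filter(values: Sequence[float]) -> np.ndarray:
    """Keep values within the inclusive [25th, 75th] percentile band.

    Percentiles use linear interpolation; order of survivors is preserved.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise RangeError("interquartile filter needs at least 4 values")
    q25, q75 = np.percentile(v, [25.0, 75.0])
    return v[(v >= q25) & (v <= q75)]


def rate_da_regression(da_ratio: Sequence[float],
                       rate: Sequence[float]) -> Tuple[float, float, float]:
    """OLS of firing rate on dopamine ratio: (slope, intercept, Pearson r)."""
    x = np.asarray(da_ratio, dtype=float)
    y = np.asarray(rate, dtype=float)
    if x.size != y.size:
        raise AlignmentError("da_ratio and rate must have equal length")
    if x.size < 3:
        raise RangeError("regression needs at least 3 pairs")
    if np.ptp(x) == 0:
        raise RangeError("degenerate regression: dopamine ratios have zero variance")
    res = _stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def current_voltage_correlation(current_trace: np.ndarray,
                                v_trace: np.ndarray,
                                window: Optional[Tuple[float, float]] = None,
                                dt_ms: Optional[float] = None) -> float:
    """Pearson correlation between a synaptic current and the membrane potential.

    Returns nan when either trace has zero variance.  ``window`` (ms)
    restricts the analysis span and requires ``dt_ms``.
    """
    i_t = np.asarray(current_trace, dtype=float)
    v_t = np.asarray(v_trace, dtype=float)
    if i_t.shape != v_t.shape:
        raise AlignmentError("traces must share the time grid")
    if window is not None:
        if dt_ms is None:
            raise RangeError("window requires dt_ms")
        lo = int(round(window[0] / dt_ms))
        hi = int(round(window[1] / dt_ms)) + 1
        i_t, v_t = i_t[lo:hi], v_t[lo:hi]
    if np.std(i_t) == 0 or np.std(v_t) == 0:
        return math.nan
    return float(np.corrcoef(i_t, v_t)[0, 1])
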