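"""Respiratory surrogate traces, inhalation-peak editing, and phase computation.

Retrospective phase-based 4D CT sorting assigns each cine image a
respiratory phase in [0, 100) derived from the surrogate trace: phase is 0%
at each inhalation peak and grows linearly in time to 100% at the next
peak.  Missed or spuriously detected inhalation peaks therefore corrupt
the phase of every sample in the cycles they bound — the failure mode this
package's comparison metric is designed to detect — and editing the peak
set (inserting missed peaks, deleting spurious ones) and recomputing the
phase reproduces the clinical "phase recalculation" workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .errors import PeakDetectionError, PeakEditError, PhaseSpanError

__all__ = [
    "BreathingTrace",
    "PeakSet",
    "PhaseAssignment",
    "detect_peaks",
    "edit_peaks",
    "compute_phase",
]


@dataclass
class BreathingTrace:
    """A timed surrogate-amplitude trace (times in s, amplitudes in a.u.)."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if self.times.ndim != 1 or self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must be equal-length 1D arrays")
        if len(self.times) < 2:
            raise ValueError("a breathing trace needs at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("trace times must be strictly increasing")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("trace amplitudes must be finite")

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.amplitudes]),
                   delimiter=",", header="time_s,amplitude", comments="")

    @classmethod
    def from_csv(cls, path) -> "BreathingTrace":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1])


@dataclass
class PeakSet:
    """Strictly increasing inhalation-peak times (seconds)."""

    peak_times: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=np.float64)
        if self.peak_times.ndim != 1:
            raise ValueError("peak_times must be a 1D array")
        if len(self.peak_times) >= 2 and not np.all(np.diff(self.peak_times) > 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.peak_times[:, None], delimiter=",",
                   header="peak_time_s", comments="")

    @classmethod
    def from_csv(cls, path) -> "PeakSet":
        return cls(np.atleast_1d(np.loadtxt(path, delimiter=",", skiprows=1)))


def detect_peaks(
    trace: BreathingTrace, min_prominence: float, min_separation: float
) -> PeakSet:
    """Local maxima of the trace with at least the given prominence and spacing.

    ``min_separation`` is in seconds and is converted to a sample distance
    using the median sampling interval.
    """
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    dt = float(np.median(np.diff(trace.times)))
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = find_peaks(trace.amplitudes, prominence=min_prominence, distance=distance)
    if len(idx) < 2:
        raise PeakDetectionError(
            f"fewer than 2 peaks found (got {len(idx)}) with "
            f"prominence>={min_prominence}, separation>={min_separation}s"
        )
    return PeakSet(trace.times[idx])


def edit_peaks(
    peaks: PeakSet,
    insert=(),
    delete=(),
    match_tolerance: float = 0.2,
) -> PeakSet:
    """Insert and/or delete inhalation peaks, matching by nearest time.

    Each deletion must match an existing peak within ``match_tolerance``
    seconds (each peak can be consumed by only one deletion); each
    insertion must not fall within ``match_tolerance`` of a surviving or
    previously inserted peak.
    """
    remaining = list(peaks.peak_times)
    for t in delete:
        if not remaining:
            raise PeakEditError(f"unmatched deletion at t={t}: no peaks left")
        dists = [abs(p - t) for p in remaining]
        k = int(np.argmin(dists))
        if dists[k] > match_tolerance:
            raise PeakEditError(
                f"unmatched deletion at t={t}: nearest peak is {dists[k]:.3f}s away"
            )
        remaining.pop(k)
    for t in insert:
        if remaining and min(abs(p - t) for p in remaining) <= match_tolerance:
            raise PeakEditError(f"duplicate insertion at t={t}: a peak already exists nearby")
        remaining.append(float(t))
    return PeakSet(np.sort(np.asarray(remaining, dtype=np.float64)))


@dataclass
class PhaseAssignment:
    """Piecewise-linear respiratory phase derived from an inhalation-peak set.

    phase(t) = 100 * (t - p_i) / (p_{i+1} - p_i)  for t in [p_i, p_{i+1});
    defined on [first peak, last peak) only.
    """

    peaks: PeakSet

    def __post_init__(self) -> None:
        if len(self.peaks) < 2:
            raise PeakDetectionError("phase computation requires at least 2 peaks")

    @property
    def span(self) -> tuple[float, float]:
        p = self.peaks.peak_times
        return float(p[0]), float(p[-1])

    def __call__(self, t):
        p = self.peaks.peak_times
        t_arr = np.asarray(t, dtype=np.float64)
        scalar = t_arr.ndim == 0
        t_arr = np.atleast_1d(t_arr)
        if np.any(t_arr < p[0]) or np.any(t_arr >= p[-1]):
            bad = t_arr[(t_arr < p[0]) | (t_arr >= p[-1])][0]
            raise PhaseSpanError(
                f"phase undefined outside peak span [{p[0]}, {p[-1]}): t={bad}"
            )
        i = np.searchsorted(p, t_arr, side="right") - 1
        phase = 100.0 * (t_arr - p[i]) / (p[i + 1] - p[i])
        return float(phase[0]) if scalar else phase


def compute_phase(peaks: PeakSet, query_times) -> np.ndarray:
    """Respiratory phase in [0, 100) at each query time (peak-linear convention)."""
    return np.atleast_1d(PhaseAssignment(peaks)(query_times))
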