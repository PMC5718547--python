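"""Normalized correlation coefficient (NCC) between axial CT slices.

The NCC used here is the cosine similarity of the raw HU pixel values,

    C_AB = sum(a * b) / (sqrt(sum(a^2)) * sqrt(sum(b^2))),

with **no mean subtraction** — this is deliberately not the Pearson
correlation.  Identical slices give +1; the value always lies in [-1, +1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSliceError, DimensionMismatchError
from .imageset_io import AxialSlice, SortedPhaseVolume

__all__ = ["ncc", "AdjacentProfile", "adjacent_profile"]


def _pixels(a) -> np.ndarray:
    if isinstance(a, AxialSlice):
        return a.pixels
    return np.asarray(a, dtype=np.float64)


def ncc(a, b) -> float:
    """NCC between two axial slices (or bare 2D arrays) of identical shape.

    Accumulation is in double precision regardless of input dtype; the
    result is clamped to [-1, +1] against floating-point rounding.

    Raises
    ------
    DimensionMismatchError
        If the two slices differ in shape.
    DegenerateSliceError
        If either slice is identically zero (zero denominator).
    """
    pa = _pixels(a).astype(np.float64, copy=False)
    pb = _pixels(b).astype(np.float64, copy=False)
    if pa.shape != pb.shape:
        raise DimensionMismatchError(f"slice shapes differ: {pa.shape} vs {pb.shape}")
    norm_a = np.sqrt(np.sum(pa * pa))
    norm_b = np.sqrt(np.sum(pb * pb))
    if norm_a == 0.0 or norm_b == 0.0:
        raise DegenerateSliceError("degenerate slice: all pixel values are zero")
    value = float(np.sum(pa * pb) / (norm_a * norm_b))
    return float(min(1.0, max(-1.0, value)))


@dataclass
class AdjacentProfile:
    """NCC between every pair of spatially adjacent slices in one phase volume.

    ``values[m-1]`` is C_{m,m+1} for 1-based slice index m in [1, N*S - 1];
    ``transition_flags[m-1]`` is True exactly where m = S*n crosses a couch
    transition.
    """

    values: np.ndarray
    transition_flags: np.ndarray
    slices_per_couch: int
    n_couch: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.transition_flags = np.asarray(self.transition_flags, dtype=bool)
        expected = self.n_couch * self.slices_per_couch - 1
        if self.values.shape != (expected,) or self.transition_flags.shape != (expected,):
            raise ValueError(f"profile length must be N*S-1 = {expected}")

    @property
    def transition_positions(self) -> np.ndarray:
        """The 1-based slice indices m at which couch transitions occur."""
        return np.flatnonzero(self.transition_flags) + 1


def adjacent_profile(volume: SortedPhaseVolume) -> AdjacentProfile:
    """Compute C_{m,m+1} for all adjacent slice pairs of one phase volume.

    Slices are concatenated across couch blocks in spatial order; entries
    at m = S, 2S, ..., (N-1)*S are flagged as couch transitions.  Any NCC
    error is re-raised with the offending pair index m attached.
    """
    slices = list(volume.iter_slices())
    s = volume.slices_per_couch
    n = volume.n_couch
    values = np.empty(n * s - 1)
    for m in range(1, n * s):  # 1-based
        try:
            values[m - 1] = ncc(slices[m - 1], slices[m])
        except (DegenerateSliceError, DimensionMismatchError) as exc:
            raise type(exc)(f"at adjacent pair m={m}: {exc}") from exc
    flags = np.zeros(n * s - 1, dtype=bool)
    flags[s - 1 :: s] = True  # m = S, 2S, ..., (N-1)*S; m = N*S is out of range
    return AdjacentProfile(values, flags, slices_per_couch=s, n_couch=n)
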