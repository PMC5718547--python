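"""Couch-transition artifact metric and the two-set comparison score.

For each couch transition n of a sorted phase volume, three NCCs are
computed on the slice pairs straddling the transition:

    C_n      = ncc(I(n, S),   I(n+1, 1))   (the edge slices)
    C_n,n    = ncc(I(n, S-1), I(n, S))     (left intracouch neighbors)
    C_n,n+1  = ncc(I(n+1, 1), I(n+1, 2))   (right intracouch neighbors)

and combined into the transition metric

    D_b,n = (C_n,n + C_n,n+1) / 2 - C_n .

The intracouch pairs are acquired within one breathing cycle, so they set
a baseline of anatomical (non-respiratory) change; any excess drop of C_n
below that baseline flags a respiration-induced discontinuity.  Comparing
two sortings of the same cine acquisition, the element-wise residual
ΔD = D_original - D_recalculated cancels static anatomical structure and
isolates the sorting-dependent artifacts; its per-phase row-sum signs,
averaged over the B phases, give an overall comparison score in [-1, +1]
(positive: the second set has fewer or smaller artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientSlicesError, ShapeMismatchError
from .imageset_io import FourDCTImageSet, SortedPhaseVolume
from .similarity import ncc

__all__ = [
    "TransitionSimilarity",
    "ArtifactMatrix",
    "ResidualMatrix",
    "ComparisonReport",
    "transition_similarity",
    "artifact_matrix",
    "residual_matrix",
    "score",
    "compare_sets",
    "ZERO_SUM_RTOL",
]

# a phase row sum within this tolerance (scaled by N-1) counts as exactly zero
ZERO_SUM_RTOL = 1e-12


@dataclass
class TransitionSimilarity:
    """The three NCCs and the metric D at one couch transition (1-based n)."""

    couch_transition: int
    edge_ncc: float
    left_ncc: float
    right_ncc: float
    d_value: float = field(init=False)

    def __post_init__(self) -> None:
        self.d_value = 0.5 * (self.left_ncc + self.right_ncc) - self.edge_ncc


@dataclass
class ArtifactMatrix:
    """B x (N-1) matrix of D values: rows = phase bins, columns = transitions."""

    d: np.ndarray
    phase_labels: list[int]
    provenance_label: str = ""

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.d.ndim != 2:
            raise ShapeMismatchError("artifact matrix must be 2D (phases x transitions)")
        if self.d.shape[0] != len(self.phase_labels):
            raise ShapeMismatchError("row count does not match the phase labels")


@dataclass
class ResidualMatrix:
    """Element-wise difference of two artifact matrices (original - recalculated)."""

    delta: np.ndarray
    phase_labels: list[int]

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.float64)
        if self.delta.ndim != 2 or self.delta.shape[0] != len(self.phase_labels):
            raise ShapeMismatchError("residual matrix shape does not match phase labels")


@dataclass
class ComparisonReport:
    """Per-phase signed comparison of two image sets and the overall score.

    ``phase_signs[b]`` is +1/0/-1 by the sign of the b-th row sum of ΔD;
    ``overall_score`` is their mean, in [-1, +1].  ``localization[b]`` is
    the 1-based couch transition with the largest |ΔD| in row b (first on
    ties; 1 for an all-zero row, where it carries no information).
    """

    residual: ResidualMatrix
    phase_sums: np.ndarray
    phase_signs: np.ndarray
    overall_score: float
    localization: np.ndarray


def transition_similarity(volume: SortedPhaseVolume, n: int) -> TransitionSimilarity:
    """Compute the transition metric at couch transition ``n`` (1-based).

    Requires S >= 2 so the intracouch neighbor pairs exist.
    """
    if volume.slices_per_couch < 2:
        raise InsufficientSlicesError(
            "insufficient slices for neighbor baseline: S >= 2 required"
        )
    if not 1 <= n <= volume.n_transitions:
        raise ValueError(f"couch transition n must be in [1, {volume.n_transitions}]")
    s = volume.slices_per_couch
    edge = ncc(volume.slice_at(n, s), volume.slice_at(n + 1, 1))
    left = ncc(volume.slice_at(n, s - 1), volume.slice_at(n, s))
    right = ncc(volume.slice_at(n + 1, 1), volume.slice_at(n + 1, 2))
    return TransitionSimilarity(n, edge_ncc=edge, left_ncc=left, right_ncc=right)


def artifact_matrix(image_set: FourDCTImageSet) -> ArtifactMatrix:
    """D at every couch transition for every phase bin of one image set."""
    if image_set.n_couch < 2:
        raise InsufficientSlicesError("at least 2 couch positions required")
    n_t = image_set.n_couch - 1
    d = np.empty((image_set.n_phases, n_t))
    for b, vol in enumerate(image_set.volumes):
        for n in range(1, n_t + 1):
            d[b, n - 1] = transition_similarity(vol, n).d_value
    return ArtifactMatrix(d, list(image_set.phase_labels),
                          provenance_label=image_set.provenance_label)


def residual_matrix(original: ArtifactMatrix, recalculated: ArtifactMatrix) -> ResidualMatrix:
    """ΔD = D_original - D_recalculated, element-wise.

    Positive entries indicate higher edge-slice similarity (fewer/smaller
    artifacts) in the recalculated set at that phase and transition.
    """
    if original.d.shape != recalculated.d.shape:
        raise ShapeMismatchError(
            f"artifact matrices differ in shape: {original.d.shape} vs {recalculated.d.shape}"
        )
    if original.phase_labels != recalculated.phase_labels:
        raise ShapeMismatchError("artifact matrices differ in phase labels")
    return ResidualMatrix(original.d - recalculated.d, list(original.phase_labels))


def score(residual: ResidualMatrix) -> ComparisonReport:
    """Row-sum sign scoring of a residual matrix.

    Each phase row of ΔD is summed; the row gets +1 / -1 / 0 by the sign of
    the sum (|sum| <= ZERO_SUM_RTOL * (N-1) counts as zero, so that exact
    self-comparison scores 0 despite floating-point noise).  The overall
    score is the mean of the per-phase signs.
    """
    delta = residual.delta
    sums = delta.sum(axis=1)
    tol = ZERO_SUM_RTOL * max(1, delta.shape[1])
    signs = np.where(np.abs(sums) <= tol, 0, np.sign(sums)).astype(int)
    overall = float(signs.mean())
    localization = np.argmax(np.abs(delta), axis=1) + 1
    return ComparisonReport(
        residual=residual,
        phase_sums=sums,
        phase_signs=signs,
        overall_score=overall,
        localization=localization,
    )


def compare_sets(set_a: FourDCTImageSet, set_b: FourDCTImageSet) -> ComparisonReport:
    """Full comparison of two sorted image sets: ΔD, per-phase signs, score.

    ``set_a`` plays the "original" role and ``set_b`` the "recalculated"
    role: a positive overall score means ``set_b`` has fewer or smaller
    artifacts than ``set_a``.
    """
    if (
        set_a.n_phases != set_b.n_phases
        or set_a.n_couch != set_b.n_couch
        or set_a.slices_per_couch != set_b.slices_per_couch
        or set_a.slice_shape != set_b.slice_shape
    ):
        raise ShapeMismatchError("image sets do not share (B, N, S, slice shape)")
    return score(residual_matrix(artifact_matrix(set_a), artifact_matrix(set_b)))
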