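# Methods

## Problem and model

Cine 4D CT acquires images at one couch position at a time, over at least
one full breathing cycle per position, and retrospectively assigns one
image per couch position to each respiratory phase bin using a surrogate
breathing trace. Within one couch block the S slices of a selected image
are reconstructed from the same rotation and hence the same breathing
state; the two *edge slices* on either side of a couch transition, however,
come from different breathing cycles. Phase-sorting errors therefore
manifest almost exclusively as discontinuities at couch transitions.

The artifact measure exploits this asymmetry. The slice similarity is the
normalized correlation coefficient of raw HU pixel values,

    C_AB = Σ I_A·I_B / (√(Σ I_A²)·√(Σ I_B²)),

deliberately **without mean subtraction** — it is a cosine similarity, not
Pearson correlation, and substituting one for the other changes the values.
At transition n of phase bin b,

    D_b,n = (C_n,n + C_n,n+1)/2 − C_n,

where C_n is the edge-pair NCC and C_n,n, C_n,n+1 the two intracouch
neighbor-pair NCCs. The neighbor pairs share a breathing state, so their
mean is a baseline for non-respiratory anatomical change near the
transition; D rises when the edge similarity drops below that baseline.

D alone is not an absolute quality score: abrupt anatomy (e.g. the lung
apex, the chest wall–lung boundary) inflates D at some transitions in any
scan. The method is therefore strictly *comparative*: for two sortings of
the same acquisition, the residual ΔD = D_original − D_recalculated
subtracts everything static, leaving only sorting-dependent structure.
Each phase row of ΔD is summed; the row gets sign +1/0/−1; the overall
score is the mean of the B signs, in [−1, +1], positive when the second
(recalculated) set has fewer or smaller artifacts. The row-sum-then-sign
design mimics a human observer who scans the whole anatomy at one phase
and renders a per-phase verdict.

### Numerical choices

- NCC accumulation is in float64 regardless of input dtype (512² sums of
  HU products overflow narrow integers), and the result is clamped to
  [−1, +1].
- An all-zero slice makes the NCC undefined and raises a distinct error
  rather than returning NaN.
- A phase row sum with |sum| ≤ 1e−12·(N−1) is assigned sign 0, so that
  comparing a set against itself scores exactly 0 even in the presence of
  floating-point noise; genuinely tied real-data sums also land here.
- Per-phase localization (argmax of |ΔD|) takes the first maximum on ties;
  for an all-zero row it defaults to transition 1 and carries no
  information.
- D is defined for n ∈ [1, N−1] only, with exactly one neighbor pair per
  side; no wrap-around and no wider baseline window.

## Phase model

Respiratory phase is 0% at each inhalation peak and linear in time up to
100% at the next peak — the standard retrospective phase-angle surrogate.
Vendor software may implement a different proprietary rule; linear-in-time
is a stated convention here, adopted because the method only needs phases
to be consistent between the two sortings being compared. Phase is
undefined outside the span of the peak set and querying there is an error,
not an extrapolation. Peak editing (the "phase recalculation" workflow)
matches deletions to the nearest existing peak within a 0.2 s tolerance
and rejects insertions that duplicate a peak within the same tolerance.

## Synthetic phantom

The generator emulates a cine acquisition of a minimal breathing thorax:
a circular soft-tissue body (40 HU) in air (−1000 HU) containing two
elliptical lungs (−800 HU) closed from below by a diaphragm dome (50 HU)
whose apex follows the standard periodic breathing trajectory

    z(t) = z0 − A·sin^(2k)(πt/τ),

full exhale at t = 0, minimum z0 − A mid-cycle. The dome is a paraboloid
per lung: a pixel at in-plane distance ρ from its lung's axis is diaphragm
when the slice position z lies below apex − c·ρ², with the curvature c set
so the dome drops ~40 mm from apex to lung margin. This is the entire
anatomy on purpose — the metric needs nothing more than a high-contrast
boundary moving across couch transitions, and the dome mirrors where
sorting artifacts concentrate clinically.

Default configuration (the conditions used by the validation tests):
64×64 pixels at 6 mm spacing (≈38 cm field of view), N = 8 couch positions
of S = 8 slices at 2.5 mm (16 cm scan length), diaphragm rest position
90 mm with amplitude A = 20 mm, period τ = 4 s, exponent 2k = 4, cine dwell
5 s per couch (one period plus a margin) with a frame every 0.25 s, and
additive Gaussian noise of 20 HU. These are clinically plausible desk-scale
values; a full corrupted/corrected pair generates and scores in well under
a second. The surrogate trace is the diaphragm displacement itself, so its
inhalation peaks coincide with motion extrema by construction; a real
external surrogate (abdominal surface) adds phase lag and drift that this
phantom does not model. The trace extends one breathing period beyond the
acquisition at both ends so every frame has a defined phase.

`make_validation_pair` deletes `n_missed` interior true peaks and inserts
`n_spurious` false peaks (uniformly placed, at least a quarter period away
from surviving peaks) to form the corrupted peak set, sorts the *same*
cine frames once with corrupted and once with true phases, and records
which (phase, couch) selections changed. Because both sortings reuse the
identical frame objects, ΔD is *exactly* zero wherever selections agree —
a stronger cancellation than real repeat-sorted data, where independent
reconstructions would still differ by noise. The default corruption level
of 3 missed + 1 spurious peaks is a fixed choice representative of a badly
miscalculated trace. All randomness (pixel noise, corruption placement)
flows from a single integer seed.

What phantom-based passes do and do not show: they demonstrate that the
pipeline detects and localizes sorting-induced edge discontinuities and
that static structure cancels; they do not probe reconstruction physics,
irregular breathing statistics, partial-volume effects, or observer
variability on real anatomy — the packaged observer-score tables cover
the human-comparison side on the original study's data.

## Observer statistics

Each observer picks, for five views per patient, which sorting looks
better (+1 recalculated / 0 neither / −1 original); the patient score is
the mean of the five picks. The agreement summary classifies the 3×3
cross-tabulation of the two observers' 50 picks into complete agreement
(diagonal), partial agreement (exactly one observer picked "neither") and
complete disagreement (opposite picks).

The signed-rank test drops zero differences, mid-ranks ties, and computes
the two-sided p-value exactly: P(|W − μ| ≥ |w₊ − μ|), μ = n(n+1)/4, over
all 2ⁿ sign assignments of the observed rank multiset. The distribution is
built by generating-function convolution over doubled ranks (mid-ranks are
half-integers), which enumerates the 2ⁿ assignments exactly in O(n·Σr)
time. For n_effective > 20 a tie-corrected normal approximation is used
instead and flagged in the result's `method` field. This zeros-dropped /
mid-rank / full-enumeration convention reproduces both published p-values
on the packaged score table (2/512 ≈ 0.0039 for each one-sample test;
222/512 ≈ 0.4336 for the paired test); statistics packages differ in
exactly these conventions, which is why they are spelled out here.

## I/O conventions

Slices are ordered by ascending scan-axis coordinate; s = 1 is the first
slice of a couch block, so the edge pair at transition n is
(I(n,S), I(n+1,1)). All user-facing indices (phase rows, transitions,
couch/slice indices) are 1-based. Non-uniform slices-per-couch is
rejected. DICOM reading applies the stored rescale slope/intercept to get
HU and can chunk couch blocks either by sorted position (runs of S) or by
shared acquisition time — vendors differ in which metadata is reliable, so
both grouping keys are exposed. The `array-stack` interchange format is a
single `.npz` with a `(B, N, S, rows, cols)` float HU array, integer phase
labels, and per-slice acquisition times (NaN where unknown). DICOM
writing, vendor 4D metadata dialects, masked/region-restricted NCC, and
absolute single-scan quality scores are out of scope.

## Known limitations

- The comparison is only meaningful for two sortings of the *same*
  acquisition; the score has no calibration across patients or scanners.
- A sorting difference confined to slices far from any couch transition is
  invisible to the metric by design.
- The exact-zero cancellation of shared frames in the phantom slightly
  flatters the method relative to real data; the Monte-Carlo acceptance
  thresholds (positive score in ≥18/20 seeds, ≥90% localization) were set
  to mirror the original validation outcome, not ceilings of the phantom.
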