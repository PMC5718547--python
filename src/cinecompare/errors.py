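"""Exception hierarchy for cinecompare.

Every failure mode that callers may want to handle separately gets its
own class; all inherit from :class:`CineCompareError`.
"""


class CineCompareError(Exception):
    """Base class for all cinecompare errors."""


class LayoutError(CineCompareError):
    """Unknown or unsupported image-set layout descriptor."""


class CorruptInputError(CineCompareError):
    """A file is missing, unreadable, or not of the expected format."""


class InconsistentSliceDimensionsError(CineCompareError):
    """Slices within one image set do not share identical pixel dimensions."""


class SliceCountError(CineCompareError):
    """The number of slices in a phase is not divisible by the slices-per-couch S."""


class DuplicatePositionError(CineCompareError):
    """Two slices within one phase volume share the same spatial position."""


class DegenerateSliceError(CineCompareError):
    """An all-zero slice makes the normalized correlation undefined."""


class DimensionMismatchError(CineCompareError):
    """Two slices passed to the NCC do not have identical dimensions."""


class InsufficientSlicesError(CineCompareError):
    """Insufficient slices for the neighbor baseline (S < 2)."""


class ShapeMismatchError(CineCompareError):
    """Two image sets or artifact matrices do not share B, N, S or slice shape."""


class PeakDetectionError(CineCompareError):
    """Fewer than 2 inhalation peaks found in the breathing trace."""


class PeakEditError(CineCompareError):
    """A requested peak deletion has no match, or an insertion duplicates a peak."""


class PhaseSpanError(CineCompareError):
    """Phase undefined outside the peak span."""


class NoEffectiveObservationsError(CineCompareError):
    """All differences are zero; the signed-rank test is undefined."""


class EmptyCouchError(CineCompareError):
    """A couch position has no cine frames to sort."""
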