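"""Synthetic cine 4D CT of a breathing thorax phantom.

The phantom is deliberately minimal — a circular soft-tissue body holding
two elliptical lungs, closed from below by a dome-shaped diaphragm whose
apex moves along the scan axis with the breathing cycle.  That is all the
comparison metric needs: a moving high-contrast boundary that crosses
couch transitions.

Diaphragm motion follows the standard periodic breathing model

    z(t) = z0 - A * sin^(2k)(pi * t / tau),

which spends more time near exhale (z0) than inhale, as real traces do.
``simulate_cine`` acquires frames couch position by couch position, exactly
like a cine protocol: the scanner dwells ``cine_duration_per_couch``
seconds at each position, reconstructing one S-slice frame every
``frame_interval`` seconds, then steps to the next position.  The surrogate
trace is the diaphragm displacement, so its inhalation peaks coincide with
motion extrema by construction.

``make_validation_pair`` recreates the miscalculated-vs-recalculated phase
experiment: the same cine frames are sorted twice, once with phases from a
peak set corrupted by missed and/or spurious inhalation peaks and once
with the true peaks, returning both image sets plus a record of which
couch blocks (and hence transitions) the corruption actually changed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .breathing import BreathingTrace, PeakSet, PhaseAssignment, edit_peaks
from .errors import EmptyCouchError, PeakDetectionError
from .imageset_io import AxialSlice, FourDCTImageSet, SortedPhaseVolume

__all__ = [
    "PhantomConfig",
    "CineFrame",
    "CineSeries",
    "ValidationPair",
    "DEFAULT_BIN_LABELS",
    "trajectory",
    "render_slice",
    "simulate_cine",
    "phase_sort",
    "make_validation_pair",
]

DEFAULT_BIN_LABELS = tuple(range(0, 100, 10))


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, tissue HU values, motion and acquisition parameters.

    Defaults give a desk-scale scan (64x64 pixels, 8 couch positions of 8
    slices) that generates and scores in seconds while keeping clinically
    plausible dimensions: ~38 cm field of view, 2.5 mm slices (16 cm scan
    length), 2 cm diaphragm excursion, 4 s breathing period, 4 frames/s
    cine with a dwell of one period plus one second per couch position.
    """

    image_size: int = 64            # pixels per side
    pixel_spacing: float = 6.0      # mm
    slice_thickness: float = 2.5    # mm
    n_couch: int = 8                # N, couch positions
    slices_per_couch: int = 8       # S
    body_radius: float = 160.0      # mm
    body_hu: float = 40.0
    lung_hu: float = -800.0
    diaphragm_hu: float = 50.0
    background_hu: float = -1000.0
    diaphragm_rest_position: float = 90.0  # mm along scan axis, full exhale
    motion_amplitude: float = 20.0  # mm, peak-to-peak diaphragm excursion
    breathing_period: float = 4.0   # s
    motion_exponent: int = 4        # 2k in sin^(2k); even, >= 2
    cine_duration_per_couch: float = 5.0  # s
    frame_interval: float = 0.25    # s
    noise_sd: float = 20.0          # HU

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.motion_amplitude < 0:
            raise ValueError("motion_amplitude must be >= 0")
        if self.cine_duration_per_couch < self.breathing_period:
            raise ValueError(
                "cine_duration_per_couch must cover at least one breathing period"
            )
        if self.motion_exponent < 2 or self.motion_exponent % 2:
            raise ValueError("motion_exponent must be a positive even integer")

    @property
    def frames_per_couch(self) -> int:
        return int(round(self.cine_duration_per_couch / self.frame_interval))

    @property
    def scan_length(self) -> float:
        return self.n_couch * self.slices_per_couch * self.slice_thickness

    def slice_z(self, couch_index: int, slice_index: int) -> float:
        """Scan-axis position (mm) of the center of slice I(n, s), 1-based."""
        k = (couch_index - 1) * self.slices_per_couch + (slice_index - 1)
        return (k + 0.5) * self.slice_thickness

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CineFrame:
    """One cine reconstruction: S slices acquired at one time at one couch."""

    acquisition_time: float
    slices: list[AxialSlice]


@dataclass
class CineSeries:
    """Cine frames grouped per couch position (index 0 = couch position 1)."""

    couch_frames: list[list[CineFrame]]

    def __post_init__(self) -> None:
        for frames in self.couch_frames:
            times = [f.acquisition_time for f in frames]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError("cine frames must be strictly time-ordered per couch")

    @property
    def n_couch(self) -> int:
        return len(self.couch_frames)


def trajectory(config: PhantomConfig, t) -> np.ndarray | float:
    """Diaphragm apex position (mm) at time t: z0 - A*sin^(2k)(pi*t/tau).

    z(0) = z0 is full exhale; the minimum z0 - A is reached mid-cycle.
    """
    t_arr = np.asarray(t, dtype=np.float64)
    s = np.sin(np.pi * t_arr / config.breathing_period)
    z = config.diaphragm_rest_position - config.motion_amplitude * s**config.motion_exponent
    return float(z) if t_arr.ndim == 0 else z


class _Geometry:
    """Precomputed in-plane masks for a config (z- and t-independent parts)."""

    def __init__(self, config: PhantomConfig):
        half = config.image_size * config.pixel_spacing / 2.0
        coords = (np.arange(config.image_size) + 0.5) * config.pixel_spacing - half
        x, y = np.meshgrid(coords, coords, indexing="xy")
        r = config.body_radius
        self.body = x**2 + y**2 <= r**2
        ax, ay = 0.32 * r, 0.60 * r
        cx = 0.45 * r
        left = ((x + cx) / ax) ** 2 + (y / ay) ** 2 <= 1.0
        right = ((x - cx) / ax) ** 2 + (y / ay) ** 2 <= 1.0
        self.lungs = (left | right) & self.body
        # squared in-plane distance to the nearest lung axis, for the dome
        rho2_left = (x + cx) ** 2 + y**2
        rho2_right = (x - cx) ** 2 + y**2
        self.rho2 = np.where(left, rho2_left, rho2_right)
        # dome drops ~40 mm from apex to the lung margin
        self.dome_curvature = 40.0 / ax**2  # mm^-1


_GEOMETRY_CACHE: dict[tuple, _Geometry] = {}


def _geometry(config: PhantomConfig) -> _Geometry:
    key = (config.image_size, config.pixel_spacing, config.body_radius)
    if key not in _GEOMETRY_CACHE:
        _GEOMETRY_CACHE[key] = _Geometry(config)
    return _GEOMETRY_CACHE[key]


def render_slice(
    config: PhantomConfig,
    z: float,
    t: float,
    rng: np.random.Generator | None = None,
    couch_index: int = 1,
    slice_index: int = 1,
) -> AxialSlice:
    """Render the axial slice at scan-axis position z (mm) and time t (s).

    Pixels inside a lung but below the local diaphragm dome surface
    ``z_apex(t) - curvature * rho^2`` take ``diaphragm_hu``; the dome
    cross-section radius therefore grows as z descends below the apex.
    Gaussian noise of ``noise_sd`` HU is added when an ``rng`` is given.
    """
    geom = _geometry(config)
    pix = np.full((config.image_size, config.image_size), config.background_hu)
    pix[geom.body] = config.body_hu
    apex = trajectory(config, t)
    dome_surface = apex - geom.dome_curvature * geom.rho2
    lung = geom.lungs & (dome_surface <= z)
    diaphragm = geom.lungs & (dome_surface > z)
    pix[lung] = config.lung_hu
    pix[diaphragm] = config.diaphragm_hu
    if rng is not None and config.noise_sd > 0:
        pix = pix + rng.normal(0.0, config.noise_sd, pix.shape)
    return AxialSlice(pix, couch_index=couch_index, slice_index=slice_index,
                      acquisition_time=float(t))


def simulate_cine(
    config: PhantomConfig, seed: int
) -> tuple[CineSeries, BreathingTrace, PeakSet]:
    """Simulate one cine acquisition of the breathing phantom.

    Couch positions are acquired sequentially; couch n dwells on
    [(n-1)*dwell, n*dwell) with one frame every ``frame_interval``.  The
    returned surrogate trace (diaphragm displacement, 25 Hz) extends one
    breathing period beyond the acquisition on both sides so that every
    frame lies strictly inside the span of the true inhalation peaks.
    """
    rng = np.random.default_rng(seed)
    tau = config.breathing_period
    dwell = config.cine_duration_per_couch
    total = config.n_couch * dwell

    couch_frames: list[list[CineFrame]] = []
    for n in range(1, config.n_couch + 1):
        t0 = (n - 1) * dwell
        frames = []
        for j in range(config.frames_per_couch):
            t = t0 + j * config.frame_interval
            slices = [
                render_slice(config, config.slice_z(n, s), t, rng=rng,
                             couch_index=n, slice_index=s)
                for s in range(1, config.slices_per_couch + 1)
            ]
            frames.append(CineFrame(acquisition_time=t, slices=slices))
        couch_frames.append(frames)

    trace_t = np.arange(-tau, total + tau, 0.04)
    surrogate = config.motion_amplitude * np.sin(np.pi * trace_t / tau) ** config.motion_exponent
    trace = BreathingTrace(trace_t, surrogate)
    # analytic maxima of sin^(2k)(pi t / tau): t = tau*(m + 1/2)
    m_lo = int(np.ceil((trace_t[0] / tau) - 0.5))
    m_hi = int(np.floor((trace_t[-1] / tau) - 0.5))
    peaks = PeakSet(tau * (np.arange(m_lo, m_hi + 1) + 0.5))
    return CineSeries(couch_frames), trace, peaks


def phase_sort(
    cine: CineSeries,
    phases: PhaseAssignment,
    bin_labels=DEFAULT_BIN_LABELS,
    provenance_label: str = "",
) -> FourDCTImageSet:
    """Sort cine frames into phase bins, one frame per (bin, couch position).

    For each couch position the frame whose phase is closest to the bin
    label in circular distance on [0, 100) is selected; ties go to the
    earlier acquisition.  Selected frames keep their AxialSlice objects, so
    two sorts of the same cine share slices they select in common.
    """
    bin_labels = sorted(int(b) for b in bin_labels)
    per_bin_blocks: dict[int, list] = {b: [] for b in bin_labels}
    for ci, frames in enumerate(cine.couch_frames, start=1):
        if not frames:
            raise EmptyCouchError(f"couch position {ci} has no cine frames")
        frame_phases = phases([f.acquisition_time for f in frames])
        for label in bin_labels:
            diff = np.abs(frame_phases - label)
            circ = np.minimum(diff, 100.0 - diff)
            best = int(np.argmin(circ))  # argmin keeps the earliest on ties
            per_bin_blocks[label].append(frames[best].slices)
    volumes = [
        SortedPhaseVolume(label, per_bin_blocks[label]) for label in bin_labels
    ]
    return FourDCTImageSet(volumes, provenance_label=provenance_label)


@dataclass
class ValidationPair:
    """A miscalculated/recalculated sorting pair plus the corruption record.

    ``changed_blocks[b, n-1]`` is True where the selected frame at phase
    bin b and couch position n differs between the two sorts;
    ``injected_transitions[b]`` lists the 1-based couch transitions
    adjacent to a changed block of phase b — where ΔD can be nonzero.
    """

    set_original: FourDCTImageSet
    set_recalculated: FourDCTImageSet
    changed_blocks: np.ndarray
    injected_transitions: list[list[int]]
    true_peaks: PeakSet
    corrupted_peaks: PeakSet


def make_validation_pair(
    config: PhantomConfig,
    n_missed_peaks: int,
    n_spurious_peaks: int,
    seed: int,
    bin_labels=DEFAULT_BIN_LABELS,
) -> ValidationPair:
    """Simulate one cine scan and sort it with corrupted vs. true phases.

    ``n_missed_peaks`` true interior inhalation peaks are deleted and
    ``n_spurious_peaks`` false peaks inserted (mid-span, away from real
    peaks) to form the corrupted peak set; sorting with its phases yields
    ``set_original``, sorting with the true peaks yields
    ``set_recalculated``.  All randomness flows from ``seed``.
    """
    if n_missed_peaks < 0 or n_spurious_peaks < 0:
        raise ValueError("corruption counts must be >= 0")
    cine, _trace, true_peaks = simulate_cine(config, seed)
    rng = np.random.default_rng([seed, 104729])

    interior = true_peaks.peak_times[1:-1]
    if n_missed_peaks > len(interior):
        raise PeakDetectionError(
            f"cannot delete {n_missed_peaks} peaks: only {len(interior)} interior peaks"
        )
    delete = (
        rng.choice(interior, size=n_missed_peaks, replace=False)
        if n_missed_peaks
        else np.empty(0)
    )
    survivors = np.array(sorted(set(true_peaks.peak_times) - set(delete)))
    lo, hi = true_peaks.peak_times[0], true_peaks.peak_times[-1]
    inserts: list[float] = []
    min_gap = 0.25 * config.breathing_period
    for _ in range(n_spurious_peaks):
        for _attempt in range(1000):
            t = float(rng.uniform(lo + min_gap, hi - min_gap))
            existing = np.concatenate([survivors, np.asarray(inserts)])
            if np.min(np.abs(existing - t)) > min_gap:
                inserts.append(t)
                break
        else:  # pragma: no cover - would need a pathological config
            raise PeakDetectionError("could not place a spurious peak away from real peaks")
    corrupted = edit_peaks(true_peaks, insert=inserts, delete=list(delete))
    if len(corrupted) < 2:
        raise PeakDetectionError("corruption left fewer than 2 peaks")

    set_o = phase_sort(cine, PhaseAssignment(corrupted), bin_labels,
                       provenance_label="original (miscalculated phase)")
    set_r = phase_sort(cine, PhaseAssignment(true_peaks), bin_labels,
                       provenance_label="recalculated (true phase)")

    b_, n_ = set_o.n_phases, set_o.n_couch
    changed = np.zeros((b_, n_), dtype=bool)
    for b in range(b_):
        for n in range(n_):
            t_o = set_o.volumes[b].couch_blocks[n][0].acquisition_time
            t_r = set_r.volumes[b].couch_blocks[n][0].acquisition_time
            changed[b, n] = t_o != t_r
    injected: list[list[int]] = []
    for b in range(b_):
        trans = set()
        for n in (np.flatnonzero(changed[b]) + 1).tolist():  # 1-based couch index
            if n - 1 >= 1:
                trans.add(n - 1)
            if n <= n_ - 1:
                trans.add(n)
        injected.append(sorted(trans))
    return ValidationPair(
        set_original=set_o,
        set_recalculated=set_r,
        changed_blocks=changed,
        injected_transitions=injected,
        true_peaks=true_peaks,
        corrupted_peaks=corrupted,
    )
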