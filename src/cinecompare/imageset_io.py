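"""Data model and I/O for retrospectively sorted 4D CT image sets.

A sorted 4D CT image set is organized as B respiratory phase bins, each
holding N couch positions (couch blocks) of S axial slices.  Slices are
ordered by ascending position along the scan axis, so the last slice of
couch block ``n`` is spatially adjacent to the first slice of block
``n + 1`` — the edge-slice pair at couch transition ``n``.

Supported on-disk layouts:

``array-stack``
    A single NumPy ``.npz`` container with arrays

    - ``pixels``  — float array of shape ``(B, N, S, n_rows, n_cols)`` in HU
    - ``phase_labels`` — integer percent labels, strictly increasing
    - ``times``   — acquisition times in seconds, shape ``(B, N, S)``,
      ``NaN`` where unknown

    This is the package's dependency-free interchange format.

``nifti-per-phase``
    A directory of one uncompressed NIfTI volume per phase bin, named
    ``phase_<label>.nii`` with data shape ``(n_rows, n_cols, N*S)``, plus
    a ``meta.json`` recording ``slices_per_couch`` and the phase labels.

``dicom-series``
    A directory with one subdirectory per phase bin, each holding the
    axial DICOM files of that phase.  Pixel data are converted to HU via
    the stored rescale slope/intercept.  Read-only.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CorruptInputError,
    DuplicatePositionError,
    InconsistentSliceDimensionsError,
    LayoutError,
    SliceCountError,
)

LAYOUTS = ("array-stack", "nifti-per-phase", "dicom-series")

__all__ = [
    "AxialSlice",
    "SortedPhaseVolume",
    "FourDCTImageSet",
    "imageset_from_array",
    "imageset_to_array",
    "read_imageset",
    "write_imageset",
    "write_report",
    "read_report",
    "LAYOUTS",
]


@dataclass
class AxialSlice:
    """One axial CT slice: a 2D grid of pixel values in Hounsfield Units.

    ``couch_index`` (n) and ``slice_index`` (s) are 1-based, following the
    reporting convention used throughout the package.
    """

    pixels: np.ndarray
    couch_index: int = 1
    slice_index: int = 1
    acquisition_time: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InconsistentSliceDimensionsError(
                f"slice pixels must be 2D, got ndim={self.pixels.ndim}"
            )
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise InconsistentSliceDimensionsError(
                f"slice must be at least 2x2, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise CorruptInputError("slice contains non-finite pixel values")
        if self.couch_index < 1 or self.slice_index < 1:
            raise ValueError("couch_index and slice_index are 1-based and positive")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SortedPhaseVolume:
    """All slices assigned to one respiratory phase bin.

    ``couch_blocks[n-1][s-1]`` is slice ``I(n, s)``; blocks are ordered by
    ascending scan-axis position.
    """

    phase_label: int
    couch_blocks: list[list[AxialSlice]]

    def __post_init__(self) -> None:
        if not self.couch_blocks:
            raise SliceCountError("phase volume has no couch blocks")
        s = len(self.couch_blocks[0])
        if s < 1:
            raise SliceCountError("couch block has no slices")
        shape = self.couch_blocks[0][0].pixels.shape
        for block in self.couch_blocks:
            if len(block) != s:
                raise SliceCountError(
                    f"non-uniform slices per couch: expected {s}, got {len(block)}"
                )
            for sl in block:
                if sl.pixels.shape != shape:
                    raise InconsistentSliceDimensionsError(
                        f"slice shape {sl.pixels.shape} != {shape}"
                    )

    @property
    def n_couch(self) -> int:
        """N, the number of couch positions."""
        return len(self.couch_blocks)

    @property
    def slices_per_couch(self) -> int:
        """S, the number of slices per couch position."""
        return len(self.couch_blocks[0])

    @property
    def n_transitions(self) -> int:
        """Number of couch transitions, N - 1."""
        return self.n_couch - 1

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.couch_blocks[0][0].pixels.shape

    def slice_at(self, n: int, s: int) -> AxialSlice:
        """Slice I(n, s) with 1-based couch index n and slice index s."""
        return self.couch_blocks[n - 1][s - 1]

    def iter_slices(self):
        """All slices in spatial order, concatenated across couch blocks."""
        for block in self.couch_blocks:
            yield from block


@dataclass
class FourDCTImageSet:
    """A sorted 4D CT image set: B phase volumes sharing (N, S, slice shape)."""

    volumes: list[SortedPhaseVolume]
    provenance_label: str = ""

    def __post_init__(self) -> None:
        if not self.volumes:
            raise SliceCountError("image set has no phase volumes")
        labels = [v.phase_label for v in self.volumes]
        if any(later <= earlier for earlier, later in zip(labels, labels[1:])):
            raise ValueError(f"phase labels must be strictly increasing, got {labels}")
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            if (
                v.n_couch != ref.n_couch
                or v.slices_per_couch != ref.slices_per_couch
                or v.slice_shape != ref.slice_shape
            ):
                raise InconsistentSliceDimensionsError(
                    "phase volumes do not share identical (N, S, slice shape)"
                )

    @property
    def n_phases(self) -> int:
        return len(self.volumes)

    @property
    def n_couch(self) -> int:
        return self.volumes[0].n_couch

    @property
    def slices_per_couch(self) -> int:
        return self.volumes[0].slices_per_couch

    @property
    def phase_labels(self) -> list[int]:
        return [v.phase_label for v in self.volumes]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.volumes[0].slice_shape

    @property
    def n_slices(self) -> int:
        return self.n_phases * self.n_couch * self.slices_per_couch


def imageset_from_array(
    pixels: np.ndarray,
    phase_labels,
    times: np.ndarray | None = None,
    provenance_label: str = "",
) -> FourDCTImageSet:
    """Build an image set from a (B, N, S, rows, cols) HU array."""
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 5:
        raise LayoutError(f"expected a 5D (B,N,S,rows,cols) array, got ndim={pixels.ndim}")
    b_, n_, s_ = pixels.shape[:3]
    phase_labels = [int(x) for x in phase_labels]
    if len(phase_labels) != b_:
        raise LayoutError("phase_labels length does not match the stack's B")
    volumes = []
    for b in range(b_):
        blocks = []
        for n in range(n_):
            block = []
            for s in range(s_):
                t = None
                if times is not None and np.isfinite(times[b, n, s]):
                    t = float(times[b, n, s])
                block.append(
                    AxialSlice(pixels[b, n, s], couch_index=n + 1,
                               slice_index=s + 1, acquisition_time=t)
                )
            blocks.append(block)
        volumes.append(SortedPhaseVolume(phase_labels[b], blocks))
    return FourDCTImageSet(volumes, provenance_label=provenance_label)


def imageset_to_array(image_set: FourDCTImageSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`imageset_from_array`: (pixels, phase_labels, times)."""
    b_, n_, s_ = image_set.n_phases, image_set.n_couch, image_set.slices_per_couch
    rows, cols = image_set.slice_shape
    pixels = np.empty((b_, n_, s_, rows, cols), dtype=np.float64)
    times = np.full((b_, n_, s_), np.nan)
    for b, vol in enumerate(image_set.volumes):
        for n, block in enumerate(vol.couch_blocks):
            for s, sl in enumerate(block):
                pixels[b, n, s] = sl.pixels
                if sl.acquisition_time is not None:
                    times[b, n, s] = sl.acquisition_time
    return pixels, np.asarray(image_set.phase_labels, dtype=np.int64), times


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_imageset(
    path,
    layout: str,
    slices_per_couch: int | None = None,
    group_by: str = "position",
) -> FourDCTImageSet:
    """Read a sorted 4D CT image set from disk.

    Parameters
    ----------
    path
        Container file (array-stack) or directory (NIfTI / DICOM).
    layout
        One of ``array-stack``, ``nifti-per-phase``, ``dicom-series``.
    slices_per_couch
        S; required for DICOM unless derivable, and for NIfTI directories
        lacking a ``meta.json``.
    group_by
        How DICOM slices are chunked into couch blocks: ``"position"``
        chunks the spatially sorted slices into runs of S; ``"time"``
        groups slices sharing one acquisition time into a block.
    """
    path = Path(path)
    if not path.exists():
        raise CorruptInputError(f"input path does not exist: {path}")
    if layout == "array-stack":
        return _read_array_stack(path)
    if layout == "nifti-per-phase":
        return _read_nifti(path, slices_per_couch)
    if layout == "dicom-series":
        return _read_dicom(path, slices_per_couch, group_by)
    raise LayoutError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")


def write_imageset(image_set: FourDCTImageSet, path, layout: str) -> None:
    """Write an image set as ``array-stack`` or ``nifti-per-phase``.

    DICOM writing is deliberately unsupported.
    """
    path = Path(path)
    if layout == "array-stack":
        pixels, labels, times = imageset_to_array(image_set)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            np.savez(fh, pixels=pixels, phase_labels=labels, times=times)
    elif layout == "nifti-per-phase":
        import nibabel as nib

        path.mkdir(parents=True, exist_ok=True)
        pixels, labels, _ = imageset_to_array(image_set)
        b_, n_, s_ = pixels.shape[:3]
        for b in range(b_):
            data = np.moveaxis(pixels[b].reshape(n_ * s_, *pixels.shape[3:]), 0, -1)
            img = nib.Nifti1Image(data, affine=np.eye(4))
            nib.save(img, str(path / f"phase_{int(labels[b]):02d}.nii"))
        meta = {"slices_per_couch": s_, "phase_labels": [int(x) for x in labels]}
        (path / "meta.json").write_text(json.dumps(meta))
    else:
        raise LayoutError(f"unsupported write layout {layout!r}")


def _read_array_stack(path: Path) -> FourDCTImageSet:
    try:
        with np.load(path) as npz:
            pixels = npz["pixels"]
            labels = npz["phase_labels"]
            times = npz["times"] if "times" in npz.files else None
    except Exception as exc:  # noqa: BLE001 - wrap any load failure
        raise CorruptInputError(f"cannot read array-stack {path}: {exc}") from exc
    return imageset_from_array(pixels, labels, times, provenance_label=str(path))


def _read_nifti(path: Path, slices_per_couch: int | None) -> FourDCTImageSet:
    import nibabel as nib

    meta_path = path / "meta.json"
    labels_from_meta = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        slices_per_couch = slices_per_couch or int(meta["slices_per_couch"])
        labels_from_meta = meta.get("phase_labels")
    if slices_per_couch is None:
        raise SliceCountError(
            "slices_per_couch is required to read a NIfTI directory without meta.json"
        )
    files = sorted(path.glob("phase_*.nii")) + sorted(path.glob("phase_*.nii.gz"))
    if not files:
        raise CorruptInputError(f"no phase_*.nii volumes found in {path}")
    stacks, labels = [], []
    for f in files:
        m = re.search(r"phase_(\d+)", f.name)
        labels.append(int(m.group(1)) if m else len(labels) * 10)
        try:
            data = np.asarray(nib.load(str(f)).get_fdata(), dtype=np.float64)
        except Exception as exc:  # noqa: BLE001
            raise CorruptInputError(f"cannot read NIfTI volume {f}: {exc}") from exc
        if data.ndim != 3:
            raise CorruptInputError(f"{f} is not a 3D volume")
        stacks.append(np.moveaxis(data, -1, 0))  # (N*S, rows, cols)
    if labels_from_meta is not None and sorted(labels) != sorted(labels_from_meta):
        raise CorruptInputError("phase labels in meta.json do not match the files")
    order = np.argsort(labels)
    stacks = [stacks[i] for i in order]
    labels = [labels[i] for i in order]
    n_total = stacks[0].shape[0]
    if any(st.shape != stacks[0].shape for st in stacks):
        raise InconsistentSliceDimensionsError("phase volumes differ in shape")
    if n_total % slices_per_couch:
        raise SliceCountError(
            f"slice count {n_total} not divisible by S={slices_per_couch}"
        )
    n_couch = n_total // slices_per_couch
    pixels = np.stack(stacks).reshape(
        len(stacks), n_couch, slices_per_couch, *stacks[0].shape[1:]
    )
    return imageset_from_array(pixels, labels, provenance_label=str(path))


def _read_dicom(path: Path, slices_per_couch: int | None, group_by: str) -> FourDCTImageSet:
    import pydicom

    if group_by not in ("position", "time"):
        raise LayoutError(f"group_by must be 'position' or 'time', got {group_by!r}")
    phase_dirs = sorted(p for p in path.iterdir() if p.is_dir())
    if not phase_dirs:
        raise CorruptInputError(f"no per-phase subdirectories found in {path}")
    volumes = []
    for i, pdir in enumerate(phase_dirs):
        m = re.search(r"(\d+)", pdir.name)
        label = int(m.group(1)) if m else i * 10
        records = []
        for f in sorted(pdir.iterdir()):
            if f.is_dir():
                continue
            try:
                ds = pydicom.dcmread(str(f))
                slope = float(getattr(ds, "RescaleSlope", 1.0))
                intercept = float(getattr(ds, "RescaleIntercept", 0.0))
                hu = ds.pixel_array.astype(np.float64) * slope + intercept
                z = float(ds.ImagePositionPatient[2])
                t = getattr(ds, "AcquisitionTime", None)
                t = float(t) if t not in (None, "") else None
            except Exception as exc:  # noqa: BLE001
                raise CorruptInputError(f"cannot read DICOM file {f}: {exc}") from exc
            records.append((z, t, hu))
        if not records:
            raise CorruptInputError(f"phase directory {pdir} holds no DICOM files")
        zs = np.array([r[0] for r in records])
        if len(np.unique(zs)) != len(zs):
            raise DuplicatePositionError(
                f"duplicate slice positions within phase {pdir.name}"
            )
        shapes = {r[2].shape for r in records}
        if len(shapes) != 1:
            raise InconsistentSliceDimensionsError(
                f"inconsistent slice dimensions in {pdir.name}: {shapes}"
            )
        s = slices_per_couch
        if s is None:
            s = _derive_s_from_times(records)
        if len(records) % s:
            raise SliceCountError(
                f"slice count not divisible by S: {len(records)} % {s} != 0"
            )
        blocks = _chunk_records(records, s, group_by)
        volumes.append(SortedPhaseVolume(label, blocks))
    return FourDCTImageSet(volumes, provenance_label=str(path))


def _derive_s_from_times(records) -> int:
    times = [t for _, t, _ in records]
    if any(t is None for t in times):
        raise SliceCountError(
            "slices_per_couch not supplied and not derivable (missing AcquisitionTime)"
        )
    _, counts = np.unique(np.asarray(times), return_counts=True)
    if len(set(counts)) != 1:
        raise SliceCountError(
            "slices_per_couch not derivable: unequal group sizes per acquisition time"
        )
    return int(counts[0])


def _chunk_records(records, s: int, group_by: str) -> list[list[AxialSlice]]:
    records = sorted(records, key=lambda r: r[0])  # ascending scan-axis position
    if group_by == "time":
        groups: dict[float, list] = {}
        for rec in records:
            if rec[1] is None:
                raise SliceCountError("group_by='time' requires AcquisitionTime on all slices")
            groups.setdefault(rec[1], []).append(rec)
        for t, g in groups.items():
            if len(g) != s:
                raise SliceCountError(
                    f"acquisition-time group at t={t} has {len(g)} slices, expected S={s}"
                )
        ordered = sorted(groups.values(), key=lambda g: g[0][0])
        chunks = ordered
    else:
        chunks = [records[i : i + s] for i in range(0, len(records), s)]
    blocks = []
    for n, chunk in enumerate(chunks, start=1):
        blocks.append(
            [
                AxialSlice(hu, couch_index=n, slice_index=si, acquisition_time=t)
                for si, (_, t, hu) in enumerate(chunk, start=1)
            ]
        )
    return blocks


# ---------------------------------------------------------------------------
# comparison-report output
# ---------------------------------------------------------------------------

def write_report(report, path) -> None:
    """Write a ComparisonReport as ``report.json`` + ``residual.csv`` under *path*.

    The CSV carries the residual matrix with 1-based phase-bin rows and
    couch-transition columns; the JSON carries per-phase sums, signs, the
    overall score and the per-phase transition localization.
    """
    import pandas as pd

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    delta = np.asarray(report.residual.delta)
    labels = list(report.residual.phase_labels)
    summary = {
        "overall_score": float(report.overall_score),
        "phase_labels": [int(x) for x in labels],
        "phase_sums": [float(x) for x in report.phase_sums],
        "phase_signs": [int(x) for x in report.phase_signs],
        "localization": [int(x) for x in report.localization],
    }
    (path / "report.json").write_text(json.dumps(summary, indent=2))
    df = pd.DataFrame(
        delta,
        index=pd.Index(labels, name="phase_percent"),
        columns=[f"transition_{n}" for n in range(1, delta.shape[1] + 1)],
    )
    df.to_csv(path / "residual.csv", float_format="%.17g")


def read_report(path) -> tuple[dict, np.ndarray]:
    """Read back a written report: (summary dict, residual matrix)."""
    import pandas as pd

    path = Path(path)
    summary = json.loads((path / "report.json").read_text())
    df = pd.read_csv(path / "residual.csv", index_col=0, float_precision="round_trip")
    return summary, df.to_numpy(dtype=np.float64)
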