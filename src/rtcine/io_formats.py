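"""Canonical in-memory containers and on-disk formats for cine and flow series.

The canonical on-disk representation is a NIfTI-1 image (axes x, y, slice,
frame) plus a JSON sidecar carrying timing and geometry that NIfTI cannot
express.  DICOM directories (classic single-frame files) are supported
read-mostly for cine stacks; export of sorted end-diastole/end-systole
stacks is available in both formats.

Sidecar schema (all keys required unless noted)::

    {
      "kind": "cine" | "flow",
      "frame_duration_ms": float,
      "pixel_spacing_mm": [row, col],
      "slice_thickness_mm": float,
      "slice_gap_mm": float,
      "n_slices": int,
      "frames_per_slice": int,
      "acquisition_order": "base-to-apex" | "apex-to-base",
      "venc_cm_s": float | null,        # required for kind == "flow"
      "stage_label": "rest" | "moderate" | "vigorous" | null,
      "frames_per_cycle": int | null    # flow series only
    }

Conventions: slice index 0 is the most basal slice, frame index 0 the first
acquired; all indices are 0-based with half-open intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import (
    ConfigError,
    EmptySeriesError,
    InconsistentGeometryError,
    MissingVencError,
    UnreadableSeriesError,
)

MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"

SIDECAR_NAME = "series.json"


@dataclass
class SeriesMetadata:
    """Timing, geometry and acquisition metadata shared by all series."""

    frame_duration: float  # ms
    pixel_spacing: tuple[float, float]  # mm (row, col)
    slice_thickness: float  # mm
    slice_gap: float = 0.0  # mm
    n_slices: int = 1
    frames_per_slice: int = 1
    acquisition_order: str = "base-to-apex"
    venc: float | None = None  # cm/s, flow series only
    stage_label: str | None = None  # rest | moderate | vigorous

    def __post_init__(self):
        if self.frame_duration <= 0:
            raise ConfigError("frame_duration must be > 0")
        if self.slice_thickness <= 0:
            raise ConfigError("slice_thickness must be > 0")
        if self.slice_gap < 0:
            raise ConfigError("slice_gap must be >= 0")
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))

    @property
    def slab(self) -> float:
        """Per-slice slab height (thickness + gap) in mm, the disc-summation step."""
        return self.slice_thickness + self.slice_gap

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area in mm^2."""
        return self.pixel_spacing[0] * self.pixel_spacing[1]


@dataclass
class RealTimeSeries:
    """A multi-slice, multi-frame short-axis cine stack.

    ``voxels`` is indexed ``[slice, frame, row, col]``.  Slices were acquired
    sequentially: slice k's frame j was acquired at global time
    ``(k * frames_per_slice + j) * frame_duration``.
    """

    voxels: np.ndarray
    metadata: SeriesMetadata

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 4:
            raise ConfigError("voxels must be 4D [slice, frame, row, col]")
        if not np.all(np.isfinite(self.voxels)):
            raise ConfigError("voxel intensities must be finite")
        s, f = self.voxels.shape[:2]
        if (s, f) != (self.metadata.n_slices, self.metadata.frames_per_slice):
            raise ConfigError(
                f"voxel shape {self.voxels.shape[:2]} inconsistent with metadata "
                f"({self.metadata.n_slices}, {self.metadata.frames_per_slice})"
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def frames_per_slice(self) -> int:
        return self.voxels.shape[1]

    def frame_time_s(self, slice_index: int, frame_index: int) -> float:
        """Global acquisition time (s) of one frame under sequential acquisition."""
        return (
            (slice_index * self.frames_per_slice + frame_index)
            * self.metadata.frame_duration
            / 1000.0
        )


@dataclass
class FlowSeries:
    """A 2D phase-contrast series: magnitude/phase frame pairs over one R-R cycle.

    ``phase`` is in radians in (-pi, pi]; velocity = venc * phase / pi.
    """

    magnitude: np.ndarray  # [frame, row, col]
    phase: np.ndarray  # [frame, row, col]
    metadata: SeriesMetadata
    frames_per_cycle: int = 30

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=np.float32)
        self.phase = np.asarray(self.phase, dtype=np.float32)
        if self.magnitude.shape != self.phase.shape or self.magnitude.ndim != 3:
            raise ConfigError("magnitude and phase must be matching 3D stacks")
        if np.any(self.magnitude < 0):
            raise ConfigError("magnitude must be non-negative")
        if np.any(self.phase <= -np.pi - 1e-6) or np.any(self.phase > np.pi + 1e-6):
            raise ConfigError("phase must lie in (-pi, pi]")
        if self.metadata.venc is None:
            raise MissingVencError("flow series requires a venc in metadata")

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]


# ---------------------------------------------------------------------------
# Canonical NIfTI + sidecar
# ---------------------------------------------------------------------------


def _metadata_to_sidecar(meta: SeriesMetadata, kind: str, frames_per_cycle=None) -> dict:
    return {
        "kind": kind,
        "frame_duration_ms": float(meta.frame_duration),
        "pixel_spacing_mm": [meta.pixel_spacing[0], meta.pixel_spacing[1]],
        "slice_thickness_mm": float(meta.slice_thickness),
        "slice_gap_mm": float(meta.slice_gap),
        "n_slices": int(meta.n_slices),
        "frames_per_slice": int(meta.frames_per_slice),
        "acquisition_order": meta.acquisition_order,
        "venc_cm_s": None if meta.venc is None else float(meta.venc),
        "stage_label": meta.stage_label,
        "frames_per_cycle": None if frames_per_cycle is None else int(frames_per_cycle),
    }


def _sidecar_to_metadata(sc: dict) -> SeriesMetadata:
    return SeriesMetadata(
        frame_duration=sc["frame_duration_ms"],
        pixel_spacing=tuple(sc["pixel_spacing_mm"]),
        slice_thickness=sc["slice_thickness_mm"],
        slice_gap=sc.get("slice_gap_mm", 0.0),
        n_slices=sc["n_slices"],
        frames_per_slice=sc["frames_per_slice"],
        acquisition_order=sc.get("acquisition_order", "base-to-apex"),
        venc=sc.get("venc_cm_s"),
        stage_label=sc.get("stage_label"),
    )


def _nifti_affine(meta: SeriesMetadata) -> np.ndarray:
    return np.diag([meta.pixel_spacing[1], meta.pixel_spacing[0], meta.slab, 1.0])


def write_series(series: RealTimeSeries | FlowSeries, path) -> Path:
    """Write a series to ``path`` (a directory) in the canonical NIfTI+sidecar form.

    The canonical round trip is lossless up to float32 precision.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(series, RealTimeSeries):
        if series.voxels.size == 0:
            raise EmptySeriesError("refusing to write an empty series")
        # voxels [s, f, r, c] -> nifti [x=c, y=r, slice, frame]
        data = np.ascontiguousarray(series.voxels.transpose(3, 2, 0, 1))
        nib.save(nib.Nifti1Image(data, _nifti_affine(series.metadata)), path / "cine.nii.gz")
        sidecar = _metadata_to_sidecar(series.metadata, "cine")
    elif isinstance(series, FlowSeries):
        if series.magnitude.size == 0:
            raise EmptySeriesError("refusing to write an empty series")
        aff = _nifti_affine(series.metadata)
        mag = np.ascontiguousarray(series.magnitude.transpose(2, 1, 0))
        pha = np.ascontiguousarray(series.phase.transpose(2, 1, 0))
        nib.save(nib.Nifti1Image(mag, aff), path / "magnitude.nii.gz")
        nib.save(nib.Nifti1Image(pha, aff), path / "phase.nii.gz")
        sidecar = _metadata_to_sidecar(series.metadata, "flow", series.frames_per_cycle)
    else:  # pragma: no cover - defensive
        raise ConfigError(f"unsupported series type {type(series)!r}")
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return path


def read_series(path, kind: str = "cine") -> RealTimeSeries | FlowSeries:
    """Read a series from a NIfTI+sidecar directory or a DICOM directory.

    Parameters
    ----------
    path : path-like
        Directory containing either the canonical files or classic DICOMs.
    kind : {"cine", "flow"}
        Expected series type.  Flow series are supported in the canonical
        format only (the sidecar is the authoritative carrier of venc).
    """
    path = Path(path)
    if kind not in ("cine", "flow"):
        raise ConfigError(f"unknown series kind {kind!r}")
    if not path.exists():
        raise UnreadableSeriesError(f"{path} does not exist")
    if (path / SIDECAR_NAME).exists():
        return _read_canonical(path, kind)
    if path.is_dir():
        if kind == "flow":
            raise MissingVencError(
                "flow series require the canonical sidecar format (venc unavailable in DICOM reader)"
            )
        return _read_dicom_dir(path)
    raise UnreadableSeriesError(f"{path} is neither a canonical series nor a DICOM directory")


def _read_canonical(path: Path, kind: str):
    sidecar = json.loads((path / SIDECAR_NAME).read_text())
    meta = _sidecar_to_metadata(sidecar)
    if kind == "cine":
        if sidecar.get("kind") != "cine":
            raise UnreadableSeriesError(f"{path} holds a {sidecar.get('kind')} series, not cine")
        img = nib.load(path / "cine.nii.gz")
        data = np.asarray(img.dataobj, dtype=np.float32)
        voxels = data.transpose(2, 3, 1, 0)  # [slice, frame, row, col]
        return RealTimeSeries(voxels=voxels, metadata=meta)
    if sidecar.get("kind") != "flow":
        raise UnreadableSeriesError(f"{path} holds a {sidecar.get('kind')} series, not flow")
    if meta.venc is None:
        raise MissingVencError(f"sidecar in {path} lacks venc_cm_s")
    mag = np.asarray(nib.load(path / "magnitude.nii.gz").dataobj, dtype=np.float32)
    pha = np.asarray(nib.load(path / "phase.nii.gz").dataobj, dtype=np.float32)
    return FlowSeries(
        magnitude=mag.transpose(2, 1, 0),
        phase=pha.transpose(2, 1, 0),
        metadata=meta,
        frames_per_cycle=sidecar.get("frames_per_cycle") or mag.shape[2],
    )


# ---------------------------------------------------------------------------
# DICOM (classic single-frame files)
# ---------------------------------------------------------------------------


def _read_dicom_dir(path: Path) -> RealTimeSeries:
    datasets = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        datasets.append(ds)
    if not datasets:
        raise UnreadableSeriesError(f"no readable DICOM files in {path}")

    # Group frames by slice position, order slices spatially and frames in time;
    # the reader is therefore invariant to the on-disk file order.
    def zpos(ds):
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "SliceLocation", 0.0))

    def ftime(ds):
        if "TriggerTime" in ds:
            return float(ds.TriggerTime)
        return float(getattr(ds, "InstanceNumber", 0))

    groups: dict[float, list] = {}
    for ds in datasets:
        groups.setdefault(round(zpos(ds), 3), []).append(ds)
    zs = sorted(groups)
    counts = {len(v) for v in groups.values()}
    if len(counts) != 1:
        raise InconsistentGeometryError("unequal frame counts across slice positions")
    if len(zs) > 2:
        dz = np.diff(zs)
        if not np.allclose(dz, dz[0], rtol=1e-3, atol=1e-3):
            raise InconsistentGeometryError(f"non-uniform slice spacing {dz}")
    frames_per_slice = counts.pop()

    first = groups[zs[0]][0]
    spacing = tuple(float(v) for v in first.PixelSpacing)
    thickness = float(getattr(first, "SliceThickness", 1.0))
    gap = 0.0
    if len(zs) > 1:
        gap = max(0.0, float(zs[1] - zs[0]) - thickness)
    times = sorted(ftime(ds) for ds in groups[zs[0]])
    frame_duration = float(np.median(np.diff(times))) if len(times) > 1 else 1.0

    stack = np.empty(
        (len(zs), frames_per_slice, int(first.Rows), int(first.Columns)), dtype=np.float32
    )
    for k, z in enumerate(zs):
        for j, ds in enumerate(sorted(groups[z], key=ftime)):
            arr = ds.pixel_array.astype(np.float32)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            inter = float(getattr(ds, "RescaleIntercept", 0.0))
            stack[k, j] = arr * slope + inter

    meta = SeriesMetadata(
        frame_duration=frame_duration,
        pixel_spacing=spacing,
        slice_thickness=thickness,
        slice_gap=gap,
        n_slices=len(zs),
        frames_per_slice=frames_per_slice,
    )
    return RealTimeSeries(voxels=stack, metadata=meta)


def _make_dicom(frame: np.ndarray, meta: SeriesMetadata, z: float, trigger_ms: float,
                instance: int) -> Dataset:
    lo, hi = float(frame.min()), float(frame.max())
    scale = 4095.0 / (hi - lo) if hi > lo else 1.0
    pixels = np.round((frame - lo) * scale).astype(np.uint16)

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = MR_IMAGE_STORAGE
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = MR_IMAGE_STORAGE
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.Rows, ds.Columns = pixels.shape
    ds.PixelSpacing = [meta.pixel_spacing[0], meta.pixel_spacing[1]]
    ds.SliceThickness = meta.slice_thickness
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.SliceLocation = float(z)
    ds.TriggerTime = float(trigger_ms)
    ds.InstanceNumber = int(instance)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 12
    ds.HighBit = 11
    ds.PixelRepresentation = 0
    ds.RescaleSlope = 1.0 / scale
    ds.RescaleIntercept = lo
    ds.PixelData = pixels.tobytes()
    return ds


def write_dicom_series(series: RealTimeSeries, path) -> Path:
    """Export a cine series as classic single-frame DICOMs (one file per frame)."""
    if series.voxels.size == 0:
        raise EmptySeriesError("refusing to write an empty series")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = series.metadata
    inst = 1
    for k in range(series.n_slices):
        z = k * meta.slab
        for j in range(series.frames_per_slice):
            ds = _make_dicom(series.voxels[k, j], meta, z, j * meta.frame_duration, inst)
            ds.save_as(path / f"slice{k:03d}_frame{j:04d}.dcm", enforce_file_format=True)
            inst += 1
    return path


def export_sorted_stack(series: RealTimeSeries, stack, path, fmt: str = "nifti") -> Path:
    """Export the ED and ES frame of every slice of a sorted stack.

    Writes 2 single-frame images per slice (``ed_sNNN``/``es_sNNN``) plus a
    sidecar recording the selected frame indices, ready for volumetric
    analysis in external contouring software.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = series.metadata
    records = []
    inst = 1
    for sel in stack.slices:
        k = sel.slice_index
        for label, j in (("ed", sel.ed_frame), ("es", sel.es_frame)):
            frame = series.voxels[k, j]
            if fmt == "nifti":
                img = nib.Nifti1Image(
                    np.ascontiguousarray(frame.T)[:, :, None], _nifti_affine(meta)[:4, :4]
                )
                nib.save(img, path / f"{label}_s{k:03d}.nii.gz")
            elif fmt == "dicom":
                ds = _make_dicom(frame, meta, k * meta.slab, j * meta.frame_duration, inst)
                ds.save_as(path / f"{label}_s{k:03d}.dcm", enforce_file_format=True)
                inst += 1
            else:
                raise ConfigError(f"unknown export format {fmt!r}")
            records.append({"slice": k, "phase": label, "frame": int(j)})
    sidecar = _metadata_to_sidecar(meta, "cine")
    sidecar["sorted_frames"] = records
    sidecar["respiratory_phase"] = stack.respiratory_phase
    (path / "sorted_stack.json").write_text(json.dumps(sidecar, indent=1))
    return path


__all__ = [
    "SeriesMetadata",
    "RealTimeSeries",
    "FlowSeries",
    "read_series",
    "write_series",
    "write_dicom_series",
    "export_sorted_stack",
]
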