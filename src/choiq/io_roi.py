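"""DICOM series loading and labelled ROI extraction.

Reads a classic single-frame CT series into a HU volume and cuts square ROIs
at configured lesion/background positions, producing the same ROIImage
objects as the synthetic generator so downstream modules are source-agnostic.

DICOM support needs the optional ``pydicom`` dependency
(``pip install choiq[dicom]``); in-memory volumes and ROI extraction work
without it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from choiq.synthetic import ROIImage, SIGNAL_ABSENT, SIGNAL_PRESENT

PHANTOM_SIZES = ("S", "M", "L")


class DicomFormatError(ValueError):
    """A DICOM series is malformed or inconsistent."""


class ROIExtractionError(ValueError):
    """A configured ROI centre cannot be extracted from the volume."""


def apply_rescale(stored: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """HU = stored * slope + intercept."""
    return np.asarray(stored, dtype=float) * slope + intercept


@dataclass
class SeriesVolume:
    """One CT acquisition as a HU voxel volume with geometry and metadata.

    ``origin_mm`` is the (x, y) patient coordinate of voxel (row 0, col 0);
    ``slice_positions_mm`` the per-slice axial coordinate. Axial orientation
    with x along columns and y along rows is assumed.
    """

    voxels: np.ndarray  # (slices, rows, cols), HU
    pixel_spacing_mm: Tuple[float, float]  # (row, col)
    slice_positions_mm: np.ndarray
    origin_mm: Tuple[float, float] = (0.0, 0.0)
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a (slices, rows, cols) array")
        self.slice_positions_mm = np.asarray(self.slice_positions_mm, dtype=float)
        if self.slice_positions_mm.size != self.voxels.shape[0]:
            raise ValueError("one slice position per slice is required")
        if min(self.pixel_spacing_mm) <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class LesionLayout:
    """Configured lesion and background ROI centres for one phantom size."""

    phantom_size: str
    lesion_centres_mm: Tuple[Tuple[float, float, float], ...]
    lesion_diameters_mm: Tuple[float, ...]
    background_centres_mm: Tuple[Tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.phantom_size not in PHANTOM_SIZES:
            raise ValueError(f"phantom_size must be one of {PHANTOM_SIZES}")
        if len(self.lesion_centres_mm) != len(self.lesion_diameters_mm):
            raise ValueError("every lesion centre needs an associated diameter")
        if any(d <= 0 for d in self.lesion_diameters_mm):
            raise ValueError("lesion diameters must be positive")


def load_layout(path) -> LesionLayout:
    """Read a LesionLayout from a YAML config.

    Expected keys: phantom_size, lesions (list of {centre_mm: [x,y,z],
    diameter_mm}), backgrounds (list of {centre_mm: [x,y,z]}).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    lesions = doc.get("lesions", [])
    backgrounds = doc.get("backgrounds", [])
    return LesionLayout(
        phantom_size=doc["phantom_size"],
        lesion_centres_mm=tuple(tuple(map(float, l["centre_mm"])) for l in lesions),
        lesion_diameters_mm=tuple(float(l["diameter_mm"]) for l in lesions),
        background_centres_mm=tuple(
            tuple(map(float, b["centre_mm"])) for b in backgrounds
        ),
    )


_META_TAGS = {
    "scanner_model": "ManufacturerModelName",
    "manufacturer": "Manufacturer",
    "kvp": "KVP",
    "ctdi_vol_mgy": "CTDIvol",
    "reconstruction_fov_mm": "ReconstructionDiameter",
    "slice_thickness_mm": "SliceThickness",
}


def load_series(path) -> SeriesVolume:
    """Load one single-frame CT DICOM series from a directory.

    Slices are sorted by axial position, stored values converted to HU via
    the rescale slope/intercept, and acquisition metadata extracted where
    present (missing fields recorded as ``"unknown"``). Mixed series,
    inconsistent matrix sizes or missing pixel spacing raise
    :class:`DicomFormatError` naming the offending file.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "DICOM reading requires the optional pydicom dependency "
            "(pip install choiq[dicom])"
        ) from exc

    src = Path(path)
    files = sorted(p for p in src.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue  # skip non-DICOM files (manifests etc.)
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append((p, ds))
    if not datasets:
        raise DicomFormatError(f"no DICOM image files found in {src}")

    first_uid = getattr(datasets[0][1], "SeriesInstanceUID", None)
    shape0 = (datasets[0][1].Rows, datasets[0][1].Columns)
    slices = []
    for p, ds in datasets:
        if getattr(ds, "SeriesInstanceUID", None) != first_uid:
            raise DicomFormatError(f"mixed series: {p}")
        if (ds.Rows, ds.Columns) != shape0:
            raise DicomFormatError(f"inconsistent matrix size: {p}")
        if not getattr(ds, "PixelSpacing", None):
            raise DicomFormatError(f"missing pixel spacing: {p}")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = apply_rescale(ds.pixel_array, slope, intercept)
        ipp = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
        slices.append((float(ipp[2]), (float(ipp[0]), float(ipp[1])), hu, ds))

    slices.sort(key=lambda s: s[0])
    ds0 = slices[0][3]
    spacing = (float(ds0.PixelSpacing[0]), float(ds0.PixelSpacing[1]))
    meta = {}
    for key, tag in _META_TAGS.items():
        value = getattr(ds0, tag, None)
        meta[key] = "unknown" if value in (None, "") else value
    return SeriesVolume(
        voxels=np.stack([s[2] for s in slices]),
        pixel_spacing_mm=spacing,
        slice_positions_mm=np.array([s[0] for s in slices]),
        origin_mm=slices[0][1],
        meta=meta,
    )


def _centre_to_indices(
    volume: SeriesVolume, centre_mm: Tuple[float, float, float]
) -> Tuple[int, int, int]:
    """Nearest-voxel (slice, row, col) for a physical (x, y, z) centre."""
    x, y, z = centre_mm
    s = int(np.argmin(np.abs(volume.slice_positions_mm - z)))
    row = int(round((y - volume.origin_mm[1]) / volume.pixel_spacing_mm[0]))
    col = int(round((x - volume.origin_mm[0]) / volume.pixel_spacing_mm[1]))
    return s, row, col


def _cut(volume: SeriesVolume, s: int, row: int, col: int, n: int) -> np.ndarray:
    """Half-open window [c - n//2, c + n - n//2) per in-plane axis."""
    half = n // 2
    r0, r1 = row - half, row - half + n
    c0, c1 = col - half, col - half + n
    _, rows, cols = volume.voxels.shape
    if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
        raise ROIExtractionError(
            f"centre at (slice {s}, row {row}, col {col}) too close to the "
            f"volume border for a {n}x{n} ROI"
        )
    return volume.voxels[s, r0:r1, c0:c1].copy()


def extract_rois(
    volume: SeriesVolume, layout: LesionLayout, roi_size_px: int = 64
) -> List[ROIImage]:
    """One ROI per configured centre, from the slice nearest its z coordinate.

    Signal ROIs are labelled signal_present with their diameter; background
    ROIs signal_absent. Centres too close to the border raise
    :class:`ROIExtractionError` listing the centre.
    """
    if not layout.lesion_centres_mm and not layout.background_centres_mm:
        raise ValueError("layout configures no ROI centres")
    if volume.pixel_spacing_mm[0] != volume.pixel_spacing_mm[1]:
        raise ValueError("anisotropic in-plane spacing is not supported for ROIs")
    spacing = volume.pixel_spacing_mm[0]
    source = str(volume.meta.get("scanner_model", "series"))
    rois: List[ROIImage] = []
    for centre in layout.background_centres_mm:
        s, row, col = _centre_to_indices(volume, centre)
        try:
            px = _cut(volume, s, row, col, roi_size_px)
        except ROIExtractionError as exc:
            raise ROIExtractionError(f"background centre {centre}: {exc}") from None
        rois.append(
            ROIImage(
                pixels=px,
                pixel_spacing_mm=spacing,
                label=SIGNAL_ABSENT,
                source_id=f"{source}:bg@{centre}",
            )
        )
    for centre, diam in zip(layout.lesion_centres_mm, layout.lesion_diameters_mm):
        s, row, col = _centre_to_indices(volume, centre)
        try:
            px = _cut(volume, s, row, col, roi_size_px)
        except ROIExtractionError as exc:
            raise ROIExtractionError(f"lesion centre {centre}: {exc}") from None
        rois.append(
            ROIImage(
                pixels=px,
                pixel_spacing_mm=spacing,
                label=SIGNAL_PRESENT,
                lesion_diameter_mm=diam,
                source_id=f"{source}:lesion@{centre}",
            )
        )
    return rois


def extract_study_rois(
    scans: Sequence[SeriesVolume], layout: LesionLayout, roi_size_px: int = 64
) -> List[ROIImage]:
    """Pool ROIs over repeated scans of one phantom position.

    With the default convention of 9 background and 4 lesion centres per
    scan, 10 scans yield the 90 signal-absent / 40 signal-present design.
    """
    rois: List[ROIImage] = []
    for volume in scans:
        rois.extend(extract_rois(volume, layout, roi_size_px))
    rois.sort(key=lambda r: r.label != SIGNAL_ABSENT)  # absent first, stable
    return rois


def export_dicom(rois: Sequence[ROIImage], out_dir) -> List[Path]:
    """Write ROIs as minimal single-frame CT DICOM files (round-trip testing).

    Requires the optional pydicom dependency.
    """
    try:
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "DICOM export requires the optional pydicom dependency"
        ) from exc

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    paths = []
    for i, roi in enumerate(rois):
        stored = np.round(roi.pixels).astype(np.int16) + 1024
        ds = Dataset()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = stored.shape
        ds.PixelSpacing = [roi.pixel_spacing_mm, roi.pixel_spacing_mm]
        ds.ImagePositionPatient = [0.0, 0.0, float(i)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored.astype("<i2").tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        path = out / f"roi_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
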