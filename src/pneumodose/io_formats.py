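"""Imaging and dosimetry I/O: DICOM CT / RTSTRUCT / RTDOSE, a NIfTI+JSON fixture
dialect, contour rasterization and grid resampling.

Conventions
-----------
All physical coordinates are millimetres on LPS patient axes. Volumes are stored
as ``values[i, j, k]`` with axis 0 = x, axis 1 = y, axis 2 = z; the centre of
voxel ``(i, j, k)`` sits at ``origin_mm + (i, j, k) * spacing_mm`` and the voxel
covers the half-open cube centred on that point. Voxel indices are 0-based.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy.ndimage import map_coordinates

log = logging.getLogger(__name__)

_CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
_RTSTRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"
_RTDOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageGrid:
    """Axis-aligned 3-D scalar volume (CT in HU, dose in Gy)."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3-D array, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D arrays of voxel-centre coordinates along each axis."""
        return tuple(  # type: ignore[return-value]
            self.origin_mm[a] + np.arange(self.shape[a]) * self.spacing_mm[a]
            for a in range(3)
        )

    def extent_mm(self) -> tuple[tuple[float, float], ...]:
        """Physical (low, high) voxel-centre bounds per axis."""
        return tuple(
            (self.origin_mm[a], self.origin_mm[a] + (self.shape[a] - 1) * self.spacing_mm[a])
            for a in range(3)
        )

    def mm_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for an (N, 3) array of mm points."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        return ImageGrid(values, self.spacing_mm, self.origin_mm, self.frame_id)


@dataclass
class ContourSet:
    """Planar polygon stack for one ROI, vertices in mm, constant z per polygon."""

    roi_name: str
    polygons: list[np.ndarray]  # each (n_vertices, 3)

    def __post_init__(self) -> None:
        cleaned = []
        for poly in self.polygons:
            p = np.asarray(poly, dtype=float)
            if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 3:
                raise ValueError("each polygon needs >= 3 (x, y, z) vertices")
            if np.ptp(p[:, 2]) > 1e-6:
                raise ValueError(f"polygon vertices must share one z, got spread {np.ptp(p[:, 2])}")
            cleaned.append(p)
        self.polygons = cleaned


@dataclass
class BinaryMask:
    """Voxelized region on an :class:`ImageGrid` geometry."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_id: str = ""
    roi_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @classmethod
    def from_grid(cls, grid: ImageGrid, voxels: np.ndarray, roi_name: str = "") -> "BinaryMask":
        voxels = np.asarray(voxels, dtype=bool)
        if voxels.shape != grid.shape:
            raise ValueError(f"mask shape {voxels.shape} != grid shape {grid.shape}")
        return cls(voxels, grid.spacing_mm, grid.origin_mm, grid.frame_id, roi_name)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def count(self) -> int:
        return int(self.voxels.sum())


def same_geometry(a, b, tol: float = 1e-6) -> bool:
    """True when two grids/masks share shape, spacing and origin."""
    return (
        tuple(a.shape) == tuple(b.shape)
        and np.allclose(a.spacing_mm, b.spacing_mm, atol=tol)
        and np.allclose(a.origin_mm, b.origin_mm, atol=tol)
    )


def mask_volume_cm3(mask: BinaryMask) -> float:
    """Mask volume in cm^3: voxel count x voxel volume (mm^3) / 1000."""
    return mask.count() * mask.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# DICOM CT series
# ---------------------------------------------------------------------------

def _uid_or_new(frame_id: str) -> str:
    """A DICOM UI value must be digits and dots; map other frame ids to a UID."""
    if frame_id and all(c in "0123456789." for c in frame_id):
        return frame_id
    return generate_uid()


def _base_file_meta(sop_class_uid: str, sop_instance_uid: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = sop_instance_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def write_ct_series(
    grid: ImageGrid,
    directory: str | Path,
    *,
    rescale_slope: float = 1.0,
    rescale_intercept: float = -1024.0,
    series_uid: str | None = None,
) -> list[Path]:
    """Write an ImageGrid as a single-frame DICOM CT series (one file per slice)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    frame_uid = _uid_or_new(grid.frame_id)
    stored = np.round((grid.values - rescale_intercept) / rescale_slope).astype(np.int16)
    paths = []
    for k in range(grid.shape[2]):
        sop_uid = generate_uid()
        ds = FileDataset(None, Dataset(), file_meta=_base_file_meta(_CT_STORAGE, sop_uid),
                         preamble=b"\0" * 128)
        ds.SOPClassUID = _CT_STORAGE
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = "Phantom"
        ds.PatientID = "PHANTOM"
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [grid.origin_mm[0], grid.origin_mm[1],
                                   grid.origin_mm[2] + k * grid.spacing_mm[2]]
        ds.PixelSpacing = [grid.spacing_mm[1], grid.spacing_mm[0]]  # [row, col]
        ds.SliceThickness = grid.spacing_mm[2]
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = grid.shape[1], grid.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = rescale_slope
        ds.RescaleIntercept = rescale_intercept
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        path = directory / f"ct_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_ct_series(path: str | Path) -> ImageGrid:
    """Read a single-frame DICOM CT series into an :class:`ImageGrid` in HU.

    Rescale slope/intercept are applied; slices are ordered by z position.
    Raises on an empty directory, mixed series, or non-uniform slice spacing.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm") if path.is_dir() else []
    if not files:
        raise FileNotFoundError(f"no DICOM files found in {path}")
    slices = [pydicom.dcmread(f) for f in files]
    series = {s.SeriesInstanceUID for s in slices}
    if len(series) != 1:
        raise ValueError(f"directory contains {len(series)} CT series; expected exactly one")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if dz.min() <= 0:
            raise ValueError("duplicate or unordered slice positions")
        if np.ptp(dz) > 0.01 * dz.mean() + 1e-4:
            raise ValueError(f"non-uniform slice spacing: {sorted(set(np.round(dz, 4)))}")
        sz = float(dz.mean())
    else:
        sz = float(getattr(slices[0], "SliceThickness", 1.0))
    first = slices[0]
    sy, sx = (float(v) for v in first.PixelSpacing)
    vols = []
    for s in slices:
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        vols.append(s.pixel_array.astype(np.float64) * slope + intercept)
    # pixel_array rows are y, columns are x -> transpose to (x, y)
    values = np.stack([v.T for v in vols], axis=2)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    return ImageGrid(values, (sx, sy, sz), origin, str(getattr(first, "FrameOfReferenceUID", "")))


# ---------------------------------------------------------------------------
# DICOM RTSTRUCT
# ---------------------------------------------------------------------------

def write_rtstruct(
    contour_sets: list[ContourSet],
    path: str | Path,
    *,
    frame_id: str | None = None,
) -> Path:
    """Write contour sets as a minimal DICOM RT structure set."""
    path = Path(path)
    sop_uid = generate_uid()
    ds = FileDataset(None, Dataset(), file_meta=_base_file_meta(_RTSTRUCT_STORAGE, sop_uid),
                     preamble=b"\0" * 128)
    ds.SOPClassUID = _RTSTRUCT_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.PatientName = "Phantom"
    ds.PatientID = "PHANTOM"
    ds.StructureSetLabel = "pneumodose"
    frame_uid = _uid_or_new(frame_id or "")
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for num, cs in enumerate(contour_sets, start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = cs.roi_name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "MANUAL"
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for poly in cs.polygons:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(poly)
            c.ContourData = [float(v) for v in np.asarray(poly).ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)
    return path


def read_rtstruct(path: str | Path, roi_name: str) -> ContourSet:
    """Read one ROI's planar contours (mm) from a DICOM RT structure set.

    Raises ``KeyError`` naming the available ROIs when ``roi_name`` is absent.
    """
    ds = pydicom.dcmread(path)
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    matches = [num for num, name in names.items() if name == roi_name]
    if not matches:
        raise KeyError(
            f"ROI {roi_name!r} not found; available ROIs: {sorted(names.values())}")
    roi_number = matches[0]
    polygons = []
    for rc in ds.ROIContourSequence:
        if int(rc.ReferencedROINumber) != roi_number:
            continue
        for c in getattr(rc, "ContourSequence", []):
            pts = np.asarray([float(v) for v in c.ContourData], dtype=float)
            if pts.size == 0 or pts.size % 3:
                raise ValueError(f"ROI {roi_name!r}: contour with invalid vertex data")
            polygons.append(pts.reshape(-1, 3))
    return ContourSet(roi_name, polygons)


# ---------------------------------------------------------------------------
# DICOM RTDOSE
# ---------------------------------------------------------------------------

def write_rtdose(grid: ImageGrid, path: str | Path, *, scaling: float = 1e-3) -> Path:
    """Write a dose grid (Gy) as a multi-frame DICOM RTDOSE with the given scaling."""
    path = Path(path)
    sop_uid = generate_uid()
    ds = FileDataset(None, Dataset(), file_meta=_base_file_meta(_RTDOSE_STORAGE, sop_uid),
                     preamble=b"\0" * 128)
    ds.SOPClassUID = _RTDOSE_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTDOSE"
    ds.PatientName = "Phantom"
    ds.PatientID = "PHANTOM"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.FrameOfReferenceUID = _uid_or_new(grid.frame_id)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = list(grid.origin_mm)
    ds.PixelSpacing = [grid.spacing_mm[1], grid.spacing_mm[0]]
    ds.GridFrameOffsetVector = [k * grid.spacing_mm[2] for k in range(grid.shape[2])]
    ds.NumberOfFrames = grid.shape[2]
    ds.Rows, ds.Columns = grid.shape[1], grid.shape[0]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.DoseGridScaling = scaling
    stored = np.round(grid.values / scaling).astype(np.uint32)
    # frames (z) of row-major (y, x) planes
    ds.PixelData = np.ascontiguousarray(np.transpose(stored, (2, 1, 0))).tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def read_rtdose(path: str | Path) -> ImageGrid:
    """Read a DICOM RTDOSE into an :class:`ImageGrid` in Gy."""
    ds = pydicom.dcmread(path)
    if "DoseGridScaling" not in ds:
        raise ValueError("RTDOSE is missing DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    arr = ds.pixel_array.astype(np.float64) * scaling  # (frames, rows, cols)
    if arr.ndim == 2:
        arr = arr[None]
    values = np.transpose(arr, (2, 1, 0))  # -> (x, y, z)
    if values.min() < 0:
        raise ValueError("negative dose values after scaling")
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if len(offsets) > 1:
        dz = np.diff(offsets)
        if np.ptp(dz) > 1e-4:
            raise ValueError("non-uniform dose grid frame offsets")
        sz = float(dz.mean())
    else:
        sz = 1.0
    sy, sx = (float(v) for v in ds.PixelSpacing)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    origin = (origin[0], origin[1], origin[2] + float(offsets[0]))
    return ImageGrid(values, (sx, sy, sz), origin, str(getattr(ds, "FrameOfReferenceUID", "")))


# ---------------------------------------------------------------------------
# NIfTI + JSON fixture dialect
# ---------------------------------------------------------------------------
# Fixture dialect only: the affine maps voxel index -> package LPS mm
# coordinates directly (diagonal spacing + origin); no RAS reinterpretation.

def write_nifti(obj: ImageGrid | BinaryMask, path: str | Path) -> Path:
    path = Path(path)
    if isinstance(obj, BinaryMask):
        data = obj.voxels.astype(np.uint8)
    else:
        data = np.asarray(obj.values, dtype=np.float32)
    affine = np.diag(list(obj.spacing_mm) + [1.0])
    affine[:3, 3] = obj.origin_mm
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def read_nifti(path: str | Path, frame_id: str = "", as_mask: bool = False,
               roi_name: str = "") -> ImageGrid | BinaryMask:
    img = nib.load(str(path))
    affine = img.affine
    if np.abs(affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))).max() > 1e-6:
        raise ValueError("fixture NIfTI must have a diagonal (axis-aligned) affine")
    spacing = tuple(float(affine[a, a]) for a in range(3))
    origin = tuple(float(affine[a, 3]) for a in range(3))
    data = np.asarray(img.dataobj)
    if as_mask:
        return BinaryMask(data > 0.5, spacing, origin, frame_id, roi_name)
    return ImageGrid(np.asarray(data, dtype=np.float64), spacing, origin, frame_id)


def write_json_sidecar(meta: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_json_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def points_in_polygon(xs: np.ndarray, ys: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorized over points.

    ``polygon`` is (n, 2) in mm; the closing edge is implicit. Points exactly on
    an edge follow the half-open crossing convention.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3:
        raise ValueError("polygon needs >= 3 vertices")
    inside = np.zeros(xs.shape, dtype=bool)
    x1, y1 = poly[-1]
    for x2, y2 in poly:
        if y1 != y2:
            crosses = (y1 > ys) != (y2 > ys)
            xint = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (xs < xint)
        x1, y1 = x2, y2
    return inside


def rasterize_contours(contours: ContourSet, grid: ImageGrid) -> BinaryMask:
    """Rasterize planar contours: a voxel is in-mask iff its centre is inside the
    slice polygon(s) by the even-odd rule; multiple polygons on one slice combine
    by exclusive-or (supports holes). Out-of-extent slices are dropped with a warning.
    """
    voxels = np.zeros(grid.shape, dtype=bool)
    xs1d, ys1d, zs1d = grid.voxel_centers_mm()
    X, Y = np.meshgrid(xs1d, ys1d, indexing="ij")
    oz, sz = grid.origin_mm[2], grid.spacing_mm[2]
    dropped = 0
    for poly in contours.polygons:
        z = float(poly[0, 2])
        k = int(round((z - oz) / sz))
        if k < 0 or k >= grid.shape[2] or abs(z - (oz + k * sz)) > sz / 2 + 1e-9:
            dropped += 1
            continue
        voxels[:, :, k] ^= points_in_polygon(X, Y, poly[:, :2])
    if dropped:
        warnings.warn(
            f"{dropped} contour slice(s) of {contours.roi_name!r} outside grid extent; dropped",
            stacklevel=2)
    mask = BinaryMask.from_grid(grid, voxels, contours.roi_name)
    if contours.polygons and mask.count() == 0:
        warnings.warn(f"rasterized mask {contours.roi_name!r} encloses no voxel centres",
                      stacklevel=2)
    return mask


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _target_index_coords(source: ImageGrid, target) -> np.ndarray:
    """Continuous source-index coordinates of the target voxel centres, (3, ...)."""
    axes = [target.origin_mm[a] + np.arange(target.shape[a]) * target.spacing_mm[a]
            for a in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([
        (mesh[a] - source.origin_mm[a]) / source.spacing_mm[a] for a in range(3)
    ])


def coverage_mask(source: ImageGrid, target) -> np.ndarray:
    """Boolean array marking target voxel centres inside the source extent."""
    coords = _target_index_coords(source, target)
    inside = np.ones(coords.shape[1:], dtype=bool)
    for a in range(3):
        inside &= (coords[a] >= 0) & (coords[a] <= source.shape[a] - 1)
    return inside


def resample_to_grid(source: ImageGrid, target: ImageGrid, order: int = 3) -> ImageGrid:
    """Resample ``source`` at the voxel centres of ``target``.

    ``order=3`` (default) interpolates with a cubic B-spline, which is exact
    for constant and affine fields and has far lower bias than trilinear on
    smooth dose penumbras; ``order=1`` gives plain trilinear. Points outside
    the source extent get 0 (for dose: unplanned regions) and their count is
    logged. Raises when the physical extents do not overlap.
    """
    coords = _target_index_coords(source, target)
    inside = coverage_mask(source, target)
    if not inside.any():
        raise ValueError("source and target grids have no overlapping extent")
    values = map_coordinates(np.asarray(source.values, dtype=np.float64), coords,
                             order=order, mode="nearest")
    values[~inside] = 0.0
    n_out = int((~inside).sum())
    if n_out:
        log.info("resample_to_grid: %d of %d target voxels outside source extent (set to 0)",
                 n_out, inside.size)
    return ImageGrid(values, target.spacing_mm, target.origin_mm, target.frame_id)
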