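"""Readers/writers for CT series, structure sets, dose grids, PDD tables and STL.

All file-format dialects live here; the numerics elsewhere see only the in-memory
containers (:class:`CTVolume`, :class:`StructureSet`, :class:`DoseGrid`,
:class:`PDDCurve`).

Coordinate convention: patient coordinates in millimetres. Voxel grids are
0-based with half-open extents ``[origin, origin + n*spacing)``; the centre of
voxel ``i`` is ``origin + (i + 0.5) * spacing``. Arrays are indexed ``[ix, iy, iz]``.
Dose is stored as % of prescription.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import trimesh
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import (
    CTImageStorage,
    ExplicitVRLittleEndian,
    RTDoseStorage,
    RTStructureSetStorage,
    generate_uid,
)
from scipy.ndimage import map_coordinates

from .errors import AlignmentError, FormatError, GeometryError, SerializationError

_HU_MIN, _HU_MAX = -1024, 4000


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class CTVolume:
    """Voxel HU grid with geometry.

    ``voxels[ix, iy, iz]`` holds Hounsfield units; ``origin`` is the corner of
    the half-open volume extent (mm), ``spacing`` the per-axis voxel size (mm).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.voxels.ndim != 3:
            raise GeometryError("CT voxel array must be 3D")
        if not np.all(self.spacing > 0):
            raise GeometryError("CT spacing must be positive on all axes")
        lo, hi = self.voxels.min(), self.voxels.max()
        if lo < _HU_MIN or hi > _HU_MAX:
            raise FormatError(f"HU outside [{_HU_MIN}, {_HU_MAX}]: [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_max(self) -> np.ndarray:
        """Far corner of the half-open volume extent (mm)."""
        return self.origin + np.array(self.shape) * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of world points (voxel centre = integer)."""
        return (np.asarray(points, float) - self.origin) / self.spacing - 0.5

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + (np.asarray(idx, float) + 0.5) * self.spacing

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) world coordinates of all voxel centres, C-order."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.index_to_world(idx)

    def sample_hu(self, points: np.ndarray, outside: float = -1000.0) -> np.ndarray:
        """Nearest-voxel HU at world points; ``outside`` (air) beyond the grid."""
        idx = np.rint(self.world_to_index(points)).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=-1)
        idx_c = np.clip(idx, 0, np.array(self.shape) - 1)
        hu = self.voxels[idx_c[..., 0], idx_c[..., 1], idx_c[..., 2]].astype(float)
        hu[~inside] = outside
        return hu


@dataclass
class StructureSet:
    """Named boolean masks on the CT grid (at least ``PTV`` and ``BODY`` for design)."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise GeometryError("structure masks have inconsistent shapes")
        self.masks = {k: np.asarray(v, bool) for k, v in self.masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def validate_for_design(self) -> None:
        for required in ("PTV", "BODY"):
            if required not in self.masks:
                raise FormatError(f"structure set lacks required ROI {required!r}")
        if np.any(self.masks["PTV"] & ~self.masks["BODY"]):
            raise GeometryError("PTV extends outside BODY")


@dataclass
class DoseGrid:
    """3D dose in % of prescription, aligned to a CT grid."""

    values: np.ndarray
    ct: CTVolume

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.ct.shape:
            raise AlignmentError("dose grid shape differs from CT grid")
        if np.any(self.values < 0):
            raise FormatError("negative dose values")

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear dose at world points (0 outside the grid)."""
        idx = self.ct.world_to_index(points)
        return map_coordinates(self.values, np.atleast_2d(idx).T, order=1,
                               mode="constant", cval=0.0)


@dataclass
class PDDCurve:
    """Central-axis percentage depth dose: depth (mm) vs dose (% of maximum)."""

    depth_mm: np.ndarray
    dose_percent: np.ndarray

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.dose_percent = np.asarray(self.dose_percent, dtype=float)
        if self.depth_mm.size < 10:
            raise FormatError("PDD curve needs at least 10 samples")
        if np.any(np.diff(self.depth_mm) <= 0):
            raise FormatError("PDD depths must be strictly increasing")
        if abs(self.dose_percent.max() - 100.0) > 0.1:
            raise FormatError("PDD maximum must equal 100 within 0.1")

    def __call__(self, z: np.ndarray) -> np.ndarray:
        """Linear interpolation, clamped at the ends."""
        return np.interp(z, self.depth_mm, self.dose_percent)


# ---------------------------------------------------------------------------
# DICOM CT series
# ---------------------------------------------------------------------------

def _file_meta(sop_class, sop_uid) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def write_ct_series(ct: CTVolume, path: str | os.PathLike) -> list[Path]:
    """Write a CT volume as one DICOM file per axial slice. Returns paths."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frame_uid = generate_uid()
    series_uid = generate_uid()
    study_uid = generate_uid()
    nx, ny, nz = ct.shape
    dx, dy, dz = ct.spacing
    first_center = ct.origin + 0.5 * ct.spacing
    out = []
    for k in range(nz):
        sop_uid = generate_uid()
        ds = Dataset()
        ds.file_meta = _file_meta(CTImageStorage, sop_uid)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "PHANTOM"
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [first_center[0], first_center[1],
                                   first_center[2] + k * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dy, dx]  # row spacing, column spacing
        ds.SliceThickness = dz
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = np.ascontiguousarray(
            ct.voxels[:, :, k].T.astype(np.int16)).tobytes()
        fname = path / f"ct_{k:04d}.dcm"
        ds.save_as(fname, enforce_file_format=True)
        out.append(fname)
    return out


def read_ct(path: str | os.PathLike) -> CTVolume:
    """Read a DICOM CT series directory into a :class:`CTVolume`.

    Slices are sorted by position along the slice normal regardless of file
    order; inconsistent inter-slice spacing (> 0.01 mm) raises
    :class:`GeometryError`.
    """
    path = Path(path)
    files = sorted(path.glob("*.dcm")) if path.is_dir() else [path]
    if not files:
        raise FormatError(f"no DICOM files under {path}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(f)
        if getattr(ds, "Modality", "") != "CT":
            continue
        for tag in ("ImagePositionPatient", "ImageOrientationPatient",
                    "PixelSpacing"):
            if tag not in ds:
                raise FormatError(f"{f.name}: missing geometry tag {tag}")
        slices.append(ds)
    if not slices:
        raise FormatError(f"no CT slices under {path}")
    iop = np.asarray(slices[0].ImageOrientationPatient, float)
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise GeometryError("only axial, identity-orientation CT is supported")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zpos = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(slices) > 1:
        dzs = np.diff(zpos)
        if np.ptp(dzs) > 0.01:
            raise GeometryError(
                f"inconsistent inter-slice spacing: range {np.ptp(dzs):.4f} mm")
        dz = float(dzs.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    dy, dx = (float(v) for v in slices[0].PixelSpacing)
    arrs = []
    for s in slices:
        a = s.pixel_array.astype(float)
        a = a * float(getattr(s, "RescaleSlope", 1.0)) + float(
            getattr(s, "RescaleIntercept", 0.0))
        arrs.append(a.T)  # (row=y, col=x) -> (x, y)
    voxels = np.stack(arrs, axis=2).round().astype(np.int16)
    first_center = np.array([float(slices[0].ImagePositionPatient[0]),
                             float(slices[0].ImagePositionPatient[1]),
                             zpos[0]])
    origin = first_center - 0.5 * np.array([dx, dy, dz])
    return CTVolume(voxels=voxels, spacing=np.array([dx, dy, dz]), origin=origin)


# ---------------------------------------------------------------------------
# DICOM RTSTRUCT
# ---------------------------------------------------------------------------

def _fill_ring(poly_xy: np.ndarray, ct: CTVolume) -> np.ndarray:
    """Crossing-number fill of one closed planar ring onto a 2D (x, y) slice mask.

    A voxel belongs to the ring iff its centre lies inside the polygon
    (even-odd/crossing-number rule, half-open on edges).
    """
    nx, ny = ct.shape[0], ct.shape[1]
    cx = ct.origin[0] + (np.arange(nx) + 0.5) * ct.spacing[0]
    cy = ct.origin[1] + (np.arange(ny) + 0.5) * ct.spacing[1]
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    inside = np.zeros((nx, ny), dtype=bool)
    v = np.asarray(poly_xy, float)
    n = len(v)
    for a in range(n):
        x1, y1 = v[a]
        x2, y2 = v[(a + 1) % n]
        if y1 == y2:
            continue
        cond = (Y >= min(y1, y2)) & (Y < max(y1, y2))
        xint = x1 + (Y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (X < xint)
    return inside


def rasterize_contours(contours: list[tuple[float, np.ndarray]],
                       ct: CTVolume) -> np.ndarray:
    """Rasterize closed planar axial contours to a boolean mask on the CT grid.

    ``contours`` is a list of ``(z_mm, (N, 2) xy-vertices)``. Multiple rings on
    one slice combine with the even-odd rule (XOR), so a hole contour carves a
    hole. Raises :class:`AlignmentError` when a contour plane misses every CT
    slice by more than half the slice spacing.
    """
    mask = np.zeros(ct.shape, dtype=bool)
    dz = ct.spacing[2]
    zc = ct.origin[2] + (np.arange(ct.shape[2]) + 0.5) * dz
    for z, poly in contours:
        k = int(np.argmin(np.abs(zc - z)))
        if abs(zc[k] - z) > dz / 2 + 1e-9:
            raise AlignmentError(
                f"contour plane z={z} mm matches no CT slice within {dz / 2} mm")
        mask[:, :, k] ^= _fill_ring(poly, ct)
    return mask


def write_rtstruct(rois: dict[str, list[tuple[float, np.ndarray]]],
                   ct: CTVolume, path: str | os.PathLike) -> Path:
    """Write named axial contour stacks as a DICOM RTSTRUCT file."""
    path = Path(path)
    sop_uid = generate_uid()
    ds = Dataset()
    ds.file_meta = _file_meta(RTStructureSetStorage, sop_uid)
    ds.SOPClassUID = RTStructureSetStorage
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.PatientName = "PHANTOM"
    ds.PatientID = "PHANTOM"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.StructureSetLabel = "mertbolus"
    frame_uid = generate_uid()
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for num, (name, contours) in enumerate(rois.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for z, poly in contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            poly = np.asarray(poly, float)
            c.NumberOfContourPoints = len(poly)
            data = np.column_stack([poly, np.full(len(poly), z)]).ravel()
            c.ContourData = [f"{v:.6f}" for v in data]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)
    return path


def read_structures(path: str | os.PathLike, ct: CTVolume) -> StructureSet:
    """Read a DICOM RTSTRUCT and rasterize each ROI onto the CT grid.

    Contours must be closed, planar and axial; non-axial contours are rejected.
    """
    ds = pydicom.dcmread(path)
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    masks: dict[str, np.ndarray] = {}
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        contours = []
        for c in getattr(rc, "ContourSequence", []):
            if c.ContourGeometricType != "CLOSED_PLANAR":
                raise FormatError(f"{name}: unsupported contour type "
                                  f"{c.ContourGeometricType}")
            pts = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            if np.ptp(pts[:, 2]) > 1e-6:
                raise GeometryError(f"{name}: non-axial contour rejected")
            contours.append((float(pts[0, 2]), pts[:, :2]))
        masks[name] = rasterize_contours(contours, ct)
    return StructureSet(masks=masks)


# ---------------------------------------------------------------------------
# DICOM RTDOSE
# ---------------------------------------------------------------------------

def write_rtdose(values: np.ndarray, spacing: np.ndarray, origin: np.ndarray,
                 path: str | os.PathLike, units: str = "RELATIVE") -> Path:
    """Write a 3D dose array (``[ix, iy, iz]``, same conventions as CT) as RTDOSE."""
    values = np.asarray(values, float)
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    sop_uid = generate_uid()
    ds = Dataset()
    ds.file_meta = _file_meta(RTDoseStorage, sop_uid)
    ds.SOPClassUID = RTDoseStorage
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTDOSE"
    ds.PatientName = "PHANTOM"
    ds.PatientID = "PHANTOM"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.DoseUnits = units
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    nx, ny, nz = values.shape
    scaling = max(values.max(), 1e-9) / (2**31 - 1)
    ds.DoseGridScaling = scaling
    ds.Rows, ds.Columns = ny, nx
    ds.NumberOfFrames = nz
    first_center = origin + 0.5 * spacing
    ds.ImagePositionPatient = list(first_center)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [spacing[1], spacing[0]]
    ds.GridFrameOffsetVector = [k * spacing[2] for k in range(nz)]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    frames = np.transpose(values, (2, 1, 0))  # (z, y, x)
    ds.PixelData = np.ascontiguousarray(
        np.round(frames / scaling).astype(np.uint32)).tobytes()
    ds.save_as(path, enforce_file_format=True)
    return Path(path)


def read_dose(path: str | os.PathLike, ct: CTVolume,
              prescription_cgy: float | None = None) -> DoseGrid:
    """Read DICOM RTDOSE and resample trilinearly onto the CT grid.

    Absolute dose (``DoseUnits`` GY) requires ``prescription_cgy``; the result
    is always % of prescription. Zero spatial overlap raises
    :class:`AlignmentError`.
    """
    ds = pydicom.dcmread(path)
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    frames = ds.pixel_array.astype(float) * scaling  # (z, y, x)
    values = np.transpose(frames, (2, 1, 0))
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    spacing = np.array([dx, dy, dz])
    first_center = np.asarray([float(v) for v in ds.ImagePositionPatient])
    origin = first_center - 0.5 * spacing
    lo = np.maximum(origin, ct.origin)
    hi = np.minimum(origin + np.array(values.shape) * spacing, ct.extent_max)
    if np.any(hi <= lo):
        raise AlignmentError("dose grid does not overlap the CT volume")
    pts = ct.voxel_centers()
    idx = (pts - origin) / spacing - 0.5
    resampled = map_coordinates(values, idx.T, order=1, mode="nearest"
                                ).reshape(ct.shape)
    units = str(getattr(ds, "DoseUnits", "RELATIVE")).upper()
    if units == "GY":
        if prescription_cgy is None:
            raise FormatError("absolute dose requires prescription_cgy")
        resampled = resampled * 100.0 * 100.0 / prescription_cgy  # Gy→cGy→%
    return DoseGrid(values=resampled, ct=ct)


# ---------------------------------------------------------------------------
# STL and PDD tables
# ---------------------------------------------------------------------------

def write_stl(mesh: trimesh.Trimesh, path: str | os.PathLike) -> Path:
    """Write a triangulated solid as binary little-endian STL (units mm).

    File layout per the standard: 80-byte header, uint32 triangle count, then
    50 bytes per triangle. Normals are recomputed from counter-clockwise
    vertex winding.
    """
    if not np.all(np.isfinite(mesh.vertices)):
        raise SerializationError("mesh contains non-finite vertices")
    path = Path(path)
    path.write_bytes(trimesh.exchange.stl.export_stl(mesh))
    return path


def read_stl(path: str | os.PathLike) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), file_type="stl", process=False)
    return mesh


def write_pdd_csv(curve: PDDCurve, path: str | os.PathLike) -> Path:
    path = Path(path)
    rows = "\n".join(f"{z:.4f},{d:.6f}"
                     for z, d in zip(curve.depth_mm, curve.dose_percent))
    path.write_text("depth_mm,dose_percent\n" + rows + "\n")
    return path


def read_pdd_csv(path: str | os.PathLike) -> PDDCurve:
    data = np.genfromtxt(path, delimiter=",", names=True)
    if data.dtype.names is None or set(data.dtype.names) < {"depth_mm",
                                                            "dose_percent"}:
        raise FormatError("PDD CSV must have header depth_mm,dose_percent")
    return PDDCurve(depth_mm=data["depth_mm"], dose_percent=data["dose_percent"])
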