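"""Reading and writing dose grids and structures.

Two on-disk representations are supported:

* DICOM RT Dose / RT Structure Set via :mod:`pydicom` — the clinical route.
  Only axis-aligned orientations are accepted; oblique grids are rejected at
  read time because the tolerance analysis needs only cardinal translations.
* A self-contained *fixture bundle*: a JSON header (geometry, structure names,
  constraint strings) followed by raw little-endian float32 dose and uint8 mask
  arrays in C order.  Fixtures round-trip bit-exactly and keep the test suite
  free of clinical data.

Internally arrays are indexed ``[i, j, k]`` along (x, y, z); DICOM pixel data
is ``(frame, row, col) = (z, y, x)`` and is transposed on the way through.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
from matplotlib.path import Path as MplPath

from .grid import BinaryMask, DoseGrid, GridGeometry

log = logging.getLogger(__name__)

_AXIAL_ORIENT = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)
_MAGIC = b"MTFIX1\n"


class DicomFormatError(ValueError):
    """Raised when a DICOM object lacks a required attribute or geometry."""


@dataclass
class PlanarContour:
    """One closed planar polygon at slice position ``z`` (mm).

    Vertices are (x, y) pairs in patient mm; the first vertex is not repeated.
    """

    z: float
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise ValueError("a planar contour needs at least 3 vertices")


@dataclass
class Structure:
    """A named organ-at-risk, as planar contours and/or a binary mask."""

    name: str
    contours: list[PlanarContour] = field(default_factory=list)
    mask: BinaryMask | None = None

    def __post_init__(self) -> None:
        if not self.contours and self.mask is None:
            raise ValueError(f"structure {self.name!r} has neither contours nor mask")

    @property
    def volume_cc(self) -> float:
        if self.mask is None:
            raise ValueError(f"structure {self.name!r} has no rasterized mask yet")
        return self.mask.volume_cc


def rasterize(structure: Structure, geometry: GridGeometry) -> BinaryMask:
    """Rasterize planar contours onto a grid with the even-odd fill rule.

    A voxel is inside if its *center* is inside the slice's polygon set
    (no partial-volume weighting).  Each contour is assigned to the nearest
    grid slice; contours farther than half a slice spacing from every slice
    are dropped with a warning.  Nested contours XOR, so holes are excluded.
    """
    if not structure.contours:
        raise ValueError(f"structure {structure.name!r} has no contours to rasterize")
    nx, ny, nz = geometry.dims
    bits = np.zeros((nx, ny, nz), dtype=bool)
    xs = geometry.axis_coords(0)
    ys = geometry.axis_coords(1)
    zs = geometry.axis_coords(2)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    half_dz = geometry.spacing[2] / 2.0
    for c in structure.contours:
        k = int(np.argmin(np.abs(zs - c.z)))
        if abs(zs[k] - c.z) > half_dz + 1e-9:
            log.warning(
                "contour of %r at z=%.2f mm is off-grid (nearest slice %.2f mm); dropped",
                structure.name, c.z, zs[k],
            )
            continue
        inside = MplPath(c.vertices).contains_points(centers).reshape(nx, ny)
        bits[:, :, k] ^= inside  # even-odd: nested contours carve holes
    mask = BinaryMask(geometry, bits)
    structure.mask = mask
    return mask


# --------------------------------------------------------------------------
# DICOM RT Dose
# --------------------------------------------------------------------------

def read_rtdose(path: str | FsPath) -> DoseGrid:
    """Read a DICOM RT Dose file into a :class:`DoseGrid` (Gy).

    Pixel values are multiplied by DoseGridScaling.  The orientation must be
    the identity axial orientation and GridFrameOffsetVector must be uniform.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    orient = tuple(round(float(v), 6) for v in getattr(ds, "ImageOrientationPatient", ()))
    if orient != _AXIAL_ORIENT:
        raise DicomFormatError(
            f"ImageOrientationPatient {orient} is not axis-aligned axial; only "
            "identity orientation is supported"
        )
    if "DoseGridScaling" not in ds:
        raise DicomFormatError("missing DoseGridScaling")
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if len(offsets) < 2:
        raise DicomFormatError("GridFrameOffsetVector must have >= 2 frames")
    dz = np.diff(offsets)
    if not np.allclose(dz, dz[0], atol=1e-6):
        raise DicomFormatError("GridFrameOffsetVector is non-uniform")
    if dz[0] <= 0:
        raise DicomFormatError("GridFrameOffsetVector must be increasing")
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # row = y, col = x
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    arr = ds.pixel_array.astype(np.float64) * float(ds.DoseGridScaling)
    # (frame, row, col) = (z, y, x) -> (x, y, z)
    values = np.ascontiguousarray(arr.transpose(2, 1, 0))
    geom = GridGeometry(origin, (col_sp, row_sp, float(dz[0])), values.shape)
    return DoseGrid(geom, values)


def write_rtdose(path: str | FsPath, dose: DoseGrid) -> None:
    """Write a minimal axial RT Dose file (fixture writer, 32-bit, Gy)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.2")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseSummationType = "PLAN"
    ds.PatientName = "FIXTURE^PHANTOM"
    ds.PatientID = "FIXTURE"

    geom = dose.geometry
    nx, ny, nz = geom.dims
    vmax = float(dose.values.max())
    scaling = max(vmax, 1e-9) / (2**32 - 1)
    stored = np.round(dose.values / scaling).astype(np.uint32)

    ds.ImageOrientationPatient = list(_AXIAL_ORIENT)
    ds.ImagePositionPatient = list(geom.origin)
    ds.PixelSpacing = [geom.spacing[1], geom.spacing[0]]  # [row=y, col=x]
    ds.GridFrameOffsetVector = [geom.spacing[2] * k for k in range(nz)]
    ds.DoseGridScaling = scaling
    ds.Rows, ds.Columns, ds.NumberOfFrames = ny, nx, nz
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(stored.transpose(2, 1, 0)).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# --------------------------------------------------------------------------
# DICOM RT Structure Set
# --------------------------------------------------------------------------

def read_rtstruct(path: str | FsPath) -> list[Structure]:
    """Read an RT Structure Set into Structures with planar contours (mm LPS)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    structures: list[Structure] = []
    for roi_c in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(roi_c.ReferencedROINumber), f"ROI{roi_c.ReferencedROINumber}")
        contours: list[PlanarContour] = []
        for item in getattr(roi_c, "ContourSequence", []):
            pts = np.asarray([float(v) for v in item.ContourData]).reshape(-1, 3)
            contours.append(PlanarContour(z=float(pts[0, 2]), vertices=pts[:, :2]))
        if not contours:
            log.warning("ROI %r has no contours; skipped", name)
            continue
        structures.append(Structure(name=name, contours=contours))
    if not structures:
        log.warning("structure set %s contains no contoured ROIs", path)
    return structures


def write_rtstruct(path: str | FsPath, structures: list[Structure]) -> None:
    """Write a minimal RT Structure Set (fixture writer)."""
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.sequence import Sequence
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientName = "FIXTURE^PHANTOM"
    ds.PatientID = "FIXTURE"
    ds.StructureSetROISequence = Sequence()
    ds.ROIContourSequence = Sequence()
    for num, s in enumerate(structures, start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = s.name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = Sequence()
        for c in s.contours:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = len(c.vertices)
            data = np.column_stack([c.vertices, np.full(len(c.vertices), c.z)])
            item.ContourData = [f"{v:.6f}" for v in data.ravel()]
            rc.ContourSequence.append(item)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)


# --------------------------------------------------------------------------
# Fixture bundle
# --------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """Dose grid + named masks + constraint strings as one on-disk unit."""

    dose: DoseGrid
    masks: dict[str, BinaryMask]
    constraints: list[str] = field(default_factory=list)


def write_fixture(path: str | FsPath, bundle: FixtureBundle) -> None:
    """Serialize a bundle: JSON header, then raw float64 dose + uint8 masks.

    Dose is stored at full double precision so write/read round-trips are
    bit-exact for any in-memory grid.
    """
    geom = bundle.dose.geometry
    header = {
        "origin": list(geom.origin),
        "spacing": list(geom.spacing),
        "dims": list(geom.dims),
        # masks may live on a different (e.g. imaging-resolution) grid
        "structures": [
            {
                "name": name,
                "origin": list(m.geometry.origin),
                "spacing": list(m.geometry.spacing),
                "dims": list(m.geometry.dims),
            }
            for name, m in bundle.masks.items()
        ],
        "constraints": bundle.constraints,
    }
    hjson = json.dumps(header).encode()
    with open(path, "wb") as f:
        f.write(_MAGIC)
        f.write(struct.pack("<I", len(hjson)))
        f.write(hjson)
        f.write(bundle.dose.values.astype("<f8").tobytes(order="C"))
        for m in bundle.masks.values():
            f.write(m.bits.astype(np.uint8).tobytes(order="C"))


def read_fixture(path: str | FsPath) -> FixtureBundle:
    with open(path, "rb") as f:
        if f.read(len(_MAGIC)) != _MAGIC:
            raise ValueError(f"{path} is not a fixture bundle")
        (hlen,) = struct.unpack("<I", f.read(4))
        header = json.loads(f.read(hlen).decode())
        geom = GridGeometry(header["origin"], header["spacing"], header["dims"])
        n = int(np.prod(geom.dims))
        dose_vals = np.frombuffer(f.read(8 * n), dtype="<f8").astype(np.float64)
        dose = DoseGrid(geom, dose_vals.reshape(geom.dims))
        masks = {}
        for s in header["structures"]:
            sgeom = GridGeometry(s["origin"], s["spacing"], s["dims"])
            sn = int(np.prod(sgeom.dims))
            bits = np.frombuffer(f.read(sn), dtype=np.uint8).astype(bool)
            masks[s["name"]] = BinaryMask(sgeom, bits.reshape(sgeom.dims))
    return FixtureBundle(dose=dose, masks=masks, constraints=list(header["constraints"]))
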