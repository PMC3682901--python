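"""DICOM-RT input/output and analysis-report serialization.

Readers return the internal data model (:class:`~rtrecur.geometry.ImageVolume`,
:class:`~rtrecur.structures.ROI`); writers emit genuine DICOM so the phantom
fixtures exercise the same parsing paths as clinical data.  Everything is in
DICOM patient coordinates (LPS, mm).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .geometry import ImageVolume
from .structures import ROI, Contour

__all__ = [
    "read_ct_series",
    "read_rtstruct",
    "read_rtdose",
    "write_ct_series",
    "write_rtstruct",
    "write_rtdose",
    "write_report",
    "read_report",
    "UIDFactory",
]

_CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
_RTSTRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"
_RTDOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"
_IMPLEMENTATION_UID = "1.2.826.0.1.3680043.8.498.1"
_FIXED_DATE = "20130101"

SLICE_GAP_TOL_MM = 1e-3


class UIDFactory:
    """Deterministic DICOM UID generator: identical seed => identical UIDs."""

    def __init__(self, seed: int = 0):
        self._root = f"2.25.{int(seed) % (2**31) + 1}"
        self._count = 0

    def __call__(self) -> str:
        self._count += 1
        return f"{self._root}.{self._count}"


# ---------------------------------------------------------------------------
# CT series
# ---------------------------------------------------------------------------

def read_ct_series(directory) -> ImageVolume:
    """Read one coherent axial CT series from a directory of DICOM files.

    Slices are sorted by their physical position along the slice normal; the
    HU rescale (slope/intercept) is applied.  Mixed frames of reference or an
    irregular inter-slice gap (beyond 1e-3 mm) raise ``ValueError``.
    """
    directory = Path(directory)
    datasets = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue
        if getattr(ds, "Modality", None) == "CT":
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no CT slices found in {directory}")

    frames = {getattr(ds, "FrameOfReferenceUID", "") for ds in datasets}
    if len(frames) > 1:
        raise ValueError(f"mixed frames of reference in CT series: {sorted(frames)}")
    frame = frames.pop()

    iop = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)

    positions = np.array(
        [np.asarray(ds.ImagePositionPatient, dtype=float) for ds in datasets]
    )
    along = positions @ normal
    order = np.argsort(along)
    datasets = [datasets[i] for i in order]
    positions = positions[order]
    along = along[order]

    if len(datasets) > 1:
        gaps = np.diff(along)
        gap = float(np.median(gaps))
        worst = float(np.max(np.abs(gaps - gap)))
        if worst > SLICE_GAP_TOL_MM:
            raise ValueError(
                "irregular slice spacing in CT series: inter-slice gaps deviate "
                f"by up to {worst:.3f} mm from the median gap {gap:.3f} mm"
            )
        slice_spacing = gap
    else:
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 1.0))

    pixel_spacing = np.asarray(datasets[0].PixelSpacing, dtype=float)  # (row, col)
    spacing = np.array([pixel_spacing[1], pixel_spacing[0], slice_spacing])

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    voxels = np.stack(slices, axis=0)

    orientation = np.column_stack([row_dir, col_dir, normal])
    return ImageVolume(
        voxels=voxels,
        origin=positions[0],
        spacing=spacing,
        orientation=orientation,
        frame_of_reference_id=frame,
    )


def write_ct_series(
    volume: ImageVolume,
    directory,
    *,
    uid_factory: UIDFactory | None = None,
    patient_id: str = "PHANTOM",
    series_description: str = "synthetic CT",
    study_uid: str | None = None,
) -> list[Path]:
    """Write an ImageVolume as a per-slice DICOM CT series (int16 HU)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    uid_factory = uid_factory or UIDFactory(0)
    study_uid = study_uid or uid_factory()
    series_uid = uid_factory()
    frame = volume.frame_of_reference_id or uid_factory()

    nz, ny, nx = volume.shape
    paths = []
    for k in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = _CT_STORAGE
        sop_uid = uid_factory()
        meta.MediaStorageSOPInstanceUID = sop_uid
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        meta.ImplementationClassUID = _IMPLEMENTATION_UID

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = _CT_STORAGE
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.PatientName = patient_id
        ds.PatientID = patient_id
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.SeriesDescription = series_description
        ds.FrameOfReferenceUID = frame
        ds.StudyDate = _FIXED_DATE
        ds.SeriesDate = _FIXED_DATE
        ds.ContentDate = _FIXED_DATE
        ds.StudyTime = "000000"
        ds.ContentTime = "000000"
        ds.StudyID = "1"
        ds.SeriesNumber = 1
        ds.InstanceNumber = k + 1
        ds.AccessionNumber = ""
        ds.ReferringPhysicianName = ""
        ds.PatientBirthDate = ""
        ds.PatientSex = "O"

        origin_k = volume.index_to_physical([0.0, 0.0, float(k)])
        ds.ImagePositionPatient = [float(f"{v:.6f}") for v in origin_k]
        ds.ImageOrientationPatient = [
            float(f"{v:.8f}")
            for v in np.concatenate([volume.orientation[:, 0], volume.orientation[:, 1]])
        ]
        ds.PixelSpacing = [
            float(f"{volume.spacing[1]:.6f}"),
            float(f"{volume.spacing[0]:.6f}"),
        ]
        ds.SliceThickness = float(f"{volume.spacing[2]:.6f}")

        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows = ny
        ds.Columns = nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed: HU stored directly
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.RescaleType = "HU"
        ds.PixelData = (
            np.round(volume.voxels[k]).astype(np.int16).tobytes()
        )

        path = directory / f"ct_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# RT structure sets
# ---------------------------------------------------------------------------

def read_rtstruct(path, frame_of_reference: str | None = None) -> list[ROI]:
    """Read a DICOM RT Structure Set into a list of ROIs (vertices in mm).

    If ``frame_of_reference`` is given and the structure set references a
    different frame, a warning is emitted and every ROI is flagged
    ``frame-of-reference-mismatch`` — never a silent pass.
    """
    ds = pydicom.dcmread(path)
    referenced_frames = set()
    for item in getattr(ds, "ReferencedFrameOfReferenceSequence", []):
        referenced_frames.add(str(item.FrameOfReferenceUID))

    mismatch = False
    if frame_of_reference is not None and referenced_frames:
        if frame_of_reference not in referenced_frames:
            mismatch = True
            warnings.warn(
                "structure set references frame(s) "
                f"{sorted(referenced_frames)}, expected {frame_of_reference}",
                UserWarning,
                stacklevel=2,
            )

    names = {}
    frames_by_number = {}
    for item in getattr(ds, "StructureSetROISequence", []):
        names[int(item.ROINumber)] = str(item.ROIName)
        frames_by_number[int(item.ROINumber)] = str(
            getattr(item, "ReferencedFrameOfReferenceUID", "")
        )

    rois = []
    for item in getattr(ds, "ROIContourSequence", []):
        number = int(item.ReferencedROINumber)
        contours = []
        for c in getattr(item, "ContourSequence", []):
            data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            if len(data) >= 3:
                contours.append(Contour(data))
        roi = ROI(
            name=names.get(number, f"ROI-{number}"),
            contours=contours,
            frame_of_reference_id=frames_by_number.get(number, ""),
        )
        if mismatch:
            roi.flags.append("frame-of-reference-mismatch")
        if not contours:
            roi.flags.append("empty-structure")
        rois.append(roi)
    return rois


def write_rtstruct(
    rois: list[ROI],
    path,
    *,
    frame_of_reference: str,
    uid_factory: UIDFactory | None = None,
    patient_id: str = "PHANTOM",
) -> Path:
    """Write ROIs as a DICOM RT Structure Set (CLOSED_PLANAR contours)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    uid_factory = uid_factory or UIDFactory(0)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTSTRUCT_STORAGE
    sop_uid = uid_factory()
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = _IMPLEMENTATION_UID

    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = _RTSTRUCT_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.PatientName = patient_id
    ds.PatientID = patient_id
    ds.StudyInstanceUID = uid_factory()
    ds.SeriesInstanceUID = uid_factory()
    ds.StructureSetLabel = "synthetic"
    ds.StructureSetDate = _FIXED_DATE
    ds.StructureSetTime = "000000"
    ds.StudyDate = _FIXED_DATE
    ds.StudyTime = "000000"
    ds.StudyID = "1"
    ds.SeriesNumber = 1
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"

    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = frame_of_reference
    ds.ReferencedFrameOfReferenceSequence = [ref_frame]

    ss_items, contour_items, obs_items = [], [], []
    for number, roi in enumerate(rois, start=1):
        ss = Dataset()
        ss.ROINumber = number
        ss.ROIName = roi.name
        ss.ReferencedFrameOfReferenceUID = frame_of_reference
        ss.ROIGenerationAlgorithm = "AUTOMATIC"
        ss_items.append(ss)

        rc = Dataset()
        rc.ReferencedROINumber = number
        seq = []
        for contour in roi.contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(contour.vertices)
            # 4 decimals keeps the DS strings short and round-trips to 1e-3 mm
            c.ContourData = [float(f"{v:.4f}") for v in contour.vertices.ravel()]
            seq.append(c)
        rc.ContourSequence = seq
        contour_items.append(rc)

        ob = Dataset()
        ob.ObservationNumber = number
        ob.ReferencedROINumber = number
        ob.RTROIInterpretedType = ""
        ob.ROIInterpreter = ""
        obs_items.append(ob)

    ds.StructureSetROISequence = ss_items
    ds.ROIContourSequence = contour_items
    ds.RTROIObservationsSequence = obs_items
    ds.save_as(path, enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# RT dose
# ---------------------------------------------------------------------------

def read_rtdose(path) -> ImageVolume:
    """Read a DICOM RT Dose grid; voxel values are absolute Gy.

    A missing ``DoseGridScaling`` raises; a summation type describing a
    composite/sum plan flags the volume ``sum-plan`` (per-plan analysis is
    then impossible and downstream stages skip it).
    """
    ds = pydicom.dcmread(path)
    if "DoseGridScaling" not in ds:
        raise ValueError(f"RT dose {path} has no DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    arr = ds.pixel_array.astype(np.float64) * scaling
    if arr.ndim == 2:
        arr = arr[None]

    iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    origin = np.asarray(ds.ImagePositionPatient, dtype=float)

    offsets = np.asarray(getattr(ds, "GridFrameOffsetVector", [0.0]), dtype=float)
    if len(offsets) > 1:
        gaps = np.diff(offsets)
        if np.max(np.abs(gaps - gaps[0])) > SLICE_GAP_TOL_MM:
            raise ValueError("non-uniform dose grid frame offsets")
        dz = float(gaps[0])
    else:
        dz = float(getattr(ds, "SliceThickness", 1.0) or 1.0)
    origin = origin + normal * offsets[0]

    pixel_spacing = np.asarray(ds.PixelSpacing, dtype=float)
    spacing = np.array([pixel_spacing[1], pixel_spacing[0], abs(dz)])

    flags = []
    summation = str(getattr(ds, "DoseSummationType", "PLAN")).upper()
    if summation in {"MULTI_PLAN", "COMPOSITE"} or (
        len(getattr(ds, "ReferencedRTPlanSequence", [])) > 1
    ):
        flags.append("sum-plan")

    return ImageVolume(
        voxels=arr,
        origin=origin,
        spacing=spacing,
        orientation=np.column_stack([row_dir, col_dir, normal]),
        frame_of_reference_id=str(getattr(ds, "FrameOfReferenceUID", "")),
        flags=flags,
    )


def write_rtdose(
    volume: ImageVolume,
    path,
    *,
    uid_factory: UIDFactory | None = None,
    patient_id: str = "PHANTOM",
    summation_type: str = "PLAN",
) -> Path:
    """Write a dose ImageVolume (Gy) as a multi-frame DICOM RT Dose."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    uid_factory = uid_factory or UIDFactory(0)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_STORAGE
    sop_uid = uid_factory()
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = _IMPLEMENTATION_UID

    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = _RTDOSE_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTDOSE"
    ds.PatientName = patient_id
    ds.PatientID = patient_id
    ds.StudyInstanceUID = uid_factory()
    ds.SeriesInstanceUID = uid_factory()
    ds.FrameOfReferenceUID = volume.frame_of_reference_id or uid_factory()
    ds.StudyDate = _FIXED_DATE
    ds.StudyTime = "000000"
    ds.StudyID = "1"
    ds.SeriesNumber = 1
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"

    nz, ny, nx = volume.shape
    dose_max = float(np.max(volume.voxels)) if volume.voxels.size else 0.0
    scaling = max(dose_max, 1e-6) / (2**31)
    stored = np.round(volume.voxels / scaling).astype(np.uint32)

    ds.ImagePositionPatient = [float(f"{v:.6f}") for v in volume.origin]
    ds.ImageOrientationPatient = [
        float(f"{v:.8f}")
        for v in np.concatenate([volume.orientation[:, 0], volume.orientation[:, 1]])
    ]
    ds.PixelSpacing = [
        float(f"{volume.spacing[1]:.6f}"),
        float(f"{volume.spacing[0]:.6f}"),
    ]
    ds.GridFrameOffsetVector = [
        float(f"{volume.spacing[2] * k:.6f}") for k in range(nz)
    ]
    ds.SliceThickness = float(f"{volume.spacing[2]:.6f}")

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.NumberOfFrames = nz
    ds.Rows = ny
    ds.Columns = nx
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = summation_type
    ds.DoseGridScaling = scaling
    ds.PixelData = stored.tobytes()

    ds.save_as(path, enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(report, path, format: str = "csv") -> Path:
    """Serialize a RecurrenceReport row with fixed 2-decimal precision.

    Missing values (e.g. the boost columns of a case with no boost plan) are
    written as explicit nulls, never dropped.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    row = report.to_row()
    if format == "csv":
        import pandas as pd

        frame = pd.DataFrame([row])
        frame.to_csv(path, index=False, na_rep="")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(row, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path) -> dict:
    """Parse a report written by :func:`write_report` back into a dict."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return json.load(fh)
    import pandas as pd

    frame = pd.read_csv(path)
    row = frame.iloc[0].to_dict()
    return {k: (None if pd.isna(v) else v) for k, v in row.items()}
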