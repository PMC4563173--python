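"""Volume I/O and physical-space plumbing.

A :class:`VoxelGrid` is the in-memory container used throughout the package:
a 3-D scalar field (Hounsfield units for CT, Bq/ml or SUV for PET) together
with its voxel spacing and physical origin in millimetres.  Grids are kept
axis-aligned: the NIfTI affine is the diagonal spacing matrix plus the origin
translation, which is sufficient for co-registered whole-body PET/CT pairs
and keeps resampling exact and cheap.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "VoxelGrid",
    "SuvCalibration",
    "F18_HALF_LIFE_MIN",
    "read_volume",
    "write_volume",
    "resample_to_grid",
    "compute_suv",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

Role = Literal["CT", "PET", "mask"]


@dataclass
class VoxelGrid:
    """A 3-D scalar volume with physical spacing and origin.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar field. Hounsfield units for CT-role grids; Bq/ml or SUV for
        PET-role grids; {0,1} integers or booleans for masks.
    spacing : 3-tuple of float
        Voxel edge length along each axis, in mm. Strictly positive.
    origin : 3-tuple of float
        Physical position of voxel (0, 0, 0), in mm.
    role : str
        One of ``"CT"``, ``"PET"``, ``"mask"``. Informational; used for
        contract checks (e.g. SUV conversion requires a PET grid).
    axcodes : str
        Anatomical orientation tag of the three axes (default ``"RAS"``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "CT"
    axcodes: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError(
                f"VoxelGrid data must be non-empty and 3-dimensional, "
                f"got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError(f"origin must have three components, got {self.origin}")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-physical affine (diagonal spacing + origin)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_data(self, data: np.ndarray, role: str | None = None) -> "VoxelGrid":
        """New grid sharing this geometry with different voxel values."""
        return replace(self, data=np.asarray(data), role=role or self.role)

    def physical_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) corners of the volume's bounding box in mm.

        Bounds run from the centre of the first voxel to the centre of the
        last one, which is what matters for interpolation support.
        """
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi


@dataclass(frozen=True)
class SuvCalibration:
    """Calibration data for body-weight SUV conversion.

    Attributes
    ----------
    injected_activity_mbq : float
        Injected tracer activity at injection time, MBq.
    injection_to_scan_min : float
        Interval between injection and scan start, minutes.
    patient_weight_kg : float
        Patient body weight, kg.
    isotope_half_life_min : float
        Physical half-life of the isotope, minutes. Defaults to fluorine-18.
    """

    injected_activity_mbq: float
    injection_to_scan_min: float
    patient_weight_kg: float
    isotope_half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        for name in (
            "injected_activity_mbq",
            "injection_to_scan_min",
            "patient_weight_kg",
            "isotope_half_life_min",
        ):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"SuvCalibration.{name} must be strictly positive, got {value}")

    @property
    def decay_factor(self) -> float:
        """Fraction of activity remaining at scan time, 2**(-t / T_half)."""
        return 2.0 ** (-self.injection_to_scan_min / self.isotope_half_life_min)


# -- file I/O ---------------------------------------------------------------


def read_volume(path: str | os.PathLike, role: str = "CT") -> VoxelGrid:
    """Read a NIfTI file or DICOM series directory into a :class:`VoxelGrid`.

    NIfTI volumes must be axis-aligned (diagonal affine up to sign); DICOM
    series are sorted by slice position along the slice normal and must have
    uniform slice spacing.

    Raises
    ------
    ValueError
        For non-3D data, non-axis-aligned affines, or a DICOM series with
        missing/irregular slices. The message names the defect.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path, role)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValueError(f"unreadable volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D data, got {data.ndim}-D shape {data.shape}")
    aff = img.affine
    rot = aff[:3, :3]
    # accept diagonal affines (with possible axis sign flips)
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-4 * max(1.0, np.max(np.abs(rot))):
        raise ValueError(
            f"{path}: non-axis-aligned affine; this pipeline requires axis-aligned volumes"
        )
    spacing = tuple(float(abs(d)) for d in np.diag(rot))
    if any(s == 0 for s in spacing):
        raise ValueError(f"{path}: degenerate affine with zero spacing")
    origin = tuple(float(v) for v in aff[:3, 3])
    try:
        axcodes = "".join(nib.aff2axcodes(aff))
    except Exception:
        axcodes = "RAS"
    return VoxelGrid(data=data, spacing=spacing, origin=origin, role=role, axcodes=axcodes)


def write_volume(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a grid as NIfTI; header reproduces spacing and origin.

    Boolean masks are stored as {0,1} uint8 volumes so any NIfTI reader can
    load them.
    """
    path = Path(path)
    if not path.parent.exists():
        raise ValueError(f"parent directory does not exist: {path.parent}")
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def _read_dicom_series(directory: Path, role: str) -> VoxelGrid:
    """Assemble a sorted DICOM series into one 3-D grid.

    Slices are ordered by the projection of ImagePositionPatient onto the
    slice normal; a missing slice shows up as an inconsistent step and is
    rejected.
    """
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() != ".txt")
    if not files:
        raise ValueError(f"no DICOM files found in {directory}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:
            raise ValueError(f"unreadable DICOM file {f}: {exc}") from exc
        if not hasattr(ds, "PixelData"):
            continue
        slices.append(ds)
    if not slices:
        raise ValueError(f"no image slices in DICOM directory {directory}")

    orient = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = orient[:3], orient[3:]
    normal = np.cross(row_dir, col_dir)
    positions = np.array(
        [float(np.dot(normal, np.asarray(ds.ImagePositionPatient, dtype=float))) for ds in slices]
    )
    order = np.argsort(positions)
    slices = [slices[i] for i in order]
    positions = positions[order]

    if len(slices) > 1:
        steps = np.diff(positions)
        if np.any(steps <= 0):
            raise ValueError(f"duplicate slice positions in DICOM series {directory}")
        if (steps.max() - steps.min()) > 0.01 * steps.mean():
            raise ValueError(
                f"inconsistent slice spacing in DICOM series {directory}: "
                f"steps range {steps.min():.4g}..{steps.max():.4g} mm "
                f"(a slice may be missing)"
            )
        slice_spacing = float(steps.mean())
    else:
        slice_spacing = float(getattr(slices[0], "SliceThickness", 1.0))

    row_spacing, col_spacing = (float(v) for v in slices[0].PixelSpacing)
    arrays = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
    # data axes: (row, column, slice)
    data = np.stack(arrays, axis=-1)
    ipp0 = np.asarray(slices[0].ImagePositionPatient, dtype=float)
    origin = tuple(float(v) for v in ipp0)
    return VoxelGrid(
        data=data,
        spacing=(row_spacing, col_spacing, slice_spacing),
        origin=origin,
        role=role,
    )


def calibration_from_dicom(dataset) -> SuvCalibration | None:
    """Best-effort extraction of SUV calibration from a DICOM PET dataset.

    Returns None when the radiopharmaceutical block or patient weight is
    absent; callers always may override with an explicit
    :class:`SuvCalibration`.
    """
    try:
        info = dataset.RadiopharmaceuticalInformationSequence[0]
        dose_bq = float(info.RadionuclideTotalDose)
        half_life_s = float(info.RadionuclideHalfLife)
        weight_kg = float(dataset.PatientWeight)
    except (AttributeError, IndexError, TypeError, ValueError):
        return None
    interval_min = 60.0
    try:
        start = str(info.RadiopharmaceuticalStartTime)
        acq = str(dataset.AcquisitionTime)
        interval_min = max((_parse_dicom_time(acq) - _parse_dicom_time(start)) / 60.0, 1e-6)
    except (AttributeError, TypeError, ValueError):
        pass
    return SuvCalibration(
        injected_activity_mbq=dose_bq / 1e6,
        injection_to_scan_min=interval_min,
        patient_weight_kg=weight_kg,
        isotope_half_life_min=half_life_s / 60.0,
    )


def _parse_dicom_time(value: str) -> float:
    value = value.split(".")[0].ljust(6, "0")
    return int(value[0:2]) * 3600 + int(value[2:4]) * 60 + int(value[4:6])


# -- resampling -------------------------------------------------------------


def resample_to_grid(
    moving: VoxelGrid,
    reference: VoxelGrid,
    interpolation: Literal["nearest", "trilinear"] = "trilinear",
) -> VoxelGrid:
    """Resample ``moving`` onto the geometry of ``reference``.

    Interpolation happens in physical space; ``nearest`` must be used for
    label masks. Voxels of the reference grid that fall outside the moving
    volume are filled with zero.

    Raises
    ------
    ValueError
        If the two grids' physical bounding boxes do not overlap at all.
    """
    if interpolation not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if moving.same_geometry(reference):
        return reference.with_data(moving.data.copy(), role=moving.role)

    lo_m, hi_m = moving.physical_extent()
    lo_r, hi_r = reference.physical_extent()
    if np.any(lo_m > hi_r) or np.any(lo_r > hi_m):
        raise ValueError("no spatial overlap between moving and reference grids")

    # physical coords of reference voxel centres -> fractional moving indices
    idx = np.indices(reference.shape, dtype=float)
    coords = [
        (reference.origin[a] + idx[a] * reference.spacing[a] - moving.origin[a])
        / moving.spacing[a]
        for a in range(3)
    ]
    order = 0 if interpolation == "nearest" else 1
    was_bool = moving.data.dtype == bool
    src = moving.data.astype(np.float64) if not was_bool else moving.data.astype(np.uint8)
    out = map_coordinates(src, coords, order=order, mode="constant", cval=0.0)
    if was_bool:
        out = out.astype(bool)
    return reference.with_data(out, role=moving.role)


# -- SUV conversion ---------------------------------------------------------


def compute_suv(
    pet: VoxelGrid,
    cal: SuvCalibration,
    decay_correct: bool = True,
) -> VoxelGrid:
    """Convert PET activity concentration (Bq/ml) to body-weight SUV.

    SUV = C / (D / W) with C the voxel activity concentration in Bq/ml,
    D the injected activity in Bq (decay-corrected to scan time when
    ``decay_correct`` is on) and W the patient weight in grams, taking
    tissue density as 1 g/ml. The result is dimensionless and non-negative;
    negative input activity (reconstruction artefacts) is clipped to zero.
    """
    if pet.role != "PET":
        raise ValueError(f"compute_suv requires a PET-role grid, got role {pet.role!r}")
    dose_bq = cal.injected_activity_mbq * 1e6
    if decay_correct:
        dose_bq *= cal.decay_factor
    weight_g = cal.patient_weight_kg * 1000.0
    suv = np.clip(pet.data, 0.0, None) * (weight_g / dose_bq)
    return pet.with_data(suv, role="PET")
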