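"""Volume and label-mask containers, NIfTI/DICOM I/O, and grid resampling.

Axis convention
---------------
Arrays are indexed ``(z, y, x)`` with ``z`` the axial slice index, 0-based,
voxel-center coordinates.  ``spacing`` is millimetres per voxel in the same
``(z, y, x)`` order.  The working grid used throughout the pipeline defaults
to (0.9, 0.66, 0.66) mm, with the coarse 0.9 mm step assigned to the axial
axis (the conventional coarse axis of reconstructed cardiac CT).

NIfTI files are written with an axis-aligned RAS affine; DICOM series are
read-only.  Inputs whose orientation is not axis-aligned raise
:class:`~noisekit.errors.SpacingError` rather than being silently reoriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage

from .errors import DicomSeriesError, SpacingError

#: Integer codes used in every label mask.
CLASS_CODES = {"background": 0, "aorta": 1, "lm": 2, "rca": 3, "ignore": 255}

#: The working resolution the segmentation network expects, (z, y, x) mm.
WORKING_SPACING = (0.9, 0.66, 0.66)


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise SpacingError(f"spacing must be three positive numbers, got {spacing}")
    return spacing


@dataclass
class Volume:
    """A 3D scalar field in Hounsfield units on a regular anisotropic grid."""

    values: np.ndarray           # (z, y, x), HU
    spacing: tuple[float, float, float]  # mm per voxel, (z, y, x)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm offset of voxel (0,0,0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class LabelMask:
    """Categorical companion of :class:`Volume` over {bg, aorta, LM, RCA, ignore}."""

    labels: np.ndarray           # (z, y, x) integer codes
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    class_codes: dict = field(default_factory=lambda: dict(CLASS_CODES))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label array must be integer typed")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        bad = set(np.unique(self.labels)) - set(self.class_codes.values())
        if bad:
            raise ValueError(f"unknown label codes {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def class_mask(self, name: str) -> np.ndarray:
        """Boolean mask of one named class."""
        return self.labels == self.class_codes[name]


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _affine_from(spacing, origin) -> np.ndarray:
    # array axes (z, y, x) are stored as NIfTI axes (x, y, z)
    sz, sy, sx = spacing
    oz, oy, ox = origin
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def _spacing_origin_from(affine) -> tuple[tuple, tuple]:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-6 * max(1.0, np.abs(rot).max()):
        raise SpacingError("non-axis-aligned NIfTI orientation is not supported")
    sx, sy, sz = np.diag(rot)
    spacing = _check_spacing((abs(sz), abs(sy), abs(sx)))
    ox, oy, oz = affine[:3, 3]
    return spacing, (float(oz), float(oy), float(ox))


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz) with spacing in the affine."""
    img = nib.Nifti1Image(
        np.ascontiguousarray(volume.values.transpose(2, 1, 0)),
        _affine_from(volume.spacing, volume.origin),
    )
    nib.save(img, str(path))


def read_volume(path) -> Volume:
    """Read a NIfTI volume; spacing must be present and positive."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    spacing, origin = _spacing_origin_from(img.affine)
    values = np.asarray(img.dataobj).transpose(2, 1, 0)
    return Volume(values=values, spacing=spacing, origin=origin)


def write_mask(mask: LabelMask, path) -> None:
    """Write a label mask as integer NIfTI-1."""
    img = nib.Nifti1Image(
        np.ascontiguousarray(mask.labels.transpose(2, 1, 0).astype(np.uint8)),
        _affine_from(mask.spacing, mask.origin),
    )
    nib.save(img, str(path))


def read_mask(path) -> LabelMask:
    """Read an integer NIfTI label mask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    spacing, origin = _spacing_origin_from(img.affine)
    labels = np.asarray(img.dataobj).transpose(2, 1, 0)
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if np.abs(labels - rounded).max() > 0:
            raise ValueError(f"{path} does not contain integer labels")
        labels = rounded.astype(np.int64)
    return LabelMask(labels=labels.astype(np.int64), spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# DICOM series (read-only)
# ---------------------------------------------------------------------------

def read_dicom_series(directory) -> Volume:
    """Read an axial DICOM series into HU.

    Slices are sorted by their z position and the modality rescale
    (``HU = slope * stored + intercept``) is applied.  The series must be
    consistent: equal in-plane shapes and pixel spacings, uniform slice step.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise DicomSeriesError(f"no files in {directory}")
    slices = []
    for p in files:
        ds = pydicom.dcmread(str(p))
        if not hasattr(ds, "PixelSpacing"):
            raise SpacingError(f"{p.name}: missing PixelSpacing")
        slices.append((p, ds))

    def zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        raise DicomSeriesError("missing ImagePositionPatient")

    slices.sort(key=lambda item: zpos(item[1]))
    ref = slices[0][1]
    py, px = (float(v) for v in ref.PixelSpacing)
    shape = (int(ref.Rows), int(ref.Columns))
    bad = [p.name for p, ds in slices
           if (int(ds.Rows), int(ds.Columns)) != shape
           or tuple(float(v) for v in ds.PixelSpacing) != (py, px)]
    if bad:
        raise DicomSeriesError(f"inconsistent slices in series: {bad}")

    zs = np.array([zpos(ds) for _, ds in slices])
    if len(zs) > 1:
        steps = np.diff(zs)
        if steps.min() <= 0 or np.ptp(steps) > 1e-3 * steps.mean():
            raise DicomSeriesError("slice positions are not uniformly increasing")
        sz = float(steps.mean())
    else:
        sz = float(getattr(ref, "SliceThickness", 0.0) or 0.0)
        if sz <= 0:
            raise SpacingError("single-slice series without SliceThickness")

    planes = []
    for _, ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    values = np.stack(planes, axis=0)
    origin = (float(zs[0]), float(ref.ImagePositionPatient[1]),
              float(ref.ImagePositionPatient[0]))
    return Volume(values=values, spacing=(sz, py, px), origin=origin)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _target_shape(shape, spacing, target) -> tuple[int, ...]:
    # round(extent / target), ties to even; at least 1 voxel per axis
    extent = np.asarray(shape) * np.asarray(spacing)
    return tuple(int(max(1, np.rint(e / t))) for e, t in zip(extent, target))


def resample(obj: Volume | LabelMask, target_spacing, mode: str | None = None):
    """Resample a volume (trilinear) or mask (nearest-neighbour) to a new grid.

    ``mode`` defaults from the input type: ``"image"`` for :class:`Volume`,
    ``"label"`` for :class:`LabelMask`.  Output shape per axis is
    ``round(extent / target)`` with ties to even; resampling to the input's
    own spacing short-circuits to an identical copy.
    """
    target = _check_spacing(target_spacing)
    if mode is None:
        mode = "label" if isinstance(obj, LabelMask) else "image"
    if mode not in ("image", "label"):
        raise ValueError(f"mode must be 'image' or 'label', got {mode!r}")

    data = obj.labels if isinstance(obj, LabelMask) else obj.values
    if mode == "image" and not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")

    if np.allclose(target, obj.spacing, rtol=0, atol=1e-12):
        out = data.copy()
    else:
        new_shape = _target_shape(data.shape, obj.spacing, target)
        grids = np.meshgrid(
            *(np.arange(n) * t / s for n, t, s in zip(new_shape, target, obj.spacing)),
            indexing="ij",
        )
        order = 1 if mode == "image" else 0
        out = ndimage.map_coordinates(
            data.astype(np.float32 if mode == "image" else data.dtype),
            np.stack([g.ravel() for g in grids]),
            order=order, mode="nearest",
        ).reshape(new_shape)

    if isinstance(obj, LabelMask):
        return replace(obj, labels=out.astype(obj.labels.dtype), spacing=target)
    return replace(obj, values=out, spacing=target)
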