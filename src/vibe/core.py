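"""Geometric image model, NIfTI I/O, resampling and plane detection.

A :class:`Volume` is a scalar 3D array together with its physical
:class:`Geometry` (voxel spacing in mm, origin of the first voxel center,
and a 3x3 direction matrix mapping index axes to physical axes).  All
physical coordinates use the LPS (left-posterior-superior) convention of
DICOM and ITK; NIfTI affines, which are RAS-based, are converted on read
and write.

Index convention: ``data[i, j, k]`` with 0-based indices, axis order
matching the NIfTI on-disk order (fastest-varying first).  Voxel *centers*
define physical positions: the center of voxel ``(i, j, k)`` is
``origin + direction @ (spacing * (i, j, k))``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import FormatError, GeometryError

__all__ = [
    "AnatomicalPlane",
    "Atlas",
    "Geometry",
    "Volume",
    "detect_plane",
    "read_volume",
    "resample_to",
    "transpose_geometry",
    "write_volume",
]

# RAS <-> LPS: flip the first two physical axes.
_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


class AnatomicalPlane(str, enum.Enum):
    """Acquisition plane of a quadruped head scan.

    The plane normal is identified with a physical axis: x for sagittal,
    y for dorsal (the quadruped analogue of human coronal) and z for
    transverse.
    """

    SAGITTAL = "sagittal"
    DORSAL = "dorsal"
    TRANSVERSE = "transverse"


#: physical axis index -> plane whose normal it is
_AXIS_TO_PLANE = {
    0: AnatomicalPlane.SAGITTAL,
    1: AnatomicalPlane.DORSAL,
    2: AnatomicalPlane.TRANSVERSE,
}


@dataclass(frozen=True)
class Geometry:
    """Physical placement of a voxel grid: spacing (mm), origin (mm), direction."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    direction: tuple[float, ...]  # row-major 3x3

    def __post_init__(self) -> None:
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0) or not np.all(np.isfinite(sp)):
            raise GeometryError(f"spacing must be 3 positive finite reals, got {self.spacing}")
        og = np.asarray(self.origin, dtype=float)
        if og.shape != (3,) or not np.all(np.isfinite(og)):
            raise GeometryError(f"origin must be 3 finite reals, got {self.origin}")
        d = self.direction_matrix
        if not np.allclose(d.T @ d, np.eye(3), atol=1e-6):
            raise GeometryError("direction matrix is not orthonormal")

    @property
    def direction_matrix(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        return d

    @staticmethod
    def from_matrices(spacing, origin, direction) -> "Geometry":
        return Geometry(
            spacing=tuple(float(s) for s in spacing),
            origin=tuple(float(o) for o in origin),
            direction=tuple(float(x) for x in np.asarray(direction).reshape(9)),
        )


@dataclass
class Volume:
    """A scalar 3D image with physical geometry."""

    data: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(f"Volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise GeometryError("Volume intensities must be finite")

    @property
    def size(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_physical(self, index) -> np.ndarray:
        """Physical position (mm, LPS) of a (possibly fractional) index."""
        idx = np.asarray(index, dtype=float)
        g = self.geometry
        return np.asarray(g.origin) + g.direction_matrix @ (np.asarray(g.spacing) * idx)

    def physical_center(self) -> np.ndarray:
        """Physical position of the grid center."""
        return self.index_to_physical((np.asarray(self.size) - 1) / 2.0)

    def same_grid(self, other: "Volume", atol: float = 1e-5) -> bool:
        if self.size != other.size:
            return False
        a, b = self.geometry, other.geometry
        return (
            np.allclose(a.spacing, b.spacing, atol=atol)
            and np.allclose(a.origin, b.origin, atol=atol)
            and np.allclose(a.direction_matrix, b.direction_matrix, atol=atol)
        )

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data=data, geometry=self.geometry)


def as_binary_mask(volume: Volume) -> Volume:
    """Validate that ``volume`` holds only {0, 1} values and return it."""
    vals = np.unique(volume.data)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise GeometryError("binary mask contains values other than 0 and 1")
    return volume


@dataclass
class Atlas:
    """A species brain atlas: intensity template plus binary brain mask."""

    template: Volume
    brain_mask: Volume

    def __post_init__(self) -> None:
        if not self.template.same_grid(self.brain_mask):
            raise GeometryError("atlas template and brain mask must share size and geometry")
        as_binary_mask(self.brain_mask)
        if not np.any(self.brain_mask.data > 0):
            raise GeometryError("atlas brain mask has no foreground voxels")


# ---------------------------------------------------------------------------
# SimpleITK interop
# ---------------------------------------------------------------------------

def to_sitk(volume: Volume) -> sitk.Image:
    """Convert a Volume to a SimpleITK image (shares geometry, copies data)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.T))
    img.SetSpacing(tuple(volume.geometry.spacing))
    img.SetOrigin(tuple(volume.geometry.origin))
    img.SetDirection(tuple(volume.geometry.direction))
    return img


def from_sitk(img: sitk.Image) -> Volume:
    data = sitk.GetArrayFromImage(img).T
    geom = Geometry.from_matrices(img.GetSpacing(), img.GetOrigin(), img.GetDirection())
    return Volume(data=np.asarray(data, dtype=np.float64), geometry=geom)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume:
    """Read a scalar 3D NIfTI-1 volume.

    4D files with a singleton fourth dimension are squeezed; any other
    non-scalar payload is rejected.  The RAS affine is converted to LPS.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected scalar 3D payload, got shape {data.shape}"
        )
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise FormatError(f"{path}: non-finite affine matrix")
    lps = _RAS2LPS @ affine
    rot = lps[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    if np.any(spacing <= 0):
        raise FormatError(f"{path}: degenerate affine (zero spacing column)")
    direction = rot / spacing
    try:
        geom = Geometry.from_matrices(spacing, lps[:3, 3], direction)
    except GeometryError as exc:
        raise FormatError(f"{path}: affine direction: {exc}") from exc
    return Volume(data=np.asarray(data, dtype=np.float64), geometry=geom)


def write_volume(volume: Volume, path, dtype=np.float32) -> None:
    """Write a Volume as NIfTI-1.  Masks should pass ``dtype=np.uint8``."""
    g = volume.geometry
    lps = np.eye(4)
    lps[:3, :3] = g.direction_matrix * np.asarray(g.spacing)
    lps[:3, 3] = g.origin
    affine = _RAS2LPS @ lps
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=dtype), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_INTERP = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor,
           "bspline": sitk.sitkBSpline}


def resample_to(
    moving: Volume,
    reference_geometry: Geometry,
    reference_size: tuple[int, int, int],
    interpolation: str = "linear",
    default_value: float = 0.0,
) -> Volume:
    """Resample ``moving`` onto the reference grid.

    Sampling happens at voxel centers of the reference grid; positions
    outside the support of ``moving`` are filled with ``default_value``.
    """
    if any(s <= 0 for s in reference_size):
        raise GeometryError(f"degenerate reference size {reference_size}")
    if interpolation not in _INTERP:
        raise GeometryError(f"unknown interpolation {interpolation!r}")
    ref = sitk.Image(tuple(int(s) for s in reference_size), sitk.sitkFloat64)
    ref.SetSpacing(tuple(reference_geometry.spacing))
    ref.SetOrigin(tuple(reference_geometry.origin))
    ref.SetDirection(tuple(reference_geometry.direction))
    out = sitk.Resample(
        to_sitk(moving), ref, sitk.Transform(), _INTERP[interpolation],
        float(default_value), sitk.sitkFloat64,
    )
    return from_sitk(out)


# ---------------------------------------------------------------------------
# Plane handling
# ---------------------------------------------------------------------------

def stacking_axis(volume: Volume) -> int:
    """Index axis along which slices are stacked: largest spacing, ties -> last."""
    sp = np.asarray(volume.geometry.spacing)
    # argmax of reversed array picks the *last* maximum
    return int(2 - np.argmax(sp[::-1]))


def detect_plane(volume: Volume) -> AnatomicalPlane:
    """Classify the acquisition plane of a volume.

    The slice-stacking index axis is the one with the largest spacing
    (ties resolved toward the last axis).  The plane is the one whose
    normal — a physical axis — is most aligned with that index axis in
    physical space.
    """
    axis = stacking_axis(volume)
    col = volume.geometry.direction_matrix[:, axis]
    phys_axis = int(np.argmax(np.abs(col)))
    return _AXIS_TO_PLANE[phys_axis]


def plane_for_axis(phys_axis: int) -> AnatomicalPlane:
    return _AXIS_TO_PLANE[phys_axis]


def central_slice_index(volume: Volume, axis: int | None = None) -> int:
    """Middle slice index along the stacking axis (even sizes: lower middle)."""
    if axis is None:
        axis = stacking_axis(volume)
    return (volume.size[axis] - 1) // 2


def extract_central_slice(volume: Volume, axis: int | None = None):
    """Return (2D array, in-plane axes, slice index) for the central slice.

    The 2D array is indexed by the two remaining index axes in ascending
    order; use :func:`slice_index_to_physical` to map pixel coordinates
    back to 3D physical points.
    """
    if axis is None:
        axis = stacking_axis(volume)
    idx = central_slice_index(volume, axis)
    in_plane = tuple(a for a in range(3) if a != axis)
    sl = [slice(None)] * 3
    sl[axis] = idx
    return volume.data[tuple(sl)], in_plane, idx


def slice_index_to_physical(volume: Volume, axis: int, slice_index: int, uv) -> np.ndarray:
    """Physical point of 2D pixel ``uv`` on slice ``slice_index`` along ``axis``."""
    in_plane = [a for a in range(3) if a != axis]
    idx = np.zeros(3)
    idx[axis] = slice_index
    idx[in_plane[0]] = uv[0]
    idx[in_plane[1]] = uv[1]
    return volume.index_to_physical(idx)


# ---------------------------------------------------------------------------
# Atlas geometry transposition
# ---------------------------------------------------------------------------

def transpose_geometry(atlas: Atlas, target: Volume) -> Atlas:
    """Adapt the atlas to the target grid (spacing, size, orientation).

    The atlas is first resampled onto a grid with the target's size,
    spacing and direction, centered on the atlas' own physical center so
    no content is lost; the grid is then re-labelled with the target's
    origin and direction so the atlas sits at the center of the target
    field of view, in the target frame.  The template uses linear
    interpolation, the mask nearest-neighbor.
    """
    tg = target.geometry
    size = target.size
    d = tg.direction_matrix
    sp = np.asarray(tg.spacing)
    center = atlas.template.physical_center()
    origin = center - d @ (sp * (np.asarray(size) - 1) / 2.0)
    staging = Geometry.from_matrices(sp, origin, d)
    template = resample_to(atlas.template, staging, size, "linear")
    mask = resample_to(atlas.brain_mask, staging, size, "nearest")
    # relabel into the target frame
    template = Volume(template.data, tg)
    mask = Volume(mask.data, tg)
    return Atlas(template=template, brain_mask=mask)


def translate_volume(volume: Volume, translation) -> Volume:
    """Shift a volume's content by ``translation`` mm (exact, via origin)."""
    g = volume.geometry
    new_origin = tuple(np.asarray(g.origin) + np.asarray(translation, dtype=float))
    return Volume(volume.data, replace(g, origin=new_origin))
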