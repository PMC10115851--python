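"""Automatic brain localization on the central slice.

After the atlas has been resampled into the target frame it sits at the
center of the field of view, while the subject's brain may be anywhere.
Because atlas and subject share only the brain (model-to-image
registration), intensity-driven registration needs a good initial
superposition.  This module finds the brain center on the central slice
of the target using graph-based (Felzenszwalb-Huttenlocher)
segmentation, whose scale parameter is tied to the expected brain area,
and translates the atlas onto it.

The scale of observation is ``k = k_factor * S_atlas`` where ``S_atlas``
is the number of non-background pixels on the central slice of the
resampled atlas.  Since ``S_atlas`` counts pixels, ``k`` scales with
image resolution and the segmentation outcome is resolution-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.segmentation import felzenszwalb as _felzenszwalb

from .core import (
    AnatomicalPlane,
    Atlas,
    Geometry,
    Volume,
    extract_central_slice,
    slice_index_to_physical,
    stacking_axis,
    translate_volume,
)
from .errors import EmptyAtlasSliceError, GeometryError, LocalizationError

__all__ = [
    "LabelImage",
    "LocatorConfig",
    "atlas_surface",
    "center_atlas",
    "felzenszwalb_segment",
    "locate_brain_center",
]


@dataclass
class LabelImage:
    """Integer-labelled 2D image; labels form the contiguous set 0..L-1."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise GeometryError("LabelImage must be 2D")
        labels = np.unique(self.data)
        # relabel to a contiguous range
        self.data = np.searchsorted(labels, self.data)

    @property
    def n_labels(self) -> int:
        return int(self.data.max()) + 1


def _default_reference_points() -> dict[AnatomicalPlane, tuple[float, float]]:
    # Relative (u, v) in [0,1]^2 over the slice's two in-plane index axes.
    # Geometric center for dorsal/transverse; shifted 10% toward the start
    # of the second in-plane axis for sagittal, where the brain sits
    # dorsally in a quadruped head.
    return {
        AnatomicalPlane.SAGITTAL: (0.5, 0.4),
        AnatomicalPlane.DORSAL: (0.5, 0.5),
        AnatomicalPlane.TRANSVERSE: (0.5, 0.5),
    }


@dataclass
class LocatorConfig:
    """Parameters of the brain localization stage.

    k_factor
        Multiplier relating the Felzenszwalb scale of observation to the
        atlas slice area: ``k = k_factor * S_atlas``.
    sigma
        Gaussian pre-smoothing width in pixels.
    min_size_factor
        Minimum region size as a fraction of ``S_atlas``; smaller regions
        are merged into their most similar neighbor.
    reference_points
        Expected relative brain position per acquisition plane, in [0,1]^2
        slice coordinates.
    exclude_background
        Drop candidate regions whose mean intensity is at air level
        (below ``background_fraction`` of the slice's 99th percentile).
    size_band
        Plausible region area as (lo, hi) multiples of ``S_atlas``; the
        scale parameter makes the brain region grow to roughly the atlas
        area, so far smaller or larger regions are not brain candidates.
        If the band excludes every region, all regions are reconsidered.
    """

    k_factor: float = 200.0
    sigma: float = 0.5
    min_size_factor: float = 0.05
    reference_points: dict[AnatomicalPlane, tuple[float, float]] = field(
        default_factory=_default_reference_points
    )
    exclude_background: bool = True
    background_fraction: float = 0.1
    size_band: tuple[float, float] = (0.5, 4.0)

    def __post_init__(self) -> None:
        if self.k_factor <= 0:
            raise GeometryError("k_factor must be positive")
        if self.sigma < 0:
            raise GeometryError("sigma must be non-negative")
        for plane, (u, v) in self.reference_points.items():
            if not (0 <= u <= 1 and 0 <= v <= 1):
                raise GeometryError(f"reference point for {plane} outside [0,1]^2")


def atlas_surface(atlas_resampled: Atlas) -> int:
    """Number of non-background template pixels on the atlas' central slice.

    Background is exactly 0 (the resampling fill value), so "non
    background" means strictly positive intensity.
    """
    slice2d, _, _ = extract_central_slice(atlas_resampled.template)
    count = int(np.count_nonzero(slice2d > 0))
    if count == 0:
        raise EmptyAtlasSliceError(
            "central slice of the resampled atlas contains no brain; "
            "the atlas may not overlap the target field of view"
        )
    return count


def felzenszwalb_segment(
    slice2d: np.ndarray, k: float, sigma: float = 0.5, min_size: int = 0
) -> LabelImage:
    """Graph-based segmentation of a 2D slice.

    Greedy Felzenszwalb-Huttenlocher merging on the 8-connected pixel
    graph with intensity-difference edge weights after Gaussian(sigma)
    smoothing; two components merge when the cheapest edge between them
    is no larger than either component's internal difference plus
    ``k/|C|``; components below ``min_size`` are merged afterwards.
    Deterministic for identical input.
    """
    arr = np.asarray(slice2d, dtype=np.float64)
    if arr.ndim != 2:
        raise GeometryError(f"felzenszwalb_segment expects a 2D image, got {arr.ndim}D")
    if not np.all(np.isfinite(arr)):
        raise GeometryError("slice contains non-finite values")
    if k <= 0:
        raise GeometryError("scale k must be positive")
    # k follows the reference implementation's convention for 8-bit
    # images (scikit-image divides the scale by 255 internally), so the
    # caller should present intensities on a 0..255-like range.
    labels = _felzenszwalb(arr, scale=float(k), sigma=float(sigma),
                           min_size=int(min_size), channel_axis=None)
    return LabelImage(labels)


def _region_centroids(labels: np.ndarray) -> np.ndarray:
    """(L, 2) array of per-label pixel centroids, index coordinates."""
    n = int(labels.max()) + 1
    counts = np.bincount(labels.ravel(), minlength=n).astype(float)
    ii, jj = np.indices(labels.shape)
    ci = np.bincount(labels.ravel(), weights=ii.ravel(), minlength=n) / counts
    cj = np.bincount(labels.ravel(), weights=jj.ravel(), minlength=n) / counts
    return np.stack([ci, cj], axis=1)


def locate_brain_center(
    target: Volume,
    atlas_resampled: Atlas,
    plane: AnatomicalPlane,
    cfg: LocatorConfig | None = None,
):
    """Find the brain center on the target's central slice.

    Segments the central slice with ``k = k_factor * S_atlas`` and
    ``min_size = min_size_factor * S_atlas``, and returns the physical
    3D point of the centroid of the region closest to the plane's
    reference point, together with the chosen region label and the
    :class:`LabelImage` for QC.  Air-level and implausibly sized regions
    are not considered candidates (falling back to all regions if that
    leaves none); centroid ties go to the smaller label.
    """
    cfg = cfg or LocatorConfig()
    s_atlas = atlas_surface(atlas_resampled)
    axis = stacking_axis(target)
    slice2d, in_plane, slice_idx = extract_central_slice(target, axis)
    # rescale to an 8-bit-like range so the k = k_factor * S_atlas scale
    # behaves identically for arbitrary MR intensity ranges
    robust_max = float(np.percentile(slice2d, 99.5))
    norm = 255.0 * slice2d / robust_max if robust_max > 0 else slice2d
    seg = felzenszwalb_segment(
        norm,
        k=cfg.k_factor * s_atlas,
        sigma=cfg.sigma,
        min_size=max(1, int(round(cfg.min_size_factor * s_atlas))),
    )
    labels = seg.data
    n = seg.n_labels
    centroids = _region_centroids(labels)
    counts = np.bincount(labels.ravel(), minlength=n).astype(float)

    candidate = np.ones(n, dtype=bool)
    if cfg.exclude_background:
        scale = float(np.percentile(slice2d, 99))
        if scale > 0:
            means = np.bincount(labels.ravel(), weights=slice2d.ravel(),
                                minlength=n) / counts
            candidate &= means > cfg.background_fraction * scale
    lo, hi = cfg.size_band
    candidate &= (counts >= lo * s_atlas) & (counts <= hi * s_atlas)
    if not np.any(candidate):
        candidate[:] = True

    # reference point: relative slice coordinates -> physical point
    u_rel, v_rel = cfg.reference_points[plane]
    shape = np.asarray(slice2d.shape, dtype=float)
    ref_uv = ((shape - 1) * (u_rel, v_rel))
    ref_phys = slice_index_to_physical(target, axis, slice_idx, ref_uv)

    spacing = np.asarray(target.geometry.spacing)[list(in_plane)]
    # distances in physical mm (spacing-weighted index distance)
    d = np.full(n, np.inf)
    for lbl in np.flatnonzero(candidate):
        delta = (centroids[lbl] - ref_uv) * spacing
        d[lbl] = float(np.hypot(*delta))
    best = int(np.argmin(d))  # argmin takes the smallest label on ties
    center_phys = slice_index_to_physical(target, axis, slice_idx, centroids[best])
    return np.asarray(center_phys), best, seg


def _mask_centroid_physical(mask: Volume) -> np.ndarray:
    idx = np.argwhere(mask.data > 0)
    centroid_index = idx.mean(axis=0)
    return mask.index_to_physical(centroid_index)


def center_atlas(
    atlas_resampled: Atlas,
    brain_center: np.ndarray,
    target: Volume,
    plane: AnatomicalPlane | None = None,
):
    """Translate the atlas so its brain-mask centroid lands on ``brain_center``.

    Only the in-plane components of the translation are applied (the
    localization is 2D, so the stacking-axis component carries no
    information); the applied translation vector is returned for audit.
    """
    center = np.asarray(brain_center, dtype=float)
    lo = target.index_to_physical((0, 0, 0))
    hi = target.index_to_physical(np.asarray(target.size) - 1)
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    if np.any(center < lo - 1e-6) or np.any(center > hi + 1e-6):
        raise LocalizationError(
            "detected brain center lies outside the target field of view; "
            "consider overriding the reference point (--reference-point)"
        )
    t = center - _mask_centroid_physical(atlas_resampled.brain_mask)
    # remove the component along the stacking axis' physical direction
    axis = stacking_axis(target)
    normal = target.geometry.direction_matrix[:, axis]
    t = t - np.dot(t, normal) * normal
    moved = Atlas(
        template=translate_volume(atlas_resampled.template, t),
        brain_mask=translate_volume(atlas_resampled.brain_mask, t),
    )
    return moved, t
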