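"""End-to-end brain extraction: orchestration of all pipeline stages.

``run_vibe`` chains the full workflow: transpose the atlas geometry onto
the target grid, match its intensity histogram to the target, locate the
brain on the central slice and translate the atlas onto it, refine with
masked rigid then elastic registration, warp the atlas brain mask
through the composed transform, binarize it and multiply it into the
target to obtain the skull-stripped image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    Atlas,
    Volume,
    as_binary_mask,
    detect_plane,
    resample_to,
    transpose_geometry,
)
from .errors import ExtractionError, GeometryError, StageError
from .intensity import HistogramMatchConfig, histogram_match
from .locator import LocatorConfig, center_atlas, locate_brain_center
from .registration import (
    BSplineDeformation,
    ElasticConfig,
    RigidConfig,
    RigidTransform,
    StageReport,
    apply_transform,
    dilate_mask,
    register_elastic,
    register_rigid,
)

__all__ = ["VibeResult", "apply_mask", "binarize_registered_atlas", "run_vibe"]


@dataclass
class VibeResult:
    """Output of a full extraction run."""

    brain_mask: Volume
    stripped: Volume
    centering_translation: np.ndarray
    rigid: RigidTransform
    deformation: BSplineDeformation | None
    reports: list[StageReport]
    plane: str
    provenance: dict = field(default_factory=dict)

    def report_dict(self) -> dict:
        return {
            "plane": self.plane,
            "centering_translation_mm": [float(x) for x in self.centering_translation],
            "stages": [r.as_dict() for r in self.reports],
            **self.provenance,
        }


def binarize_registered_atlas(
    warped_mask_values: Volume,
    threshold: float = 0.5,
    keep_largest_component: bool = True,
    max_hole_voxels: int = 27,
) -> Volume:
    """Binarize the linearly transported atlas mask.

    Values >= ``threshold`` become foreground; by default only the
    largest connected component is kept (interpolation speckle removal)
    and interior holes of at most ``max_hole_voxels`` voxels are filled.
    """
    fg = warped_mask_values.data >= threshold
    if not np.any(fg):
        raise ExtractionError("registered atlas mask binarized to an empty mask")
    if keep_largest_component:
        labels, n = ndimage.label(fg)
        if n > 1:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            fg = labels == int(np.argmax(sizes))
    if max_hole_voxels > 0:
        filled = ndimage.binary_fill_holes(fg)
        holes, n_holes = ndimage.label(filled & ~fg)
        if n_holes:
            hole_sizes = np.bincount(holes.ravel())
            small = np.flatnonzero(hole_sizes[1:] <= max_hole_voxels) + 1
            fg = fg | np.isin(holes, small)
    return Volume(fg.astype(np.float64), warped_mask_values.geometry)


def apply_mask(target: Volume, mask: Volume) -> Volume:
    """Voxelwise product of the target with a binary mask (background -> 0)."""
    as_binary_mask(mask)
    if not target.same_grid(mask):
        raise GeometryError("target and mask must share the same grid")
    return target.with_data(target.data * mask.data)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise StageErrors tagged with the stage."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, StageError) and exc.stage is None:
                exc.stage = name
            return False
    return _Ctx()


def run_vibe(
    target: Volume,
    atlas: Atlas,
    histogram_cfg: HistogramMatchConfig | None = None,
    locator_cfg: LocatorConfig | None = None,
    rigid_cfg: RigidConfig | None = None,
    elastic_cfg: ElasticConfig | None = None,
    plane=None,
    enable_centering: bool = True,
    enable_elastic: bool = True,
    keep_largest_component: bool = True,
    max_hole_voxels: int = 27,
    seed: int = 0,
) -> VibeResult:
    """Run the full atlas-based extraction pipeline on one subject.

    Stage order: geometry transposition and resampling of the atlas onto
    the target grid; histogram matching of the template to the target;
    brain localization on the central slice and atlas centering; masked
    rigid registration; masked B-spline elastic registration; transport
    and binarization of the atlas mask; voxelwise masking of the target.
    Deterministic for a fixed seed.  ``plane`` defaults to automatic
    detection; ``enable_centering``/``enable_elastic`` exist for
    ablation studies.
    """
    rigid_cfg = rigid_cfg or RigidConfig(seed=seed)
    elastic_cfg = elastic_cfg or ElasticConfig.for_volume(target, seed=seed)

    with _stage("prepare"):
        atlas_t = transpose_geometry(atlas, target)
    with _stage("histogram_match"):
        template = histogram_match(atlas_t.template, target, histogram_cfg)
        atlas_t = Atlas(template=template, brain_mask=atlas_t.brain_mask)

    detected = plane or detect_plane(target)
    centering = np.zeros(3)
    if enable_centering:
        with _stage("locate"):
            center, _, _ = locate_brain_center(target, atlas_t, detected, locator_cfg)
            atlas_t, centering = center_atlas(atlas_t, center, target)

    with _stage("rigid"):
        fixed_mask = resample_to(atlas_t.brain_mask, target.geometry, target.size,
                                 "nearest")
        fixed_mask = dilate_mask(fixed_mask, rigid_cfg.fixed_mask_dilation_radius)
        rigid, rigid_report = register_rigid(target, atlas_t.template, fixed_mask,
                                             rigid_cfg)
    reports = [rigid_report]

    deformation = None
    if enable_elastic:
        with _stage("elastic"):
            # the elastic mask follows the rigidly aligned atlas position
            aligned_mask = apply_transform(
                atlas_t.brain_mask, rigid, target.geometry, target.size, "nearest")
            if not np.any(aligned_mask.data > 0):
                aligned_mask = fixed_mask
            elastic_mask = dilate_mask(aligned_mask,
                                       elastic_cfg.mask_dilation_radius)
            deformation, elastic_report = register_elastic(
                target, atlas_t.template, elastic_mask, elastic_cfg, rigid)
        reports.append(elastic_report)

    with _stage("extract"):
        chain = [rigid, deformation] if deformation is not None else [rigid]
        warped = apply_transform(atlas_t.brain_mask, chain, target.geometry,
                                 target.size, "linear")
        mask = binarize_registered_atlas(
            warped, keep_largest_component=keep_largest_component,
            max_hole_voxels=max_hole_voxels)
        stripped = apply_mask(target, mask)

    return VibeResult(
        brain_mask=mask,
        stripped=stripped,
        centering_translation=centering,
        rigid=rigid,
        deformation=deformation,
        reports=reports,
        plane=str(getattr(detected, "value", detected)),
        provenance={
            "seed": seed,
            "centering_enabled": enable_centering,
            "elastic_enabled": enable_elastic,
            "rigid_config": {k: v for k, v in vars(rigid_cfg).items()},
            "elastic_config": {k: v for k, v in vars(elastic_cfg).items()},
        },
    )
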