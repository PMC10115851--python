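import numpy as np
import pytest

from vibe.core import AnatomicalPlane, Atlas, Volume, detect_plane, transpose_geometry
from vibe.errors import EmptyAtlasSliceError, GeometryError, LocalizationError
from vibe.locator import (
    LocatorConfig,
    atlas_surface,
    center_atlas,
    felzenszwalb_segment,
    locate_brain_center,
)
from vibe.phantom import PhantomSpec, make_atlas, make_subject

from conftest import make_volume


def crisp_atlas(semi=(5.0, 7.0), size=(32, 32, 16)):
    """Synthetic atlas with an analytic elliptic cylinder, built directly
    on the target-style grid so pixel membership is exact."""
    nx, ny, nz = size
    ii, jj = np.mgrid[0:nx, 0:ny]
    cx, cy = (nx - 1) / 2, (ny - 1) / 2
    ellipse = ((ii - cx) / semi[0]) ** 2 + ((jj - cy) / semi[1]) ** 2 <= 1.0
    data = np.repeat(ellipse[:, :, None], nz, axis=2).astype(float)
    vol = make_volume(data * 100.0, spacing=(1.0, 1.0, 2.0))
    mask = make_volume(data, spacing=(1.0, 1.0, 2.0))
    return Atlas(template=vol, brain_mask=mask), ellipse


class TestAtlasSurface:
    def test_ellipse_membership_count(self):
        atlas, ellipse = crisp_atlas()
        assert atlas_surface(atlas) == int(ellipse.sum())

    def test_all_background_central_slice_raises(self):
        data = np.zeros((8, 8, 8))
        data[:, :, 7] = 1.0  # brain only on the last slice
        atlas = Atlas(template=make_volume(data, spacing=(1, 1, 3)),
                      brain_mask=make_volume((data > 0).astype(float), spacing=(1, 1, 3)))
        with pytest.raises(EmptyAtlasSliceError):
            atlas_surface(atlas)

    def test_full_foreground_slice(self):
        data = np.ones((6, 5, 4))
        atlas = Atlas(template=make_volume(data, spacing=(1, 1, 2)),
                      brain_mask=make_volume(data, spacing=(1, 1, 2)))
        assert atlas_surface(atlas) == 6 * 5


class TestFelzenszwalb:
    def test_constant_image_single_region(self):
        seg = felzenszwalb_segment(np.full((20, 20), 5.0), k=10.0)
        assert seg.n_labels == 1

    def test_two_halves_split_for_small_k(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 100.0
        seg = felzenszwalb_segment(img, k=1.0, sigma=0.0, min_size=1)
        assert seg.n_labels == 2
        # the split follows the intensity boundary
        assert len(np.unique(seg.data[:, :10])) == 1
        assert len(np.unique(seg.data[:, 10:])) == 1

    def test_huge_k_merges_everything(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 100.0
        seg = felzenszwalb_segment(img, k=1e9, sigma=0.0, min_size=1)
        assert seg.n_labels == 1

    def test_output_is_partition_and_deterministic(self, rng):
        img = rng.normal(50, 20, size=(40, 40))
        seg1 = felzenszwalb_segment(img, k=100.0, sigma=0.5, min_size=5)
        seg2 = felzenszwalb_segment(img, k=100.0, sigma=0.5, min_size=5)
        np.testing.assert_array_equal(seg1.data, seg2.data)
        labels = np.unique(seg1.data)
        np.testing.assert_array_equal(labels, np.arange(labels.size))

    def test_non_2d_rejected(self):
        with pytest.raises(GeometryError):
            felzenszwalb_segment(np.zeros((4, 4, 4)), k=1.0)


class TestLocateBrainCenter:
    def test_phantom_brain_found_within_half_radius(self):
        spec = PhantomSpec(translation_mm=(10.0, -7.0, 0.0), seed=2)
        subject, truth = make_subject(spec)
        atlas_t = transpose_geometry(make_atlas(spec), subject)
        center, label, seg = locate_brain_center(subject, atlas_t,
                                                 detect_plane(subject))
        true_center = np.array(spec.translation_mm)
        # in-plane distance only (the locator is 2D)
        err = np.linalg.norm((center - true_center)[:2])
        assert err < 0.5 * min(spec.brain_semiaxes_mm)

    def test_far_offset_still_found(self):
        spec = PhantomSpec(translation_mm=(25.0, 0.0, 0.0), seed=5)
        subject, truth = make_subject(spec)
        atlas_t = transpose_geometry(make_atlas(spec), subject)
        center, _, _ = locate_brain_center(subject, atlas_t, detect_plane(subject))
        err = np.linalg.norm((center - np.array([25.0, 0, 0]))[:2])
        assert err < 0.5 * min(spec.brain_semiaxes_mm)

    def test_resolution_invariance(self):
        """The k = k_factor * S_atlas scaling keeps the selected region's
        centroid stable across a 2x in-plane resolution change."""
        coarse = PhantomSpec(translation_mm=(8.0, -6.0, 0.0), seed=4)
        fine = coarse.replace(size=(128, 128, 64), in_plane_spacing_mm=0.625)
        centers = []
        for spec in (coarse, fine):
            subject, _ = make_subject(spec)
            atlas_t = transpose_geometry(make_atlas(spec), subject)
            c, _, _ = locate_brain_center(subject, atlas_t, detect_plane(subject))
            centers.append(c)
        delta = np.linalg.norm((centers[0] - centers[1])[:2])
        assert delta <= coarse.in_plane_spacing_mm  # one coarse voxel


class TestCenterAtlas:
    def test_fixed_point_zero_translation(self, default_atlas):
        subject, _ = make_subject(PhantomSpec())
        atlas_t = transpose_geometry(default_atlas, subject)
        centroid = np.argwhere(atlas_t.brain_mask.data > 0).mean(axis=0)
        center = atlas_t.brain_mask.index_to_physical(centroid)
        moved, t = center_atlas(atlas_t, center, subject)
        assert np.linalg.norm(t) < 1e-6

    def test_known_offset_recovered(self):
        # moderate texture: the example checks centroid geometry, so the
        # brain should segment as one region rather than lobe subregions
        spec = PhantomSpec(translation_mm=(10.0, -6.0, 0.0), seed=1,
                           texture_amplitude=0.1)
        subject, _ = make_subject(spec)
        atlas_t = transpose_geometry(make_atlas(spec), subject)
        center, _, _ = locate_brain_center(subject, atlas_t, detect_plane(subject))
        moved, t = center_atlas(atlas_t, center, subject)
        np.testing.assert_allclose(t[:2], (10.0, -6.0), atol=spec.in_plane_spacing_mm)
        assert t[2] == pytest.approx(0.0, abs=1e-9)  # in-plane only

    def test_center_outside_fov_raises(self, default_atlas):
        subject, _ = make_subject(PhantomSpec())
        atlas_t = transpose_geometry(default_atlas, subject)
        with pytest.raises(LocalizationError):
            center_atlas(atlas_t, np.array([500.0, 0.0, 0.0]), subject)


class TestLocatorConfig:
    def test_reference_point_validation(self):
        with pytest.raises(GeometryError):
            LocatorConfig(reference_points={AnatomicalPlane.DORSAL: (1.5, 0.5),
                                            AnatomicalPlane.SAGITTAL: (0.5, 0.5),
                                            AnatomicalPlane.TRANSVERSE: (0.5, 0.5)})

    def test_k_factor_positive(self):
        with pytest.raises(GeometryError):
            LocatorConfig(k_factor=0.0)
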