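"""Synthetic cranial phantom generator with analytic ground truth.

The phantom emulates the structure of an animal head MRI at the level
the extraction pipeline cares about: a brain-shaped high-intensity
object (three nested ellipsoidal tissue compartments: a CSF core, a
white-matter shell, a gray-matter rim) surrounded by a poorly
contrasted skull shell and lateral muscle blobs, displaced from the
field-of-view center by a rigid transform plus a global elastic
inflation, rendered on an arbitrarily oriented anisotropic grid under
one of three contrast regimes, with additive Gaussian noise.

Ground-truth masks and tissue labels are evaluated analytically from
the generating geometry at voxel centers — never by running the
pipeline — so every stage can be validated against them without
circularity.  The companion :func:`make_atlas` renders the same brain,
unposed and noise-free, as a synthetic stand-in for a real species
atlas.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import AnatomicalPlane, Atlas, Geometry, Volume
from .errors import PhantomSpecError

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CONTRAST_REGIMES",
    "make_atlas",
    "make_subject",
    "standard_suite",
    "rigid_suite",
]

#: Per-regime compartment intensities (arbitrary MR-like units).  Each
#: regime preserves the characteristic ordering of the three brain
#: tissues: T1-like CSF < gray < white, T2-like white < gray < CSF,
#: FLAIR-like CSF < white < gray (fluid attenuated).
CONTRAST_REGIMES: dict[str, dict[str, float]] = {
    "t1_like": {"csf": 150, "gray": 550, "white": 900, "skull": 120,
                "muscle": 450, "scalp": 650},
    "t2_like": {"csf": 900, "gray": 450, "white": 250, "skull": 150,
                "muscle": 350, "scalp": 700},
    "flair_like": {"csf": 100, "gray": 700, "white": 450, "skull": 150,
                   "muscle": 400, "scalp": 650},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one synthetic subject.

    Distances in mm, rotations in degrees.  The brain is an ellipsoid
    with the given semi-axes along the physical (x, y, z) axes of the
    unposed (atlas) frame; ``inflation`` scales the brain (and its
    compartments) radially about its center, emulating inter-subject
    size variability that only the elastic stage can absorb.  The pose
    maps atlas physical points p to subject points R p + t, rotating
    about the brain center.
    """

    brain_semiaxes_mm: tuple[float, float, float] = (10.0, 13.0, 9.0)
    ventricle_size: float = 1.0      # CSF ventricle size multiplier
    white_size: float = 1.0          # white-matter lobe size multiplier
    skull_gap_mm: float = 1.0        # fluid gap between brain and skull
    skull_thickness_mm: float = 2.4
    scalp_thickness_mm: float = 1.8  # bright fat/skin layer outside the skull
    muscle_semiaxes_mm: tuple[float, float, float] = (5.0, 4.0, 8.0)
    include_head_tissues: bool = True
    contrast: str = "t1_like"
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    inflation: float = 1.0
    texture_amplitude: float = 0.25  # intra-brain texture depth (fractional)
    psf_sigma_voxels: float = 0.6    # acquisition point-spread (partial volume)
    noise_sd_frac: float = 0.02      # fraction of the regime's max intensity
    size: tuple[int, int, int] = (64, 64, 64)
    in_plane_spacing_mm: float = 1.25
    slice_spacing_mm: float = 2.0
    plane: AnatomicalPlane = AnatomicalPlane.TRANSVERSE
    #: native grid of the synthetic atlas: high-resolution isotropic,
    #: like a real published template, and deliberately incommensurate
    #: with the subject spacing so the atlas is genuinely resampled.
    atlas_spacing_mm: float = 0.9
    atlas_margin_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contrast not in CONTRAST_REGIMES:
            raise PhantomSpecError(f"unknown contrast regime {self.contrast!r}")
        if min(self.brain_semiaxes_mm) <= 0 or self.inflation <= 0:
            raise PhantomSpecError("brain semi-axes and inflation must be positive")
        if self.ventricle_size <= 0 or self.white_size <= 0:
            raise PhantomSpecError("tissue size multipliers must be positive")
        if any(abs(r) > 30 for r in self.rotation_deg):
            raise PhantomSpecError("rotations above 30 degrees are not plausible poses")

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a synthetic subject."""

    brain_mask: Volume
    tissue_labels: np.ndarray        # 0 bg, 1 CSF, 2 gray, 3 white; subject grid
    rotation: np.ndarray             # 3x3, atlas -> subject
    translation: np.ndarray          # mm, atlas -> subject
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Grid construction
# ---------------------------------------------------------------------------

_EX, _EY, _EZ = np.eye(3)

#: index-axis -> physical-axis assignment per plane; the stacking (last)
#: index axis carries the plane normal.
_PLANE_COLUMNS = {
    AnatomicalPlane.TRANSVERSE: (_EX, _EY, _EZ),
    AnatomicalPlane.DORSAL: (_EX, _EZ, _EY),
    AnatomicalPlane.SAGITTAL: (_EY, _EZ, _EX),
}


def plane_geometry(spec: PhantomSpec) -> Geometry:
    """Grid geometry for the spec's plane, centered on the physical origin."""
    direction = np.stack(_PLANE_COLUMNS[spec.plane], axis=1)
    if np.linalg.det(direction) < 0:
        direction = direction.copy()
        direction[:, 1] *= -1  # keep a proper rotation
    spacing = np.array([spec.in_plane_spacing_mm, spec.in_plane_spacing_mm,
                        spec.slice_spacing_mm])
    origin = -direction @ (spacing * (np.asarray(spec.size) - 1) / 2.0)
    return Geometry.from_matrices(spacing, origin, direction)


def _voxel_centers(geometry: Geometry, size) -> np.ndarray:
    """(nx, ny, nz, 3) physical coordinates of all voxel centers."""
    idx = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in size],
                               indexing="ij"), axis=-1)
    sp = np.asarray(geometry.spacing)
    d = geometry.direction_matrix
    return np.asarray(geometry.origin) + (idx * sp) @ d.T


def rotation_matrix(rotation_deg) -> np.ndarray:
    """ZYX Euler rotation matrix (same convention as the rigid transform)."""
    ax, ay, az = np.radians(rotation_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


# ---------------------------------------------------------------------------
# Analytic anatomy, evaluated in the atlas (unposed) frame
# ---------------------------------------------------------------------------

def _rho(points: np.ndarray, semiaxes) -> np.ndarray:
    """Normalized ellipsoidal radius: 1 on the ellipsoid surface."""
    return np.sqrt(((points / np.asarray(semiaxes)) ** 2).sum(axis=-1))


def _texture_blobs():
    """Fixed random Gaussian blobs defining the intra-brain texture field.

    Positions live in normalized brain coordinates (the unit ball), so
    the texture stretches with the brain under inflation and rotates
    with the head under posing; the fixed internal seed makes the
    anatomy itself deterministic (the phantom's ``seed`` only drives
    acquisition noise).
    """
    rng = np.random.default_rng(1234567)
    centers = []
    while len(centers) < 120:
        c = rng.uniform(-0.95, 0.95, size=3)
        if np.linalg.norm(c) <= 0.95:
            centers.append(c)
    centers = np.asarray(centers)
    widths = rng.uniform(0.06, 0.30, size=len(centers))
    amps = rng.choice([-1.0, 1.0], size=len(centers)) * rng.uniform(0.5, 1.0, len(centers))
    # normalize so the field has roughly unit peak magnitude
    uu = np.stack(np.meshgrid(*[np.linspace(-1, 1, 21)] * 3, indexing="ij"), axis=-1)
    f = _blob_field(uu, centers, widths, amps)
    return centers, widths, amps / np.abs(f).max()


def _blob_field(u: np.ndarray, centers, widths, amps) -> np.ndarray:
    out = np.zeros(u.shape[:-1])
    for c, w, a in zip(centers, widths, amps):
        d2 = ((u - c) ** 2).sum(axis=-1)
        out += a * np.exp(-d2 / (2.0 * w * w))
    return out


_TEXTURE = _texture_blobs()


def _brain_texture(unit_points: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth deterministic intensity modulation in normalized brain coords.

    Real parenchyma is not piecewise constant: gyri, sulci and deep
    nuclei give it smooth aperiodic texture that rotates with the head
    and is what makes the pose observable to an intensity metric.  The
    modulation multiplies tissue intensities and stays within
    ``1 +- amplitude``.
    """
    centers, widths, amps = _TEXTURE
    return 1.0 + amplitude * _blob_field(unit_points, centers, widths, amps)


def _muscle_centers(spec: PhantomSpec) -> np.ndarray:
    a = np.asarray(spec.brain_semiaxes_mm) * spec.inflation
    offset = (a[0] + spec.skull_gap_mm + spec.skull_thickness_mm
              + spec.muscle_semiaxes_mm[0])
    return np.array([[offset, 0.0, 0.0], [-offset, 0.0, 0.0]])


#: internal anatomy in normalized brain coordinates (center, semi-axes).
#: Deliberately asymmetric — lateralized white-matter lobes and an
#: elongated, dorsally offset ventricle — so that the subject's pose is
#: observable to an intensity metric, as it is in a real brain.
_WHITE_LOBES = (
    ((0.38, -0.30, 0.08), (0.42, 0.50, 0.42)),
    ((-0.38, -0.30, 0.08), (0.42, 0.50, 0.42)),
    ((0.0, 0.50, -0.15), (0.35, 0.40, 0.35)),
)
_VENTRICLE = ((0.0, 0.20, 0.05), (0.18, 0.50, 0.18))


def _render(points: np.ndarray, spec: PhantomSpec):
    """Noise-free intensities, brain mask and tissue labels at ``points``."""
    regime = CONTRAST_REGIMES[spec.contrast]
    semi = np.asarray(spec.brain_semiaxes_mm, dtype=float)
    s = spec.inflation
    rho = _rho(points, semi * s)
    u = points / (semi * s)  # normalized brain coordinates

    labels = np.zeros(points.shape[:-1], dtype=np.uint8)
    labels[rho <= 1.0] = 2  # gray matter everywhere inside the brain ...
    for center, axes in _WHITE_LOBES:  # ... overridden by white lobes ...
        inside = _rho(u - np.asarray(center),
                      np.asarray(axes) * spec.white_size) <= 1.0
        labels[inside & (rho <= 1.0)] = 3
    vc, vaxes = _VENTRICLE  # ... and the CSF ventricle on top
    inside = _rho(u - np.asarray(vc), np.asarray(vaxes) * spec.ventricle_size) <= 1.0
    labels[inside & (rho <= 1.0)] = 1

    intensity = np.zeros(points.shape[:-1], dtype=np.float64)
    intensity[labels == 1] = regime["csf"]
    intensity[labels == 3] = regime["white"]
    intensity[labels == 2] = regime["gray"]
    if spec.texture_amplitude > 0:
        texture = _brain_texture(u, spec.texture_amplitude)
        brain = labels > 0
        intensity[brain] *= texture[brain]

    if spec.include_head_tissues:
        gap_outer = _rho(points, semi * s + spec.skull_gap_mm)
        skull_outer = _rho(points, semi * s + spec.skull_gap_mm
                           + spec.skull_thickness_mm)
        scalp_outer = _rho(points, semi * s + spec.skull_gap_mm
                           + spec.skull_thickness_mm + spec.scalp_thickness_mm)
        intensity[(rho > 1.0) & (gap_outer <= 1.0)] = regime["csf"]
        intensity[(gap_outer > 1.0) & (skull_outer <= 1.0)] = regime["skull"]
        intensity[(skull_outer > 1.0) & (scalp_outer <= 1.0)] = regime["scalp"]
        outside = skull_outer > 1.0
        for center in _muscle_centers(spec):
            muscle = _rho(points - center, spec.muscle_semiaxes_mm) <= 1.0
            intensity[muscle & outside] = regime["muscle"]
    mask = (rho <= 1.0).astype(np.float64)
    return intensity, mask, labels


def _check_brain_in_fov(spec: PhantomSpec, geometry: Geometry) -> None:
    r = rotation_matrix(spec.rotation_deg)
    semi = np.asarray(spec.brain_semiaxes_mm) * spec.inflation
    half_extent = np.sqrt((r ** 2) @ (semi ** 2))  # AABB of the rotated ellipsoid
    center = np.asarray(spec.translation_mm, dtype=float)
    sp = np.asarray(geometry.spacing)
    d = geometry.direction_matrix
    fov_half = np.abs(d @ (sp * (np.asarray(spec.size) - 1) / 2.0))
    if np.any(np.abs(center) + half_extent > fov_half):
        raise PhantomSpecError(
            f"posed brain (center {tuple(center)}, extent {tuple(half_extent)}) "
            f"does not fit in the field of view (half extent {tuple(fov_half)})"
        )


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def make_atlas(spec: PhantomSpec | None = None) -> Atlas:
    """Render the unposed, noise-free, brain-only template plus its mask.

    Pose, inflation, noise and the non-brain head tissues are forced off
    regardless of the incoming spec; a T1-like regime is used, matching
    the convention that species atlases are built from T1-weighted
    acquisitions.  The template is strictly positive exactly where the
    mask is 1.  Deterministic (no randomness is involved).
    """
    spec = (spec or PhantomSpec()).replace(
        rotation_deg=(0.0, 0.0, 0.0),
        translation_mm=(0.0, 0.0, 0.0),
        inflation=1.0,
        noise_sd_frac=0.0,
        include_head_tissues=False,
        contrast="t1_like",
    )
    n = int(np.ceil(2 * (max(spec.brain_semiaxes_mm) + spec.atlas_margin_mm)
                    / spec.atlas_spacing_mm))
    geometry = Geometry.from_matrices(
        [spec.atlas_spacing_mm] * 3,
        -np.ones(3) * spec.atlas_spacing_mm * (n - 1) / 2.0,
        np.eye(3),
    )
    spec = spec.replace(size=(n, n, n))
    points = _voxel_centers(geometry, (n, n, n))
    intensity, mask, _ = _render(points, spec)
    if spec.psf_sigma_voxels > 0:
        # acquisition blur, then re-masking: a skull-stripped template is
        # exactly zero outside its own brain mask
        intensity = ndimage.gaussian_filter(intensity, spec.psf_sigma_voxels)
        intensity *= mask
    return Atlas(
        template=Volume(intensity, geometry),
        brain_mask=Volume(mask, geometry),
    )


def make_subject(spec: PhantomSpec | None = None):
    """Render a posed, noisy subject volume with its analytic ground truth.

    Returns ``(subject, truth)`` where ``truth`` carries the brain mask,
    per-voxel tissue labels and the generating rigid transform.
    Deterministic for a fixed spec (the seed drives the noise).
    """
    spec = spec or PhantomSpec()
    geometry = plane_geometry(spec)
    _check_brain_in_fov(spec, geometry)
    points = _voxel_centers(geometry, spec.size)
    r = rotation_matrix(spec.rotation_deg)
    t = np.asarray(spec.translation_mm, dtype=float)
    atlas_points = (points - t) @ r  # (q - t) @ R == R^T (q - t) rowwise
    intensity, mask, labels = _render(atlas_points, spec)
    if spec.psf_sigma_voxels > 0:
        intensity = ndimage.gaussian_filter(intensity, spec.psf_sigma_voxels)
    if spec.noise_sd_frac > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_sd_frac * max(CONTRAST_REGIMES[spec.contrast].values())
        intensity = intensity + rng.normal(0.0, sd, size=intensity.shape)
    subject = Volume(intensity, geometry)
    truth = PhantomTruth(
        brain_mask=Volume(mask, geometry),
        tissue_labels=labels,
        rotation=r,
        translation=t,
        spec=spec,
    )
    return subject, truth


#: the three fixed poses of the standard suite: modest, medium and large
#: displacement/rotation with increasing brain inflation.
_SUITE_POSES = (
    {"translation_mm": (5.0, -3.0, 4.0), "rotation_deg": (4.0, -3.0, 2.0),
     "inflation": 1.04},
    {"translation_mm": (-8.0, 6.0, -5.0), "rotation_deg": (-7.0, 5.0, -4.0),
     "inflation": 1.07},
    {"translation_mm": (10.0, -7.0, 6.0), "rotation_deg": (8.0, -6.0, 9.0),
     "inflation": 1.10},
)


def standard_suite(base_seed: int = 0) -> list[PhantomSpec]:
    """The 27-case suite: 3 contrast regimes x 3 planes x 3 poses."""
    specs = []
    for ci, contrast in enumerate(CONTRAST_REGIMES):
        for pi, plane in enumerate(AnatomicalPlane):
            for qi, pose in enumerate(_SUITE_POSES):
                specs.append(PhantomSpec(
                    contrast=contrast, plane=plane,
                    seed=int(base_seed) + 9 * ci + 3 * pi + qi,
                    **pose,
                ))
    return specs


def rigid_suite(n: int = 20, base_seed: int = 0,
                max_translation: float = 15.0,
                max_rotation_deg: float = 10.0) -> list[PhantomSpec]:
    """Random rigid poses (no inflation) for registration-recovery studies.

    Translations are drawn uniformly in the ball of radius
    ``max_translation`` mm; rotations have a uniformly random axis and a
    total angle uniform in [0, ``max_rotation_deg``].  Subjects use an
    isotropic grid — the 3D-acquisition regime in which rigid accuracy
    is meaningfully measured (thick-slice series quantize the
    through-plane axis too coarsely for sub-degree comparisons).
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(base_seed)
    specs = []
    for i in range(n):
        while True:
            t = rng.uniform(-max_translation, max_translation, size=3)
            if np.linalg.norm(t) <= max_translation:
                break
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.radians(rng.uniform(0.0, max_rotation_deg))
        # decompose into the generator's ZYX Euler convention
        rot = Rotation.from_rotvec(angle * axis).as_euler("ZYX", degrees=True)[::-1]
        specs.append(PhantomSpec(
            translation_mm=tuple(t), rotation_deg=tuple(rot),
            slice_spacing_mm=1.25,
            seed=int(base_seed) + 1000 + i,
        ))
    return specs
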