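"""Seeded synthetic pelvic MR/CT phantom pairs with ground-truth labels.

Each case is a pair of co-registered volumes built from the same ellipsoid
geometry: a body with a subcutaneous fat rim, femoral heads and a sacrum,
bladder, prostate, and a rectal balloon (air- or water-filled) wrapped in a
rectal wall.  CT values come from a per-tissue Hounsfield-unit lookup, MR
values from a T2-like lookup (bladder/water bright, fat bright, bone dark)
modulated by a smooth multiplicative bias field.  A couch-like slab of
HU ~ 0 outside the body exercises body extraction.  Optionally the MR is
resampled through a random affine plus a band-limited elastic displacement
to emulate imperfect MR-CT alignment; the applied transform is stored as
ground truth.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import HU_MAX, HU_MIN, LabelGrid, Modality, VolumeGrid

# Label ids.  Cortical bone and couch carry their own ids so that with zero
# noise the CT is an exact per-label lookup.
BACKGROUND, SOFT_TISSUE, FAT, BONE, BLADDER, PROSTATE, RECTUM_WALL, BALLOON_FILL = range(8)
BONE_CORTICAL = 8
COUCH = 9

LEGEND: dict[int, str] = {
    BACKGROUND: "background",
    SOFT_TISSUE: "soft_tissue",
    FAT: "fat",
    BONE: "bone",
    BLADDER: "bladder",
    PROSTATE: "prostate",
    RECTUM_WALL: "rectum_wall",
    BALLOON_FILL: "balloon_fill",
    BONE_CORTICAL: "bone_cortical",
    COUCH: "couch",
}


class SpecificationError(ValueError):
    """Phantom geometry that cannot fit inside the requested grid."""


@dataclass
class MisregistrationSpec:
    """Bounds for the simulated MR-to-CT misalignment."""

    max_translation_mm: float = 5.0
    max_rotation_deg: float = 3.0
    elastic_amplitude_mm: float = 3.0
    elastic_scale_mm: float = 40.0

    def is_identity(self) -> bool:
        return (
            self.max_translation_mm == 0
            and self.max_rotation_deg == 0
            and self.elastic_amplitude_mm == 0
        )


def _default_ct_mean(balloon_fill: str) -> dict[str, float]:
    return {
        "background": -1000.0,
        "soft_tissue": 40.0,
        "fat": -90.0,
        "bone": 700.0,
        "bone_cortical": 1200.0,
        "bladder": 0.0,
        "prostate": 45.0,
        "rectum_wall": 40.0,
        "balloon_fill": -1000.0 if balloon_fill == "air" else 0.0,
        "couch": 0.0,
    }


def _default_ct_noise() -> dict[str, float]:
    return {
        "background": 5.0,
        "soft_tissue": 15.0,
        "fat": 15.0,
        "bone": 50.0,
        "bone_cortical": 80.0,
        "bladder": 10.0,
        "prostate": 15.0,
        "rectum_wall": 15.0,
        "balloon_fill": 8.0,
        "couch": 10.0,
    }


def _default_mr_mean(balloon_fill: str) -> dict[str, float]:
    # T2-TSE-like contrast in arbitrary units: fluid bright, fat bright,
    # cortical bone nearly void.
    return {
        "background": 20.0,
        "soft_tissue": 350.0,
        "fat": 750.0,
        "bone": 100.0,
        "bone_cortical": 50.0,
        "bladder": 900.0,
        "prostate": 430.0,
        "rectum_wall": 300.0,
        "balloon_fill": 20.0 if balloon_fill == "air" else 880.0,
        "couch": 20.0,
    }


def _default_mr_noise() -> dict[str, float]:
    d = {name: 15.0 for name in LEGEND.values()}
    d["background"] = 5.0
    return d


# Semi-axis ranges in mm, axis order (slice, row, col).  The body spans the
# imaged slab like a torso section does; slice-axis alignment is carried by
# the internal structures (bones, bladder, balloon), which vary along z.
_DEFAULT_GEOMETRY: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "body": ((150.0, 82.0, 90.0), (200.0, 95.0, 102.0)),
    "bladder": ((18.0, 24.0, 28.0), (24.0, 30.0, 34.0)),
    "prostate": ((13.0, 15.0, 15.0), (17.0, 19.0, 19.0)),
    "femoral_head": ((18.0, 18.0, 18.0), (24.0, 24.0, 24.0)),
    "balloon": ((18.0, 13.0, 13.0), (24.0, 17.0, 17.0)),
}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic pelvic phantom generator."""

    shape: tuple[int, int, int] = (24, 96, 96)
    spacing: tuple[float, float, float] = (2.5, 3.0, 3.0)
    balloon_fill: str = "air"  # or "water"
    ct_mean: dict[str, float] = field(default_factory=dict)
    ct_noise_sd: dict[str, float] = field(default_factory=_default_ct_noise)
    mr_mean: dict[str, float] = field(default_factory=dict)
    mr_noise_sd: dict[str, float] = field(default_factory=_default_mr_noise)
    bias_amplitude: float = 0.15  # multiplicative MR bias, fraction
    bias_scale_mm: float = 80.0
    geometry: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = field(
        default_factory=lambda: {k: v for k, v in _DEFAULT_GEOMETRY.items()}
    )
    center_jitter_mm: float = 4.0
    fat_rim_fraction: float = 0.90  # inner body scale below which tissue is not fat
    rectum_wall_mm: float = 4.0
    couch_hu: float = 0.0
    misregistration: MisregistrationSpec = field(default_factory=MisregistrationSpec)

    def __post_init__(self) -> None:
        if self.balloon_fill not in ("air", "water"):
            raise ValueError("balloon_fill must be 'air' or 'water'")
        self.ct_mean = {**_default_ct_mean(self.balloon_fill), **self.ct_mean}
        self.mr_mean = {**_default_mr_mean(self.balloon_fill), **self.mr_mean}
        self.ct_noise_sd = {**_default_ct_noise(), **self.ct_noise_sd}
        self.mr_noise_sd = {**_default_mr_noise(), **self.mr_noise_sd}
        for name, hu in self.ct_mean.items():
            if not (HU_MIN <= hu <= HU_MAX):
                raise SpecificationError(f"CT mean for {name} outside [{HU_MIN}, {HU_MAX}]")
        if any(sd < 0 for sd in self.ct_noise_sd.values()) or any(
            sd < 0 for sd in self.mr_noise_sd.values()
        ):
            raise SpecificationError("noise sds must be >= 0")
        # geometry must fit inside the grid in-plane (body is allowed to
        # extend through the slice slab, as a torso section does)
        half_row = self.shape[1] * self.spacing[1] / 2
        half_col = self.shape[2] * self.spacing[2] / 2
        body_hi = self.geometry["body"][1]
        if body_hi[1] + self.center_jitter_mm >= half_row - self.spacing[1]:
            raise SpecificationError("body rows do not fit inside the grid")
        if body_hi[2] + self.center_jitter_mm >= half_col - self.spacing[2]:
            raise SpecificationError("body columns do not fit inside the grid")

    def with_zero_noise(self) -> "PhantomSpec":
        """Copy with all voxel noise and MR bias switched off."""
        return replace(
            self,
            ct_noise_sd={k: 0.0 for k in self.ct_noise_sd},
            mr_noise_sd={k: 0.0 for k in self.mr_noise_sd},
            bias_amplitude=0.0,
        )

    def with_misregistration(
        self, translation: float, rotation: float, elastic: float
    ) -> "PhantomSpec":
        return replace(
            self,
            misregistration=replace(
                self.misregistration,
                max_translation_mm=translation,
                max_rotation_deg=rotation,
                elastic_amplitude_mm=elastic,
            ),
        )


@dataclass
class PairedCase:
    """A registered-or-misaligned MR/CT pair with ground truth.

    ``true_affine`` is the 4x4 sampling map in world mm taking a coordinate
    on the CT grid to the coordinate of the original (aligned) MR that was
    resampled there; ``true_displacement`` is the additional dense elastic
    term in mm (axis-first, shape ``(3,) + grid shape``).  Both are identity/
    zero until :func:`apply_misregistration` is called.
    """

    ct: VolumeGrid
    mr: VolumeGrid
    labels: LabelGrid
    true_affine: np.ndarray
    true_displacement: np.ndarray | None
    mr_valid: np.ndarray
    seed: int
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if self.ct.shape != self.labels.shape:
            raise ValueError("ct and labels must share geometry")
        if abs(np.linalg.det(self.true_affine[:3, :3])) < 1e-9:
            raise ValueError("affine part of true_transform must be invertible")

    @property
    def is_aligned(self) -> bool:
        return np.allclose(self.true_affine, np.eye(4)) and (
            self.true_displacement is None or not np.any(self.true_displacement)
        )

    def body_label_mask(self) -> np.ndarray:
        """All voxels belonging to the body (everything but background/couch)."""
        return ~np.isin(self.labels.labels, [BACKGROUND, COUCH])


def _ellipsoid(coords, center, semi_axes) -> np.ndarray:
    zs, ys, xs = coords
    t = (
        ((zs - center[0]) / semi_axes[0]) ** 2
        + ((ys[None, :, None] - center[1]) / semi_axes[1]) ** 2
        + ((xs[None, None, :] - center[2]) / semi_axes[2]) ** 2
    )
    return t <= 1.0


def _sample_axes(rng, lohi) -> np.ndarray:
    lo, hi = np.asarray(lohi[0], float), np.asarray(lohi[1], float)
    return rng.uniform(lo, hi)


def generate_phantom(spec: PhantomSpec, seed: int) -> PairedCase:
    """Build one aligned MR/CT phantom pair; deterministic given (spec, seed)."""
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.shape
    sp = np.asarray(spec.spacing)
    # grid centered at world 0
    origin = -(np.asarray(spec.shape) - 1) / 2 * sp
    zs = origin[0] + np.arange(nz) * sp[0]
    ys = origin[1] + np.arange(ny) * sp[1]
    xs = origin[2] + np.arange(nx) * sp[2]
    zg = zs[:, None, None]
    coords = (zg, ys, xs)

    labels = np.full(spec.shape, BACKGROUND, dtype=np.int32)
    jit = lambda: rng.uniform(-spec.center_jitter_mm, spec.center_jitter_mm, size=3)  # noqa: E731

    body_axes = _sample_axes(rng, spec.geometry["body"])
    body_center = np.array([0.0, 0.0, 0.0]) + jit() * np.array([0, 1, 1])
    body = _ellipsoid(coords, body_center, body_axes)
    labels[body] = FAT
    inner = _ellipsoid(
        coords, body_center, body_axes * np.array([1.0, spec.fat_rim_fraction, spec.fat_rim_fraction])
    )
    labels[inner] = SOFT_TISSUE

    # skeletal structures: two femoral heads and a sacrum block
    fh_axes = _sample_axes(rng, spec.geometry["femoral_head"])
    fh_row = 5.0 + jit()[1] * 0.5
    fh_col = 0.72 * body_axes[2]
    for sgn in (-1.0, 1.0):
        c = body_center + np.array([0.0, fh_row, sgn * fh_col])
        labels[_ellipsoid(coords, c, fh_axes)] = BONE
    sacrum_center = body_center + np.array([0.0, 0.76 * body_axes[1], 0.0])
    sacrum_axes = np.array([120.0, 14.0, 32.0])
    labels[_ellipsoid(coords, sacrum_center, sacrum_axes)] = BONE

    # organs
    bladder_axes = _sample_axes(rng, spec.geometry["bladder"])
    labels[_ellipsoid(coords, body_center + np.array([0.0, -42.0, 0.0]) + jit() * 0.5, bladder_axes)] = BLADDER
    prostate_axes = _sample_axes(rng, spec.geometry["prostate"])
    labels[_ellipsoid(coords, body_center + jit() * 0.5, prostate_axes)] = PROSTATE

    balloon_axes = _sample_axes(rng, spec.geometry["balloon"])
    balloon_center = body_center + np.array([0.0, 0.42 * body_axes[1], 0.0]) + jit() * 0.4
    wall = _ellipsoid(coords, balloon_center, balloon_axes + spec.rectum_wall_mm)
    labels[wall] = RECTUM_WALL
    labels[_ellipsoid(coords, balloon_center, balloon_axes)] = BALLOON_FILL

    # cortical rim: bone voxels adjacent to non-bone
    bone = labels == BONE
    if bone.any():
        eroded = ndimage.binary_erosion(bone, iterations=1)
        labels[bone & ~eroded] = BONE_CORTICAL

    # couch slab posterior to the body, full width, all slices
    couch_row0 = body_center[1] + body_axes[1] + 15.0
    couch_sel = (ys >= couch_row0) & (ys <= couch_row0 + 12.0)
    labels[:, couch_sel, :] = COUCH

    # intensity synthesis from per-label lookups
    names = [LEGEND[i] for i in range(len(LEGEND))]
    ct_lut = np.array([spec.ct_mean[n] for n in names])
    ct_sd_lut = np.array([spec.ct_noise_sd[n] for n in names])
    mr_lut = np.array([spec.mr_mean[n] for n in names])
    mr_sd_lut = np.array([spec.mr_noise_sd[n] for n in names])

    ct = ct_lut[labels]
    if ct_sd_lut.any():
        ct = ct + ct_sd_lut[labels] * rng.standard_normal(spec.shape)
    ct = np.clip(ct, HU_MIN, HU_MAX)

    mr = mr_lut[labels].astype(np.float64)
    if spec.bias_amplitude > 0:
        sigma = spec.bias_scale_mm / sp
        raw = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=sigma)
        peak = np.abs(raw).max()
        if peak > 0:
            mr = mr * (1.0 + spec.bias_amplitude * raw / peak)
    if mr_sd_lut.any():
        mr = mr + mr_sd_lut[labels] * rng.standard_normal(spec.shape)
    mr = np.clip(mr, 0.0, None)

    geom = dict(spacing=tuple(sp), origin=tuple(origin))
    return PairedCase(
        ct=VolumeGrid(ct, modality=Modality.CT_HU, **geom),
        mr=VolumeGrid(mr, modality=Modality.MR_AU, **geom),
        labels=LabelGrid(labels, legend=dict(LEGEND), **geom),
        true_affine=np.eye(4),
        true_displacement=None,
        mr_valid=np.ones(spec.shape, dtype=bool),
        seed=int(seed),
        spec=spec,
    )


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    """Rotation about the (slice, row, col) axes, composed col-axis last."""
    a, b, c = np.deg2rad(angles_deg)
    rz = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
    ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    rx = np.array([[np.cos(c), -np.sin(c), 0], [np.sin(c), np.cos(c), 0], [0, 0, 1]])
    return rx @ ry @ rz


def _smooth_displacement(rng, shape, spacing, amplitude_mm, scale_mm) -> np.ndarray:
    """Band-limited random displacement field, max vector norm = amplitude."""
    sigma = scale_mm / np.asarray(spacing)
    d = np.stack([ndimage.gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(3)])
    norm = np.sqrt((d**2).sum(axis=0)).max()
    if norm > 0:
        d *= amplitude_mm / norm
    return d


def sampling_map_world(
    affine: np.ndarray, displacement: np.ndarray | None, grid: VolumeGrid
) -> np.ndarray:
    """Dense world-mm coordinates sampled by ``affine`` (+ displacement) on ``grid``."""
    zs, ys, xs = grid.world_coords()
    pts = np.stack(np.meshgrid(zs, ys, xs, indexing="ij"))  # (3, S, R, C)
    flat = pts.reshape(3, -1)
    mapped = affine[:3, :3] @ flat + affine[:3, 3:4]
    mapped = mapped.reshape(pts.shape)
    if displacement is not None:
        mapped = mapped + displacement
    return mapped


def resample_through(
    values: np.ndarray,
    grid: VolumeGrid,
    mapped_world: np.ndarray,
    order: int = 1,
    cval: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``values`` (living on ``grid``) at world points; returns (data, valid)."""
    idx = np.stack(
        [(mapped_world[a] - grid.origin[a]) / grid.spacing[a] for a in range(3)]
    )
    out = ndimage.map_coordinates(values, idx, order=order, mode="constant", cval=cval)
    valid = np.ones(mapped_world.shape[1:], dtype=bool)
    for a in range(3):
        valid &= (idx[a] >= -0.5) & (idx[a] <= values.shape[a] - 0.5)
    return out, valid


def warp_mr(
    case: PairedCase,
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    displacement: np.ndarray | None = None,
) -> PairedCase:
    """Apply an exact rigid motion (+ optional dense elastic term) to the MR.

    Content moves by ``+translation_mm`` and rotates by ``rotation_deg``
    about the volume center; ``displacement`` (mm, axis-first) is added to
    the sampling map.  CT and labels are untouched; the applied sampling map
    is stored as ``true_affine`` / ``true_displacement``.
    """
    t = np.asarray(translation_mm, dtype=float)
    rot = _rotation_matrix(np.asarray(rotation_deg, dtype=float))
    # sampling map: output world x -> R^-1 (x - t - c) + c
    c = np.asarray(case.mr.origin) + (np.asarray(case.mr.shape) - 1) / 2 * np.asarray(
        case.mr.spacing
    )
    rinv = rot.T
    affine = np.eye(4)
    affine[:3, :3] = rinv
    affine[:3, 3] = c - rinv @ (t + c)

    mapped = sampling_map_world(affine, displacement, case.mr)
    warped, valid = resample_through(case.mr.values, case.mr, mapped, order=1, cval=0.0)
    warped = np.clip(warped, 0.0, None)
    return replace(
        case,
        mr=case.mr.with_values(warped),
        true_affine=affine,
        true_displacement=displacement,
        mr_valid=valid,
    )


def apply_misregistration(
    case: PairedCase, seed: int, misreg: MisregistrationSpec | None = None
) -> PairedCase:
    """Resample the MR through a random bounded affine + elastic displacement.

    Magnitudes are drawn uniformly within the bounds of ``misreg`` (default:
    the case's own :class:`MisregistrationSpec`); deterministic given
    (case, seed).
    """
    if not case.is_aligned:
        raise ValueError("case is already misregistered")
    m = misreg or case.spec.misregistration
    if m.is_identity():
        return case
    rng = np.random.default_rng(seed)
    t = rng.uniform(-m.max_translation_mm, m.max_translation_mm, size=3)
    angles = rng.uniform(-m.max_rotation_deg, m.max_rotation_deg, size=3)
    disp = None
    if m.elastic_amplitude_mm > 0:
        disp = _smooth_displacement(
            rng, case.mr.shape, case.mr.spacing, m.elastic_amplitude_mm, m.elastic_scale_mm
        )
        actual = np.sqrt((disp**2).sum(axis=0)).max()
        if actual > m.elastic_amplitude_mm + 1e-6:
            raise RuntimeError("elastic displacement exceeds the specified bound")
    return warp_mr(case, tuple(t), tuple(angles), disp)
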