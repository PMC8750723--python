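"""Paired-volume preprocessing: resample, register, mask, normalize, filter, crop.

The chain runs in a fixed order — resample to a common spacing, affine-register
MR to CT (the smooth elastic residual is deliberately left in place),
extract the body by thresholding + 3-D connected components, normalize CT
from [-1024, 3071] HU to [-1, 1] and MR to (x - mean) / (2.5 * sd) of the
body voxels clipped to [-1, 1], drop axial slices whose MR misses more than
5% of the CT body, and centrally crop in-plane.  Each step records
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .grid import HU_MIN, Modality, VolumeGrid
from .phantom import (
    PairedCase,
    _rotation_matrix,
    resample_through,
    sampling_map_world,
)

BODY_THRESHOLD_HU = -300.0


class EmptyForegroundError(ValueError):
    """CT contains no voxel above the body threshold."""


class DegenerateInputError(ValueError):
    """Input statistics make the requested normalization undefined."""


@dataclass
class NormalizationSpec:
    """Constants of the intensity normalizations."""

    ct_range: tuple[float, float] = (-1024.0, 3071.0)
    target_range: tuple[float, float] = (-1.0, 1.0)
    mr_sd_multiplier: float = 2.5
    mr_clip: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.ct_range[0] >= self.ct_range[1]:
            raise ValueError("ct_range min must be < max")
        if self.mr_sd_multiplier <= 0:
            raise ValueError("mr_sd_multiplier must be > 0")


@dataclass
class SliceFilterReport:
    kept: list[int]
    coverage: np.ndarray  # per-slice body-coverage fraction in [0, 1]

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if any(i < 0 or i >= len(self.coverage) for i in self.kept):
            raise ValueError("kept indices outside slice range")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "slice": np.arange(len(self.coverage)),
                "coverage": self.coverage,
                "kept": np.isin(np.arange(len(self.coverage)), self.kept),
            }
        )


# ---------------------------------------------------------------------------
# resampling


def _default_cval(modality: Modality) -> float:
    return {Modality.CT_HU: HU_MIN, Modality.NORMALIZED: -1.0}.get(modality, 0.0)


def resample_volume(
    vol: VolumeGrid,
    target_spacing: tuple[float, float, float],
    interpolation: str = "linear",
    cval: float | None = None,
) -> VolumeGrid:
    """Resample to ``target_spacing`` preserving the field of view.

    The output grid keeps the input origin; its shape is the smallest grid
    covering the input extent at the new spacing.  ``linear`` for images,
    ``nearest`` for label/mask companions.
    """
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if target == vol.spacing:
        return vol.with_values(vol.values.copy())
    if cval is None:
        cval = _default_cval(vol.modality)
    order = 1 if interpolation == "linear" else 0
    extent = np.asarray(vol.shape) * np.asarray(vol.spacing)
    new_shape = np.maximum(1, np.ceil(extent / np.asarray(target) - 1e-9)).astype(int)
    idx = np.stack(
        np.meshgrid(
            *[np.arange(n) * target[a] / vol.spacing[a] for a, n in enumerate(new_shape)],
            indexing="ij",
        )
    )
    out = ndimage.map_coordinates(vol.values, idx, order=order, mode="constant", cval=cval)
    if vol.modality is Modality.CT_HU:
        out = np.clip(out, *(-1024.0, 3071.0))
    return VolumeGrid(out, target, vol.origin, vol.modality)


# ---------------------------------------------------------------------------
# body extraction


def extract_body_mask(ct: VolumeGrid, threshold: float = BODY_THRESHOLD_HU) -> np.ndarray:
    """Largest 3-D connected component above ``threshold``, holes filled per slice.

    Removes the couch and background; raises :class:`EmptyForegroundError`
    on an all-air volume.
    """
    if ct.modality is not Modality.CT_HU:
        raise ValueError("extract_body_mask expects a CT_HU volume")
    fg = ct.values > threshold
    if not fg.any():
        raise EmptyForegroundError("no voxels above the body threshold")
    lab, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    body = lab == (1 + int(np.argmax(sizes)))
    for k in range(body.shape[0]):
        body[k] = ndimage.binary_fill_holes(body[k])
    return body


# ---------------------------------------------------------------------------
# intensity normalization


def normalize_ct(ct: VolumeGrid, spec: NormalizationSpec | None = None) -> VolumeGrid:
    """Affine map of [-1024, 3071] HU onto [-1, 1], clipping outside values."""
    spec = spec or NormalizationSpec()
    lo, hi = spec.ct_range
    tlo, thi = spec.target_range
    v = np.clip(ct.values, lo, hi)
    out = (v - lo) / (hi - lo) * (thi - tlo) + tlo
    return VolumeGrid(out, ct.spacing, ct.origin, Modality.NORMALIZED)


def denormalize_ct(vol: VolumeGrid, spec: NormalizationSpec | None = None) -> VolumeGrid:
    """Exact inverse of :func:`normalize_ct` on the target range."""
    spec = spec or NormalizationSpec()
    lo, hi = spec.ct_range
    tlo, thi = spec.target_range
    v = np.clip(vol.values, tlo, thi)
    out = (v - tlo) / (thi - tlo) * (hi - lo) + lo
    return VolumeGrid(out, vol.spacing, vol.origin, Modality.CT_HU)


def normalize_mr(
    mr: VolumeGrid, body: np.ndarray, spec: NormalizationSpec | None = None
) -> VolumeGrid:
    """(x - mean) / (2.5 * sd) over body voxels, clipped to [-1, 1]."""
    spec = spec or NormalizationSpec()
    if not body.any():
        raise DegenerateInputError("body mask is empty")
    inside = mr.values[body]
    mu, sd = float(inside.mean()), float(inside.std())
    if sd == 0:
        raise DegenerateInputError("body-voxel standard deviation is zero")
    out = np.clip((mr.values - mu) / (spec.mr_sd_multiplier * sd), *spec.mr_clip)
    return VolumeGrid(out, mr.spacing, mr.origin, Modality.NORMALIZED)


# ---------------------------------------------------------------------------
# slice filtering


def filter_slices(
    mr_registered: VolumeGrid,
    ct_body: np.ndarray,
    valid: np.ndarray | None = None,
    max_missing_fraction: float = 0.05,
) -> SliceFilterReport:
    """Keep slices whose MR covers at least 95% of that slice's CT body.

    ``valid`` marks MR voxels that were mapped from inside the original MR
    field of view (all-valid when omitted).  A slice is discarded iff its
    missing fraction is strictly greater than ``max_missing_fraction``.
    Slices without body voxels carry no body information and are kept with
    coverage 1.
    """
    if mr_registered.shape != ct_body.shape:
        raise ValueError("MR and body mask must share geometry")
    if valid is None:
        valid = np.ones_like(ct_body, dtype=bool)
    n_slices = ct_body.shape[0]
    coverage = np.ones(n_slices)
    for k in range(n_slices):
        n_body = int(ct_body[k].sum())
        if n_body:
            coverage[k] = float((ct_body[k] & valid[k]).sum()) / n_body
    kept = [k for k in range(n_slices) if 1.0 - coverage[k] <= max_missing_fraction + 1e-12]
    return SliceFilterReport(kept=kept, coverage=coverage)


# ---------------------------------------------------------------------------
# crop / pad


def crop_or_pad_array(
    arr: np.ndarray,
    target_rows_cols: tuple[int, int],
    mode: str = "center",
    pad_value: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Crop and/or pad the last two axes to ``target_rows_cols``.

    ``center`` is deterministic; ``random`` draws offsets from ``rng``
    (seeded by the caller).  Padding uses ``pad_value``.
    """
    tr, tc = (int(t) for t in target_rows_cols)
    if tr <= 0 or tc <= 0:
        raise ValueError("target size must be positive")
    if mode not in ("center", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "random" and rng is None:
        rng = np.random.default_rng(0)
    out = arr
    for axis, target in ((-2, tr), (-1, tc)):
        n = out.shape[axis]
        if n > target:  # crop
            max_off = n - target
            off = max_off // 2 if mode == "center" else int(rng.integers(0, max_off + 1))
            sl = [slice(None)] * out.ndim
            sl[axis] = slice(off, off + target)
            out = out[tuple(sl)]
        elif n < target:  # pad
            total = target - n
            before = total // 2 if mode == "center" else int(rng.integers(0, total + 1))
            widths = [(0, 0)] * out.ndim
            widths[axis] = (before, total - before)
            out = np.pad(out, widths, constant_values=pad_value)
    return out


def crop_or_pad(
    vol: VolumeGrid,
    target_rows_cols: tuple[int, int],
    mode: str = "center",
    pad_value: float = 0.0,
    rng: np.random.Generator | None = None,
) -> VolumeGrid:
    """Volume version of :func:`crop_or_pad_array`; origin follows the offset."""
    out = crop_or_pad_array(vol.values, target_rows_cols, mode, pad_value, rng)
    # center mode: track origin shift so world geometry stays consistent
    origin = list(vol.origin)
    for axis, target in ((1, target_rows_cols[0]), (2, target_rows_cols[1])):
        delta = vol.shape[axis] - target
        shift = (delta // 2) if delta > 0 else -((-delta) // 2)
        if mode == "center":
            origin[axis] += shift * vol.spacing[axis]
    return VolumeGrid(out, vol.spacing, tuple(origin), vol.modality)


# ---------------------------------------------------------------------------
# affine registration (MR -> CT)


@dataclass
class RegistrationResult:
    affine: np.ndarray  # 4x4 sampling map, fixed-grid world -> moving world
    translation_mm: np.ndarray  # content shift convention (as in warp_mr)
    rotation_deg: np.ndarray
    moved: VolumeGrid  # moving volume resampled onto the fixed grid
    valid: np.ndarray  # voxels mapped from inside the moving FOV
    converged: bool
    initial_cost: float
    final_cost: float


def _neg_mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Negative mutual information of two paired samples (natural log)."""
    h, _, _ = np.histogram2d(a, b, bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())
    return -mi


def _params_to_affine(params: np.ndarray, center: np.ndarray) -> np.ndarray:
    t, angles = params[:3], params[3:6]
    rinv = _rotation_matrix(angles).T
    aff = np.eye(4)
    aff[:3, :3] = rinv
    aff[:3, 3] = center - rinv @ (t + center)
    return aff


def register_affine(
    moving: VolumeGrid,
    fixed: VolumeGrid,
    fixed_body: np.ndarray | None = None,
    levels: tuple[int, ...] = (4, 2),
    maxiter: int = 60,
) -> RegistrationResult:
    """Recover the rigid/affine part of the MR-to-CT misalignment.

    Maximizes the mutual information between the fixed CT and the moved MR
    over the CT body mask (the standard multimodal criterion; T2 contrast
    is not a monotone function of HU, so matched-intensity MSE is not
    usable), with Powell descent on a multi-resolution pyramid seeded by
    the body-centroid offset.  The elastic residual is deliberately not
    corrected.  If the optimum does not improve on identity the result is
    flagged and the identity transform returned.
    """
    if moving.shape != fixed.shape or not np.allclose(moving.spacing, fixed.spacing):
        raise ValueError("register_affine expects volumes on a common grid")
    if fixed_body is None:
        fixed_body = extract_body_mask(fixed)
    fixed_vals = fixed.values

    center = np.asarray(fixed.origin) + (np.asarray(fixed.shape) - 1) / 2 * np.asarray(
        fixed.spacing
    )

    # centroid initialization from a crude MR foreground mask
    pos = moving.values[moving.values > 0]
    thr = np.quantile(pos, 0.5) * 0.25 if pos.size else 0.0
    m_mask = moving.values > max(thr, 1e-6)
    params = np.zeros(6)
    if m_mask.any():
        cf = ndimage.center_of_mass(fixed_body)
        cm = ndimage.center_of_mass(m_mask)
        params[:3] = (np.asarray(cf) - np.asarray(cm)) * np.asarray(fixed.spacing)

    def make_level(factor: int):
        # anisotropic pyramid: downsample in-plane only, keeping the (much
        # coarser, information-dense) slice axis at full resolution.
        # 0.7-voxel pre-smoothing suppresses the grid-aligned local minima
        # that interpolation artifacts induce in histogram-based MI
        if factor == 1:
            f, b, m, grid = fixed_vals, fixed_body, moving.values, fixed
        else:
            zoom = (1.0, 1.0 / factor, 1.0 / factor)
            f = ndimage.zoom(fixed_vals, zoom, order=1)
            b = ndimage.zoom(fixed_body.astype(float), zoom, order=1) > 0.5
            m = ndimage.zoom(moving.values, zoom, order=1)
            grid = VolumeGrid(
                f,
                (fixed.spacing[0], fixed.spacing[1] * factor, fixed.spacing[2] * factor),
                fixed.origin,
                Modality.CT_HU,
            )
        f = ndimage.gaussian_filter(f, 0.7)
        m = ndimage.gaussian_filter(m, 0.7)
        return f, b, m, grid

    def make_cost(factor: int):
        f_vals, f_body, m_vals, level_grid = make_level(factor)
        if not f_body.any():
            return None
        m_grid = VolumeGrid(m_vals, level_grid.spacing, level_grid.origin, Modality.MR_AU)

        def cost(p: np.ndarray) -> float:
            aff = _params_to_affine(p, center)
            mapped = sampling_map_world(aff, None, level_grid)
            moved, _ = resample_through(m_vals, m_grid, mapped, order=1, cval=0.0)
            # evaluate over the full fixed body; out-of-field voxels read as
            # MR background, so shrinking the overlap costs information
            # (excluding them makes MI rise as overlap shrinks — a bias)
            if f_body.sum() < 16:
                return 0.0
            return _neg_mutual_information(f_vals[f_body], moved[f_body])

        return cost

    cost = None
    for li, factor in enumerate(levels):
        level_cost = make_cost(factor)
        if level_cost is None:
            continue
        cost = level_cost
        if li == 0:
            # slice-axis valley of MI is narrow: seed it by exhaustive scan
            z_grid = np.arange(-8.0, 8.01, 1.0)
            z_costs = []
            for tz in z_grid:
                p = params.copy()
                p[0] += tz
                z_costs.append(cost(p))
            params[0] += z_grid[int(np.argmin(z_costs))]
        res = optimize.minimize(
            cost,
            params,
            method="Powell",
            options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-6},
        )
        params = res.x
    if cost is None:
        raise EmptyForegroundError("body mask empty at every pyramid level")
    # convergence is judged at the finest level actually optimized
    initial_cost = cost(np.zeros(6))
    final_cost = cost(params)
    converged = final_cost <= initial_cost + 1e-9
    if not converged:
        params = np.zeros(6)
    affine = _params_to_affine(params, center)
    mapped = sampling_map_world(affine, None, moving)
    moved_vals, valid = resample_through(moving.values, moving, mapped, order=1, cval=0.0)
    moved = VolumeGrid(np.clip(moved_vals, 0, None), fixed.spacing, fixed.origin, moving.modality)
    return RegistrationResult(
        affine=affine,
        translation_mm=params[:3].copy(),
        rotation_deg=params[3:6].copy(),
        moved=moved,
        valid=valid,
        converged=converged,
        initial_cost=float(initial_cost),
        final_cost=float(final_cost),
    )


# ---------------------------------------------------------------------------
# full chain


@dataclass
class PreprocessConfig:
    target_spacing: tuple[float, float, float] | None = None  # None: keep CT spacing
    register: bool = True
    crop_rows_cols: tuple[int, int] | None = None
    body_threshold_hu: float = BODY_THRESHOLD_HU
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    max_missing_fraction: float = 0.05
    registration_levels: tuple[int, ...] = (4, 2)


@dataclass
class PreprocessedCase:
    """Output of the preprocessing chain for one MR/CT pair."""

    ct: VolumeGrid  # body-masked CT in HU (reference for evaluation)
    ct_norm: VolumeGrid
    mr_norm: VolumeGrid
    body: np.ndarray
    labels: np.ndarray | None
    kept_slices: list[int]
    report: SliceFilterReport
    registration: RegistrationResult | None
    provenance: dict

    def paired_slices(self, skip_empty_body: bool = True) -> list[tuple[np.ndarray, np.ndarray]]:
        """Kept axial (mr, ct) slice pairs in normalized units.

        Slices without any body voxel carry no anatomy; by default they are
        excluded from the training pool (they remain part of the volume).
        """
        kept = self.kept_slices
        if skip_empty_body:
            kept = [k for k in kept if self.body[k].any()]
        return [(self.mr_norm.values[k], self.ct_norm.values[k]) for k in kept]


def preprocess_case(case: PairedCase, config: PreprocessConfig | None = None) -> PreprocessedCase:
    """Run the fixed chain: resample, register, body mask, normalize, filter, crop."""
    config = config or PreprocessConfig()
    provenance = {"order": ["resample", "register", "body_mask", "normalize", "slice_filter", "crop"]}

    ct, mr = case.ct, case.mr
    labels = case.labels.labels
    valid = case.mr_valid.astype(float)
    if config.target_spacing is not None and tuple(config.target_spacing) != ct.spacing:
        ct = resample_volume(ct, config.target_spacing, "linear")
        mr = resample_volume(mr, config.target_spacing, "linear")
        lab_vol = VolumeGrid(labels.astype(float), case.labels.spacing, case.labels.origin, Modality.DENSITY)
        labels = np.rint(resample_volume(lab_vol, config.target_spacing, "nearest").values).astype(np.int32)
        valid_vol = VolumeGrid(valid, case.mr.spacing, case.mr.origin, Modality.DENSITY)
        valid = resample_volume(valid_vol, config.target_spacing, "linear", cval=0.0).values
    provenance["spacing"] = ct.spacing

    body = extract_body_mask(ct, config.body_threshold_hu)

    registration = None
    if config.register:
        registration = register_affine(mr, ct, fixed_body=body, levels=config.registration_levels)
        mr = registration.moved
        mapped_valid, _ = resample_through(
            valid, VolumeGrid(valid, mr.spacing, mr.origin, Modality.DENSITY),
            sampling_map_world(registration.affine, None, mr), order=1, cval=0.0,
        )
        valid = np.where(registration.valid, mapped_valid, 0.0)
        provenance["registration"] = {
            "converged": registration.converged,
            "translation_mm": registration.translation_mm.tolist(),
            "rotation_deg": registration.rotation_deg.tolist(),
        }

    ct_masked = ct.with_values(np.where(body, ct.values, HU_MIN))
    ct_norm = normalize_ct(ct_masked, config.normalization)
    mr_norm = normalize_mr(mr, body, config.normalization)

    report = filter_slices(
        mr_norm, body, valid > 0.999, max_missing_fraction=config.max_missing_fraction
    )

    if config.crop_rows_cols is not None:
        tr = config.crop_rows_cols
        ct_masked = crop_or_pad(ct_masked, tr, "center", HU_MIN)
        ct_norm = crop_or_pad(ct_norm, tr, "center", -1.0)
        mr_norm = crop_or_pad(mr_norm, tr, "center", 0.0)
        body = crop_or_pad_array(body.astype(float), tr, "center", 0.0) > 0.5
        labels = crop_or_pad_array(labels.astype(float), tr, "center", 0.0).astype(np.int32)
        provenance["crop_rows_cols"] = tuple(tr)

    return PreprocessedCase(
        ct=ct_masked,
        ct_norm=ct_norm,
        mr_norm=mr_norm,
        body=body,
        labels=labels,
        kept_slices=report.kept,
        report=report,
        registration=registration,
        provenance=provenance,
    )
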