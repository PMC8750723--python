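"""Toy arc-dose engine, DVH metrics and 3-D global gamma analysis.

The dose engine is a deliberately simple rotational photon surrogate: for
each of N equispaced coplanar angles a parallel beam is shaped to the PTV
projection (plus margin) and attenuated exponentially with water-equivalent
depth computed from the CT-derived density.  It is not a clinical dose
algorithm (no scatter, no optimization, no MLC), but it is deterministic
and strictly sensitive to HU, which is what comparing dose on CT versus
synthetic CT requires.

DVH metrics use exact sorted-voxel quantiles: D_x% is the minimum dose of
the hottest x% of structure voxels (rank ceil(x/100 * N), 1-based, doses
sorted descending).  Gamma analysis is global: dose differences are
normalized to the maximum of the reference dose, voxels below the 10%
low-dose threshold are ignored, and the search runs over the evaluated
grid refined 3x per axis within a radius of 3 x DTA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import Modality, VolumeGrid
from .metrics import EmptyMaskError, StructureSet


@dataclass
class PlanSpec:
    """Fixed arc plan: prescription, geometry and attenuation."""

    prescription_gy: float = 60.0
    n_angles: int = 24
    aperture_margin_mm: float = 5.0
    mu_per_mm: float = 0.005  # attenuation per mm water-equivalent depth

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be > 0")
        if self.n_angles < 2:
            raise ValueError("need at least 2 beam angles")


@dataclass
class GammaCriteria:
    """Dose-difference (% of global normalization) / distance-to-agreement pair."""

    dose_percent: float = 2.0
    dta_mm: float = 2.0
    low_dose_threshold: float = 0.10
    search_radius_factor: float = 3.0

    def __post_init__(self) -> None:
        if min(self.dose_percent, self.dta_mm, self.search_radius_factor) <= 0:
            raise ValueError("gamma criteria must be positive")
        if not (0 < self.low_dose_threshold < 1):
            raise ValueError("low-dose threshold must be in (0, 1)")

    @property
    def label(self) -> str:
        return f"{self.dose_percent:g}%/{self.dta_mm:g}mm"


@dataclass
class DvhCurve:
    structure: str
    doses_desc: np.ndarray  # voxel doses sorted descending, Gy

    def __post_init__(self) -> None:
        self.doses_desc = np.asarray(self.doses_desc, dtype=float)
        if self.doses_desc.size == 0:
            raise EmptyMaskError("DVH of an empty structure")

    def fraction_above(self, dose_gy: float) -> float:
        """Cumulative volume fraction receiving at least ``dose_gy``."""
        return float(np.mean(self.doses_desc >= dose_gy))

    def table(self, n: int = 200) -> np.ndarray:
        """(dose, volume fraction) pairs spanning 0 to the maximum dose."""
        top = float(self.doses_desc[0]) if self.doses_desc[0] > 0 else 1.0
        doses = np.linspace(0.0, top, n)
        return np.column_stack([doses, [self.fraction_above(d) for d in doses]])


def hu_to_density(ct: VolumeGrid) -> VolumeGrid:
    """Piecewise-linear HU to relative (water = 1) density conversion.

    rho = 1 + HU/1000 up to 100 HU, then a reduced slope reaching 2.0 at
    1600 HU, clipped at zero.
    """
    hu = ct.values
    low = 1.0 + hu / 1000.0
    high = 1.1 + (hu - 100.0) * (0.9 / 1500.0)
    rho = np.where(hu <= 100.0, low, high)
    return VolumeGrid(np.clip(rho, 0.0, None), ct.spacing, ct.origin, Modality.DENSITY)


def compute_arc_dose(
    ct: VolumeGrid,
    structures: StructureSet,
    plan: PlanSpec,
    scale: float | None = None,
    return_scale: bool = False,
):
    """Deterministic multi-angle exponential-attenuation dose on a CT volume.

    With ``scale=None`` the dose is normalized so the mean PTV dose equals
    the prescription and (optionally) the factor returned; recalculating a
    fixed plan on another volume passes that factor back in, as a clinical
    recalculation keeps the monitor units of the original plan.
    """
    if "ptv" not in structures or not structures["ptv"].any():
        raise EmptyMaskError("plan needs a non-empty PTV structure")
    ptv = structures["ptv"]
    rho = hu_to_density(ct).values
    sp = ct.spacing
    dose = np.zeros_like(rho)
    for angle in np.linspace(0.0, 360.0, plan.n_angles, endpoint=False):
        if angle % 360 == 0:
            rot_rho, rot_ptv = rho, ptv.astype(float)
        else:
            rot_rho = ndimage.rotate(rho, angle, axes=(1, 2), reshape=False, order=1, cval=0.0)
            rot_ptv = ndimage.rotate(
                ptv.astype(float), angle, axes=(1, 2), reshape=False, order=1, cval=0.0
            )
        # parallel beam along +rows: water-equivalent depth at voxel centers
        wepl = (np.cumsum(rot_rho, axis=1) - 0.5 * rot_rho) * sp[1]
        fluence = np.exp(-plan.mu_per_mm * wepl)
        proj = rot_ptv.max(axis=1) > 0.5  # (slices, cols) PTV projection
        if proj.any():
            aperture = (
                ndimage.distance_transform_edt(~proj, sampling=(sp[0], sp[2]))
                <= plan.aperture_margin_mm
            )
        else:
            aperture = proj
        beam = fluence * aperture[:, None, :]
        if angle % 360 == 0:
            dose += beam
        else:
            dose += ndimage.rotate(beam, -angle, axes=(1, 2), reshape=False, order=1, cval=0.0)
    if scale is None:
        mean_ptv = float(dose[ptv].mean())
        if mean_ptv <= 0:
            raise ValueError("zero dose in PTV; plan geometry broken")
        scale = plan.prescription_gy / mean_ptv
    dose = np.clip(dose * scale, 0.0, None)
    grid = VolumeGrid(dose, ct.spacing, ct.origin, Modality.DOSE_GY)
    return (grid, scale) if return_scale else grid


# ---------------------------------------------------------------------------
# DVH


def dvh_curve(dose: VolumeGrid, mask: np.ndarray, structure: str = "structure") -> DvhCurve:
    if not mask.any():
        raise EmptyMaskError(f"empty structure {structure!r}")
    vals = np.sort(dose.values[mask])[::-1]
    return DvhCurve(structure, vals)


def dvh_metric(curve: DvhCurve, x_percent: float) -> float:
    """D_x%: minimum dose received by the hottest x% of the structure."""
    if not (0 < x_percent <= 100):
        raise ValueError("x_percent must be in (0, 100]")
    n = curve.doses_desc.size
    rank = max(1, math.ceil(x_percent / 100.0 * n))
    return float(curve.doses_desc[rank - 1])


DVH_METRICS = (98.0, 95.0, 50.0, 5.0, 2.0)


def dvh_metrics_table(dose: VolumeGrid, mask: np.ndarray, structure: str = "structure") -> dict[str, float]:
    curve = dvh_curve(dose, mask, structure)
    return {f"D{x:g}%": dvh_metric(curve, x) for x in DVH_METRICS}


# ---------------------------------------------------------------------------
# gamma


def _refine3(values: np.ndarray) -> np.ndarray:
    """Trilinear refinement on a 3x finer grid aligned with the voxel centers."""
    fine_idx = [np.arange(3 * (n - 1) + 1) / 3.0 for n in values.shape]
    grids = np.meshgrid(*fine_idx, indexing="ij")
    return ndimage.map_coordinates(values, np.stack(grids), order=1, mode="nearest")


@dataclass
class GammaResult:
    gamma: np.ndarray  # gamma map; NaN where below the low-dose threshold
    pass_rate_percent: float
    criteria: GammaCriteria
    evaluated: np.ndarray = field(repr=False, default=None)


def gamma_evaluate(
    ref_dose: VolumeGrid, eval_dose: VolumeGrid, criteria: GammaCriteria
) -> GammaResult:
    """3-D global gamma of ``eval_dose`` against ``ref_dose``.

    For each reference voxel at or above the low-dose threshold (fraction of
    the reference maximum), gamma is the minimum over candidate positions of
    ``sqrt((dose diff / (DD% * Dmax))^2 + (distance / DTA)^2)``; candidates
    are the evaluated grid refined 3x per axis within ``search_radius_factor
    * DTA``.  Pass rate is the percentage of evaluated voxels with gamma <= 1.
    """
    if not ref_dose.same_geometry(eval_dose):
        raise ValueError("dose grids must share geometry")
    ref = ref_dose.values
    d_norm = float(ref.max())
    evaluated = ref >= criteria.low_dose_threshold * d_norm
    if d_norm <= 0 or not evaluated.any():
        raise EmptyMaskError("no voxels above the low-dose threshold")
    dd = criteria.dose_percent / 100.0 * d_norm
    fine = _refine3(eval_dose.values)
    sp = np.asarray(ref_dose.spacing)
    fine_sp = sp / 3.0
    radius = criteria.search_radius_factor * criteria.dta_mm

    max_off = [int(math.floor(radius / fine_sp[a])) for a in range(3)]
    shape = ref.shape
    gamma2 = np.full(shape, np.inf)
    for dz in range(-max_off[0], max_off[0] + 1):
        for dy in range(-max_off[1], max_off[1] + 1):
            for dx in range(-max_off[2], max_off[2] + 1):
                dist2 = float(
                    (dz * fine_sp[0]) ** 2 + (dy * fine_sp[1]) ** 2 + (dx * fine_sp[2]) ** 2
                )
                if dist2 > radius * radius:
                    continue
                ref_sl, fine_sl = [], []
                ok = True
                for a, d in zip(range(3), (dz, dy, dx)):
                    n = shape[a]
                    lo = max(0, math.ceil(-d / 3.0))
                    hi = min(n, math.floor((3 * (n - 1) - d) / 3.0) + 1)
                    if lo >= hi:
                        ok = False
                        break
                    ref_sl.append(slice(lo, hi))
                    fine_sl.append(slice(3 * lo + d, 3 * (hi - 1) + d + 1, 3))
                if not ok:
                    continue
                diff = fine[tuple(fine_sl)] - ref[tuple(ref_sl)]
                cand = (diff / dd) ** 2 + dist2 / criteria.dta_mm**2
                np.minimum(gamma2[tuple(ref_sl)], cand, out=gamma2[tuple(ref_sl)])
    gamma = np.sqrt(gamma2)
    gamma[~evaluated] = np.nan
    pass_rate = 100.0 * float(np.mean(gamma[evaluated] <= 1.0))
    return GammaResult(gamma, pass_rate, criteria, evaluated)
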