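import math

import numpy as np
import pytest

from sctsynth.dosimetry import (
    GammaCriteria,
    PlanSpec,
    _refine3,
    compute_arc_dose,
    dvh_curve,
    dvh_metric,
    gamma_evaluate,
    hu_to_density,
)
from sctsynth.grid import Modality, VolumeGrid
from sctsynth.metrics import EmptyMaskError, StructureSet


def _ct(values, spacing=(2.0, 2.0, 2.0)):
    return VolumeGrid(np.asarray(values, float), spacing, modality=Modality.CT_HU)


def _dose(values, spacing=(2.0, 2.0, 2.0)):
    return VolumeGrid(np.asarray(values, float), spacing, modality=Modality.DOSE_GY)


class TestHuToDensity:
    @pytest.mark.parametrize(
        "hu,rho", [(0.0, 1.0), (-1000.0, 0.0), (-500.0, 0.5), (100.0, 1.1), (1600.0, 2.0)]
    )
    def test_anchor_points(self, hu, rho):
        out = hu_to_density(_ct(np.full((1, 1, 1), hu)))
        assert out.values.item() == pytest.approx(rho)

    def test_never_negative(self):
        out = hu_to_density(_ct(np.full((1, 1, 1), -1024.0)))
        assert out.values.item() == 0.0


def _water_phantom_with_ptv(n=21, spacing=2.0, r_vox=3):
    ct = _ct(np.zeros((n, n, n)), (spacing,) * 3)
    c = (n - 1) / 2
    z, y, x = np.ogrid[:n, :n, :n]
    ptv = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= r_vox**2
    ss = StructureSet({"ptv": ptv}, ct.spacing, ct.origin)
    return ct, ss, ptv


class TestArcDose:
    def test_mean_ptv_dose_equals_prescription(self):
        ct, ss, ptv = _water_phantom_with_ptv()
        dose = compute_arc_dose(ct, ss, PlanSpec(prescription_gy=60.0, n_angles=8))
        assert dose.values[ptv].mean() == pytest.approx(60.0)

    def test_symmetric_plan_gives_symmetric_dose(self):
        """Homogeneous water, centered spherical PTV, 4 cardinal angles."""
        ct, ss, _ = _water_phantom_with_ptv()
        dose = compute_arc_dose(ct, ss, PlanSpec(n_angles=4)).values
        assert np.allclose(dose, dose[:, ::-1, :], atol=1e-6)
        assert np.allclose(dose, dose[:, :, ::-1], atol=1e-6)
        assert np.allclose(dose, np.swapaxes(dose, 1, 2), atol=1e-6)

    def test_bone_slab_reduces_distal_dose(self):
        """Attenuation is monotone: a dense slab lowers every distal voxel
        of the axis-aligned beam (angle 0 travels along +rows)."""
        n = 21
        ct, ss, ptv = _water_phantom_with_ptv(n)
        plan = PlanSpec(n_angles=2)  # beams at 0 and 180 degrees
        ref = compute_arc_dose(ct, ss, plan, scale=1.0).values
        slab = ct.values.copy()
        slab[:, 4:6, :] = 1600.0  # dense slab crossing the angle-0 beam
        with_slab = compute_arc_dose(
            _ct(slab, ct.spacing), ss, plan, scale=1.0
        ).values
        aperture = ref[:, 12, :] > 0
        distal = ref[:, 12:, :]  # everything beyond the slab for beam 0
        assert np.all(with_slab[:, 12:, :][:, :, :][..., aperture.any(axis=0)] <= distal[..., aperture.any(axis=0)] + 1e-12)
        assert (with_slab[:, 12:, :] < distal - 1e-9).any()

    def test_empty_ptv_rejected(self):
        ct, _, _ = _water_phantom_with_ptv()
        ss = StructureSet({"ptv": np.zeros(ct.shape, bool)}, ct.spacing)
        with pytest.raises(EmptyMaskError):
            compute_arc_dose(ct, ss, PlanSpec())

    def test_dose_sensitive_to_hu(self):
        ct, ss, _ = _water_phantom_with_ptv()
        dose_a = compute_arc_dose(ct, ss, PlanSpec(), scale=1.0).values
        denser = _ct(np.full(ct.shape, 200.0), ct.spacing)
        dose_b = compute_arc_dose(denser, ss, PlanSpec(), scale=1.0).values
        assert not np.allclose(dose_a, dose_b)


class TestDvh:
    def test_uniform_dose_flat_metrics(self):
        dose = _dose(np.full((2, 5, 5), 60.0))
        curve = dvh_curve(dose, np.ones(dose.shape, bool))
        for x in (98, 50, 2):
            assert dvh_metric(curve, x) == 60.0

    def test_rank_convention_on_1_to_100(self):
        dose = _dose(np.arange(1.0, 101.0).reshape(4, 5, 5))
        curve = dvh_curve(dose, np.ones(dose.shape, bool))
        assert dvh_metric(curve, 95) == 6.0
        assert dvh_metric(curve, 2) == 99.0
        assert dvh_metric(curve, 98) == 3.0
        assert dvh_metric(curve, 50) == 51.0

    def test_metric_ordering(self, rng):
        dose = _dose(rng.uniform(0, 70, size=(4, 6, 6)))
        curve = dvh_curve(dose, np.ones(dose.shape, bool))
        values = [dvh_metric(curve, x) for x in (98, 95, 50, 5, 2)]
        assert values == sorted(values)

    def test_invalid_percent_rejected(self):
        dose = _dose(np.ones((2, 2, 2)))
        curve = dvh_curve(dose, np.ones(dose.shape, bool))
        for x in (0, -5, 101):
            with pytest.raises(ValueError):
                dvh_metric(curve, x)

    def test_empty_structure_rejected(self):
        with pytest.raises(EmptyMaskError):
            dvh_curve(_dose(np.ones((2, 2, 2))), np.zeros((2, 2, 2), bool))

    def test_cumulative_fraction_monotone(self, rng):
        dose = _dose(rng.uniform(0, 70, size=(3, 4, 4)))
        curve = dvh_curve(dose, np.ones(dose.shape, bool))
        fracs = [curve.fraction_above(d) for d in np.linspace(0, 80, 30)]
        assert fracs[0] == 1.0
        assert fracs[-1] == 0.0
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


def _brute_force_gamma(ref: VolumeGrid, ev: VolumeGrid, crit: GammaCriteria) -> np.ndarray:
    """Naive per-voxel search over the same 3x-refined grid and radius."""
    fine = _refine3(ev.values)
    sp = np.asarray(ref.spacing)
    fine_sp = sp / 3.0
    radius = crit.search_radius_factor * crit.dta_mm
    d_norm = ref.values.max()
    dd = crit.dose_percent / 100.0 * d_norm
    out = np.full(ref.shape, np.nan)
    evaluated = ref.values >= crit.low_dose_threshold * d_norm
    max_off = [int(math.floor(radius / fine_sp[a])) for a in range(3)]
    for i in np.ndindex(ref.shape):
        if not evaluated[i]:
            continue
        best = np.inf
        for dz in range(-max_off[0], max_off[0] + 1):
            for dy in range(-max_off[1], max_off[1] + 1):
                for dx in range(-max_off[2], max_off[2] + 1):
                    fz, fy, fx = 3 * i[0] + dz, 3 * i[1] + dy, 3 * i[2] + dx
                    if not (
                        0 <= fz < fine.shape[0]
                        and 0 <= fy < fine.shape[1]
                        and 0 <= fx < fine.shape[2]
                    ):
                        continue
                    dist2 = (dz * fine_sp[0]) ** 2 + (dy * fine_sp[1]) ** 2 + (dx * fine_sp[2]) ** 2
                    if dist2 > radius * radius:
                        continue
                    g2 = ((fine[fz, fy, fx] - ref.values[i]) / dd) ** 2 + dist2 / crit.dta_mm**2
                    best = min(best, g2)
        out[i] = np.sqrt(best)
    return out


class TestGamma:
    def test_identical_doses_pass_fully(self, rng):
        dose = _dose(rng.uniform(10, 70, size=(3, 4, 4)))
        res = gamma_evaluate(dose, dose, GammaCriteria(2, 2))
        assert res.pass_rate_percent == 100.0
        assert np.nanmax(res.gamma) == 0.0

    def test_uniform_one_percent_offset(self):
        ref = _dose(np.full((3, 4, 4), 100.0))
        ev = _dose(np.full((3, 4, 4), 101.0))
        res = gamma_evaluate(ref, ev, GammaCriteria(2, 2))
        assert np.nanmax(res.gamma) == pytest.approx(0.5)
        assert res.pass_rate_percent == 100.0

    def test_uniform_three_percent_offset_fails(self):
        ref = _dose(np.full((3, 4, 4), 100.0))
        ev = _dose(np.full((3, 4, 4), 103.0))
        res = gamma_evaluate(ref, ev, GammaCriteria(2, 2))
        assert np.nanmin(res.gamma) == pytest.approx(1.5)
        assert res.pass_rate_percent == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_search(self, seed):
        rng = np.random.default_rng(seed)
        ref = _dose(rng.uniform(0, 60, size=(5, 5, 3)), (2.5, 2.0, 2.0))
        ev = _dose(np.clip(ref.values + rng.normal(0, 2.0, ref.shape), 0, None), ref.spacing)
        crit = GammaCriteria(2, 2)
        res = gamma_evaluate(ref, ev, crit)
        brute = _brute_force_gamma(ref, ev, crit)
        assert np.allclose(res.gamma, brute, equal_nan=True)

    def test_pass_rate_monotone_in_criteria(self, rng):
        ref = _dose(rng.uniform(10, 60, size=(4, 6, 6)))
        ev = _dose(np.clip(ref.values * (1 + rng.normal(0, 0.02, ref.shape)), 0, None))
        p22 = gamma_evaluate(ref, ev, GammaCriteria(2, 2)).pass_rate_percent
        p32 = gamma_evaluate(ref, ev, GammaCriteria(3, 2)).pass_rate_percent
        p33 = gamma_evaluate(ref, ev, GammaCriteria(3, 3)).pass_rate_percent
        assert p22 <= p32 <= p33

    def test_global_scale_invariance(self, rng):
        ref = _dose(rng.uniform(10, 60, size=(3, 4, 4)))
        ev = _dose(np.clip(ref.values + rng.normal(0, 1, ref.shape), 0, None))
        a = gamma_evaluate(ref, ev, GammaCriteria(2, 2)).gamma
        b = gamma_evaluate(
            _dose(ref.values * 2), _dose(ev.values * 2), GammaCriteria(2, 2)
        ).gamma
        assert np.allclose(a, b, equal_nan=True)

    def test_all_below_threshold_rejected(self):
        ref = _dose(np.zeros((2, 2, 2)))
        with pytest.raises(EmptyMaskError):
            gamma_evaluate(ref, ref, GammaCriteria(2, 2))
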