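"""DVH metrics and SBRT conformity indices against analytic and
voxel-loop oracles."""

import numpy as np
import pytest

from sabrqa.core import (
    DoseDistribution,
    Prescription,
    StructureMask,
    StructureRole,
    VoxelGrid,
)
from sabrqa.dosimetry import (
    coverage_pct,
    d2cm_pct,
    d_cc,
    d_max,
    dvh,
    high_dose_spillage_pct,
    ptv_eval,
    r50,
    v_gy,
)
from sabrqa.synthetic import synth_dose

from conftest import box_mask, sphere_mask


def uniform_dose(grid, value):
    return DoseDistribution(grid, np.full(grid.shape, float(value)))


@pytest.fixture
def slab_with_gradient():
    """100 cc slab, dose rising linearly 0 -> 40 Gy along x."""
    grid = VoxelGrid((50, 25, 10), (2.0, 2.0, 2.0))
    mask = box_mask(grid, (0, 0, 0), (50, 25, 10), label="slab",
                    role=StructureRole.OAR)
    dose_vals = np.zeros(grid.shape)
    # dose constant within a 2 cc x-layer; 40 Gy at the hot end
    for i in range(50):
        dose_vals[i] = 40.0 * (i + 1) / 50.0
    return mask, DoseDistribution(grid, dose_vals)


class TestDvh:
    def test_uniform_dose_step(self, grid32):
        mask = box_mask(grid32, (0, 0, 0), (10, 10, 10))
        curve = dvh(mask, uniform_dose(grid32, 20.0), bin_gy=0.5)
        vol = mask.volume_cc
        assert curve.cumulative_volume_cc[0] == pytest.approx(vol)
        below = curve.dose_axis_gy <= 20.0
        assert np.allclose(curve.cumulative_volume_cc[below], vol)
        assert np.all(curve.cumulative_volume_cc[~below] == 0.0)

    def test_monotone_nonincreasing_random(self, grid32):
        rng = np.random.default_rng(0)
        mask = box_mask(grid32, (2, 2, 2), (30, 30, 30))
        dose = DoseDistribution(grid32, rng.uniform(0, 60, grid32.shape))
        curve = dvh(mask, dose)
        assert np.all(np.diff(curve.cumulative_volume_cc) <= 1e-12)

    def test_linear_slab_closed_form(self, slab_with_gradient):
        """Volume above d is (1 - d/40) of the slab, within one bin."""
        mask, dose = slab_with_gradient
        curve = dvh(mask, dose, bin_gy=0.1)
        vol = mask.volume_cc
        for d in (10.0, 20.0, 30.0):
            i = int(np.searchsorted(curve.dose_axis_gy, d))
            expected = vol * (1.0 - d / 40.0)
            assert curve.cumulative_volume_cc[i] == pytest.approx(
                expected, abs=vol / 50.0
            )

    def test_empty_mask_rejected(self, grid32):
        empty = box_mask(grid32, (0, 0, 0), (0, 0, 0))
        with pytest.raises(ValueError):
            dvh(empty, uniform_dose(grid32, 10.0))


class TestPointMetrics:
    def test_uniform_dose_all_metrics(self, grid32):
        mask = box_mask(grid32, (0, 0, 0), (10, 10, 10))
        dose = uniform_dose(grid32, 20.0)
        assert d_max(mask, dose) == 20.0
        assert d_cc(mask, dose, 3.0) == 20.0
        assert v_gy(mask, dose, 20.0) == pytest.approx(mask.volume_cc)
        assert v_gy(mask, dose, 20.01) == 0.0

    def test_dcc_tends_to_dmax(self, slab_with_gradient):
        mask, dose = slab_with_gradient
        assert d_cc(mask, dose, 1e-9) == d_max(mask, dose)

    def test_dcc_slab_closed_form(self, slab_with_gradient):
        # hottest 10 cc of a 100 cc slab with 0->40 Gy gradient: D >= 36 Gy
        mask, dose = slab_with_gradient
        assert d_cc(mask, dose, 10.0) == pytest.approx(36.0, abs=0.8)

    def test_dcc_exceeding_volume_rejected(self, slab_with_gradient):
        mask, dose = slab_with_gradient
        with pytest.raises(ValueError, match="exceeds"):
            d_cc(mask, dose, 1000.0)

    def test_voxel_loop_oracle_exact(self):
        """All point metrics equal explicit voxel loops on a small grid."""
        grid = VoxelGrid((16, 16, 16), (2.5, 2.0, 3.0))
        rng = np.random.default_rng(21)
        vox = rng.random(grid.shape) < 0.4
        mask = StructureMask(grid, vox, "m", StructureRole.OAR)
        dose = DoseDistribution(grid, rng.uniform(0, 50, grid.shape))
        doses = [
            dose.dose_gy[i, j, k]
            for i in range(16) for j in range(16) for k in range(16)
            if vox[i, j, k]
        ]
        vv = grid.voxel_volume_cc
        assert d_max(mask, dose) == max(doses)
        assert v_gy(mask, dose, 25.0) == sum(1 for d in doses if d >= 25.0) * vv
        v_req = 0.1
        n_hot = int(np.ceil(v_req / vv))
        assert d_cc(mask, dose, v_req) == sorted(doses, reverse=True)[n_hot - 1]


class TestCoverage:
    def test_full_coverage(self, grid32, rx40):
        ptv = box_mask(grid32, (5, 5, 5), (15, 15, 15))
        assert coverage_pct(ptv, uniform_dose(grid32, 40.0), rx40) == 100.0

    def test_half_coverage(self, grid32, rx40):
        ptv = box_mask(grid32, (0, 0, 0), (10, 10, 10))
        vals = np.zeros(grid32.shape)
        vals[:5] = 40.0  # exactly half the PTV voxels
        assert coverage_pct(ptv, DoseDistribution(grid32, vals), rx40) == 50.0

    def test_synth_plateau_full_coverage(self, centered_sphere, rx40):
        dose = synth_dose([centered_sphere], rx40, falloff_mm=16.0)
        assert coverage_pct(centered_sphere, dose, rx40) == 100.0


class TestR50:
    def test_sphere_phantom_continuum(self, centered_sphere, rx40):
        # 16 mm sphere, 16 mm linear falloff: 50% isodose at 24 mm,
        # continuum R50 = (24/16)^3 = 3.375
        dose = synth_dose([centered_sphere], rx40, falloff_mm=16.0)
        assert r50([centered_sphere], dose, rx40) == pytest.approx(3.375, rel=0.05)

    def test_dose_confined_to_ptv(self, grid32, rx40):
        ptv = box_mask(grid32, (5, 5, 5), (15, 15, 15))
        vals = np.where(ptv.voxels, 40.0, 0.0)
        assert r50([ptv], DoseDistribution(grid32, vals), rx40) == 1.0

    def test_second_distant_target_inflates_r50(self, grid64, rx40):
        """A second dose cloud inflates the single-PTV R50 — the
        motivation for the multi-target exemption."""
        c = 63.0
        a = sphere_mask(grid64, (40, c, c), 12.0, label="PTV")
        b = sphere_mask(grid64, (90, c, c), 12.0, label="PTV2")
        dose_single = synth_dose([a], rx40, falloff_mm=16.0)
        dose_both = synth_dose([a, b], rx40, falloff_mm=16.0)
        assert r50([a], dose_both, rx40) > r50([a], dose_single, rx40)


class TestD2cm:
    def test_falloff_shorter_than_shell_gives_zero(self, centered_sphere, rx40):
        dose = synth_dose([centered_sphere], rx40, falloff_mm=16.0)
        assert d2cm_pct([centered_sphere], dose, rx40) == 0.0

    def test_falloff_40mm_gives_half_prescription(self, centered_sphere, rx40):
        # dose at 20 mm = 40 * (1 - 20/40) = 20 Gy -> 50% of TD
        dose = synth_dose([centered_sphere], rx40, falloff_mm=40.0)
        assert d2cm_pct([centered_sphere], dose, rx40) == pytest.approx(50.0, abs=5.0)

    def test_uniform_dose_everywhere(self, centered_sphere, rx40):
        dose = uniform_dose(centered_sphere.grid, 40.0)
        assert d2cm_pct([centered_sphere], dose, rx40) == 100.0

    def test_monotone_in_shell_distance(self, centered_sphere, rx40):
        dose = synth_dose([centered_sphere], rx40, falloff_mm=40.0)
        vals = [
            d2cm_pct([centered_sphere], dose, rx40, shell_mm=s)
            for s in (12.0, 20.0, 30.0)
        ]
        assert vals[0] >= vals[1] >= vals[2]

    def test_grid_too_coarse_rejected(self, rx40):
        grid = VoxelGrid((20, 20, 20), (6.0, 6.0, 6.0))
        ptv = box_mask(grid, (8, 8, 8), (12, 12, 12))
        with pytest.raises(ValueError, match="coarse"):
            d2cm_pct([ptv], uniform_dose(grid, 40.0), Prescription("PTV", 40.0, 5))


class TestSpillage:
    def test_no_hot_voxels_outside(self, centered_sphere, rx40):
        dose = synth_dose([centered_sphere], rx40, falloff_mm=16.0)
        assert high_dose_spillage_pct([centered_sphere], dose, rx40) == 0.0

    def test_hotspot_confined_inside_is_zero(self, centered_sphere, rx40):
        dose = synth_dose([centered_sphere], rx40, falloff_mm=16.0, hotspot_pct=110.0)
        assert high_dose_spillage_pct([centered_sphere], dose, rx40) == 0.0

    def test_external_blob_voxel_count(self, grid32, rx40):
        # 8 hot voxels at 106% TD outside an 800-voxel PTV -> 1.0%
        ptv = box_mask(grid32, (0, 0, 0), (10, 10, 8))
        vals = np.where(ptv.voxels, 40.0, 0.0)
        vals[20:22, 20:22, 20:22] = 0.424 * 100  # 42.4 Gy = 106% of 40
        dose = DoseDistribution(grid32, vals)
        assert high_dose_spillage_pct([ptv], dose, rx40) == pytest.approx(1.0)


class TestPtvEval:
    def test_no_overlap_unchanged(self, grid32):
        ptv = box_mask(grid32, (0, 0, 0), (10, 10, 10), label="PTV")
        oar = box_mask(grid32, (20, 20, 20), (30, 30, 30), label="bowel",
                       role=StructureRole.OAR)
        ev = ptv_eval(ptv, [oar])
        assert np.array_equal(ev.voxels, ptv.voxels)
        assert ev.role == StructureRole.PTV_EVAL

    def test_oar_covering_ptv_empty_with_warning(self, grid32):
        ptv = box_mask(grid32, (2, 2, 2), (8, 8, 8), label="PTV")
        oar = box_mask(grid32, (0, 0, 0), (12, 12, 12), label="bowel",
                       role=StructureRole.OAR)
        with pytest.warns(UserWarning, match="empty"):
            ev = ptv_eval(ptv, [oar])
        assert ev.is_empty

    def test_half_overlap_volume(self, grid32):
        ptv = box_mask(grid32, (0, 0, 0), (10, 10, 10), label="PTV")
        oar = box_mask(grid32, (5, 0, 0), (15, 10, 10), label="bowel",
                       role=StructureRole.OAR)
        ev = ptv_eval(ptv, [oar])
        assert ev.volume_cc == pytest.approx(ptv.volume_cc / 2)

    def test_margin_expansion_subtracts_more(self, grid32):
        ptv = box_mask(grid32, (0, 0, 0), (10, 10, 10), label="PTV")
        oar = box_mask(grid32, (10, 0, 0), (14, 10, 10), label="bowel",
                       role=StructureRole.OAR)
        v0 = ptv_eval(ptv, [oar], margin_mm=0.0).volume_cc
        v4 = ptv_eval(ptv, [oar], margin_mm=4.0).volume_cc
        assert v4 < v0 == pytest.approx(ptv.volume_cc)


class TestInvariants:
    def test_dmax_bounds_dcc(self, slab_with_gradient):
        mask, dose = slab_with_gradient
        for v in (0.5, 5.0, 50.0):
            assert d_max(mask, dose) >= d_cc(mask, dose, v)

    def test_full_coverage_implies_r50_at_least_one(self, centered_sphere, rx40):
        dose = synth_dose([centered_sphere], rx40, falloff_mm=12.0)
        assert coverage_pct(centered_sphere, dose, rx40) == 100.0
        assert r50([centered_sphere], dose, rx40) >= 1.0
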