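"""Dose grid container and forward engine: linearity, superposition,
profile fidelity, transit limit, averaging readouts, persistence."""

import numpy as np
import pytest

import gpqa
from gpqa.grid import DoseGrid, GridSpec


def _single_shot_plan(cup=None, y=None, collimator=15, dwell=120.0):
    cup = cup or gpqa.CupGeometry(size_class="medium", inner_index=5)
    y = cup.apex_y / 2.0 if y is None else y
    cp = gpqa.ControlPoint(x=0.0, y=y, z=0.0, collimator=collimator, dwell_time=dwell)
    return gpqa.Plan(
        plan_id="one", cup=cup, control_points=[cp],
        targets=[gpqa.TargetStructure(label="PTV", volume=10.0, centroid=(0.0, y, 0.0))],
        prescription_Gy=8.0,
    )


class TestGridContainer:
    def test_point_dose_and_neighborhood_mean_on_uniform_grid(self):
        g = DoseGrid(origin=(0, 0, 0), spacing=(1, 1, 1), values=np.full((11, 11, 11), 3.5))
        assert g.point_dose((5.2, 4.9, 6.1)) == pytest.approx(3.5)
        assert g.neighborhood_mean((5, 5, 5)) == pytest.approx(3.5)

    def test_neighborhood_mean_equals_center_on_linear_ramp(self):
        g = DoseGrid(origin=(0, 0, 0), spacing=(1, 1, 1), values=np.zeros((11, 11, 11)))
        X, Y, Z = g.meshgrid()
        g.values = 1.0 + 0.05 * X + 0.02 * Y - 0.01 * Z
        assert g.neighborhood_mean((5, 5, 5)) == pytest.approx(g.values[5, 5, 5])

    def test_neighborhood_mean_matches_brute_force_125_voxel_average(self, lib):
        plan = _single_shot_plan()
        g = gpqa.compute_dose_grid(plan, lib, GridSpec.from_center((0, plan.cup.apex_y / 2, 0), 15.0, 1.0))
        p = (3.0, plan.cup.apex_y / 2 + 2.0, -4.0)
        i, j, k = g.voxel_index(p)
        acc = 0.0
        for di in range(-2, 3):
            for dj in range(-2, 3):
                for dk in range(-2, 3):
                    acc += g.values[i + di, j + dj, k + dk]
        assert g.neighborhood_mean(p) == pytest.approx(acc / 125.0, rel=1e-12)

    def test_point_outside_grid_raises(self):
        g = DoseGrid(origin=(0, 0, 0), spacing=(1, 1, 1), values=np.zeros((5, 5, 5)))
        with pytest.raises(ValueError, match="outside grid"):
            g.point_dose((10, 0, 0))
        with pytest.raises(ValueError, match="outside grid"):
            g.neighborhood_mean((1, 1, 1))  # 5x5x5 block would clip the edge

    def test_npz_and_text_round_trips(self, tmp_path):
        g = DoseGrid(origin=(1, 2, 3), spacing=(1, 2, 1), values=np.random.default_rng(0).random((4, 5, 6)))
        g.save(tmp_path / "g.npz")
        b = DoseGrid.load(tmp_path / "g.npz")
        np.testing.assert_array_equal(b.values, g.values)
        np.testing.assert_array_equal(b.origin, g.origin)
        np.testing.assert_array_equal(b.spacing, g.spacing)
        g.save_text(tmp_path / "g.json")
        t = DoseGrid.load_text(tmp_path / "g.json")
        np.testing.assert_allclose(t.values, g.values)


class TestForwardEngine:
    def test_single_shot_peak_is_rate_times_time(self, lib0):
        plan = _single_shot_plan(dwell=120.0)  # 2 min
        cp = plan.control_points[0]
        rate = lib0.dose_rate_lookup(15, plan.cup, cp.y, 0.0)
        g = gpqa.compute_dose_grid(plan, lib0, GridSpec.from_center(cp.position, 10.0, 1.0))
        assert g.point_dose(cp.position) == pytest.approx(rate * 2.0, rel=1e-12)
        assert g.values.max() == pytest.approx(rate * 2.0, rel=1e-12)

    def test_doubling_dwell_times_doubles_every_voxel(self, lib, small_plan_spec):
        plan = gpqa.generate_synthetic_plan(small_plan_spec, seed=4)
        spec = GridSpec.from_center(plan.target("PTV").centroid, 15.0, 2.0)
        g1 = gpqa.compute_dose_grid(plan, lib, spec)
        doubled = plan.model_copy(update={
            "control_points": [cp.model_copy(update={"dwell_time": 2 * cp.dwell_time})
                               for cp in plan.control_points]})
        g2 = gpqa.compute_dose_grid(doubled, lib, spec)
        np.testing.assert_allclose(g2.values, 2 * g1.values, rtol=1e-12)

    def test_two_point_plan_is_sum_of_single_points(self, lib):
        cup = gpqa.CupGeometry(size_class="medium", inner_index=5)
        y = cup.apex_y / 2
        cps = [gpqa.ControlPoint(x=-5, y=y, z=0, collimator=15, dwell_time=30),
               gpqa.ControlPoint(x=6, y=y + 3, z=2, collimator=25, dwell_time=45)]
        target = [gpqa.TargetStructure(label="PTV", volume=10.0, centroid=(0, y, 0))]
        spec = GridSpec.from_center((0, y, 0), 20.0, 2.0)
        both = gpqa.compute_dose_grid(
            gpqa.Plan(plan_id="ab", cup=cup, control_points=cps, targets=target, prescription_Gy=8),
            lib, spec)
        parts = [gpqa.compute_dose_grid(
            gpqa.Plan(plan_id="x", cup=cup, control_points=[cp], targets=target, prescription_Gy=8),
            lib, spec) for cp in cps]
        np.testing.assert_allclose(both.values, parts[0].values + parts[1].values, atol=1e-14)

    def test_grid_refinement_converges_at_isocenter(self, lib0):
        plan = _single_shot_plan()
        cp = plan.control_points[0]
        d1 = gpqa.compute_dose_grid(plan, lib0, GridSpec.from_center(cp.position, 8.0, 1.0)).point_dose(cp.position)
        d2 = gpqa.compute_dose_grid(plan, lib0, GridSpec.from_center(cp.position, 8.0, 0.5)).point_dose(cp.position)
        assert abs(d2 - d1) / d1 < 0.002

    def test_radial_profile_reproduces_library_ocr(self, lib0):
        # alpha = 0, centered shot: grid profile == central kernel
        plan = _single_shot_plan()
        cp = plan.control_points[0]
        g = gpqa.compute_dose_grid(plan, lib0, GridSpec.from_center(cp.position, 30.0, 1.0))
        rate = lib0.dose_rate_lookup(15, plan.cup, cp.y, 0.0)
        xs = np.arange(0.0, 28.0, 0.37)
        prof = np.array([g.point_dose((x, cp.y, 0.0)) for x in xs]) / (rate * 2.0)
        ocr = lib0.ocr_lookup(15, plan.cup, np.zeros_like(xs), xs)
        assert np.max(np.abs(prof - ocr)) < 0.005

    def test_transit_off_is_infinite_speed_limit(self, lib):
        cup = gpqa.CupGeometry(size_class="medium", inner_index=5)
        y = cup.apex_y / 2
        cps = [gpqa.ControlPoint(x=-5, y=y, z=0, collimator=15, dwell_time=30),
               gpqa.ControlPoint(x=5, y=y, z=0, collimator=15, dwell_time=30)]
        plan = gpqa.Plan(plan_id="t", cup=cup, control_points=cps,
                         targets=[gpqa.TargetStructure(label="PTV", volume=5, centroid=(0, y, 0))],
                         prescription_Gy=8)
        spec = GridSpec.from_center((0, y, 0), 15.0, 2.0)
        off = gpqa.compute_dose_grid(plan, lib, spec, transit=False)
        fast = gpqa.compute_dose_grid(plan, lib, spec, transit=True, table_speed=1e12)
        assert np.max(np.abs(off.values - fast.values)) < 1e-9
        slow = gpqa.compute_dose_grid(plan, lib, spec, transit=True, table_speed=5.0)
        assert np.all(slow.values >= off.values - 1e-12)
        assert slow.values.max() > off.values.max()

    def test_uncovered_cup_raises(self, lib):
        plan = _single_shot_plan(cup=gpqa.CupGeometry(size_class="small", inner_index=9))
        with pytest.raises(KeyError, match="does not cover"):
            gpqa.compute_dose_grid(plan, lib, GridSpec.from_center((0, 50, 0), 10.0, 1.0))


class TestMediumCorrection:
    def test_default_is_plus_1p6_percent(self):
        out = gpqa.apply_medium_correction(1.000)
        assert out.value == pytest.approx(1.016)
        assert (out.factor, out.sign) == (0.016, +1)

    def test_zero_factor_is_identity(self):
        assert gpqa.apply_medium_correction(2.5, factor=0.0).value == 2.5

    def test_sign_round_trip_leaves_second_order_residual(self):
        down = gpqa.apply_medium_correction(1.0, sign=-1)
        both = gpqa.apply_medium_correction(down.value, sign=+1)
        assert both.value == pytest.approx(1.0 - 0.016**2, rel=1e-12)

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            gpqa.apply_medium_correction(1.0, sign=0)
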