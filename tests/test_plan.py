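"""Plan model: file round-trips, QA shifts, reference-point selection,
jig coordinates and the synthetic-cohort generator."""

import numpy as np
import pydantic
import pytest

import gpqa
from gpqa.grid import DoseGrid
from gpqa.plan import _draw_pinned_beta


class TestPlanIO:
    def test_minimal_single_control_point_plan(self, tmp_path):
        p = tmp_path / "p.json"
        p.write_text(
            """{"format": "gpqa-plan-v1", "units": {"length": "mm", "time": "s", "dose": "Gy"},
                "plan_id": "mini", "cup": {"size_class": "small", "inner_index": 3},
                "prescription_Gy": 8.0,
                "control_points": [{"x_mm": 0, "y_mm": 30, "z_mm": 0, "collimator_mm": 15, "time_s": 60}],
                "targets": []}"""
        )
        plan = gpqa.read_plan(p)
        assert plan.n_control_points == 1
        assert plan.control_points[0].collimator == 15

    def test_round_trip_is_lossless(self, tmp_path):
        plan = gpqa.generate_synthetic_plan(seed=3)
        path = tmp_path / "plan.json"
        gpqa.write_plan(plan, path)
        back = gpqa.read_plan(path)
        assert back == plan

    def test_invalid_collimator_rejected_with_field_name(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(
            """{"plan_id": "bad", "cup": {"size_class": "small", "inner_index": 3},
                "prescription_Gy": 8.0,
                "control_points": [{"x_mm": 0, "y_mm": 30, "z_mm": 0, "collimator_mm": 20, "time_s": 60}],
                "targets": []}"""
        )
        with pytest.raises(pydantic.ValidationError, match="collimator"):
            gpqa.read_plan(p)

    def test_cup_base_diameter_must_match_size_class(self):
        with pytest.raises(pydantic.ValidationError, match="base_diameter"):
            gpqa.CupGeometry(size_class="small", inner_index=3, base_diameter=121.7)


class TestQAPlan:
    def _toy_plan(self, centroid=(10.0, 20.0, 30.0)):
        cup = gpqa.CupGeometry(size_class="large", inner_index=8)
        cps = [
            gpqa.ControlPoint(x=centroid[0] + dx, y=centroid[1] + dy, z=centroid[2] + dz,
                              collimator=15, dwell_time=1.0)
            for dx, dy, dz in [(0, 0, 0), (5, -3, 2), (-4, 6, -1)]
        ]
        targets = [gpqa.TargetStructure(label="GTV", volume=5.0, centroid=centroid)]
        return gpqa.Plan(plan_id="toy", cup=cup, control_points=cps, targets=targets,
                         prescription_Gy=8.0)

    def test_shift_moves_all_points_by_chamber_minus_centroid(self):
        plan = self._toy_plan(centroid=(10.0, 20.0, 30.0))
        qa = gpqa.make_qa_plan(plan, (0.0, 0.0, 0.0), centroid_of="GTV")
        for cp, old in zip(qa.control_points, plan.control_points):
            assert (cp.x, cp.y, cp.z) == (old.x - 10.0, old.y - 20.0, old.z - 30.0)
        assert qa.is_qa_plan and qa.qa_metadata["centroid_of"] == "GTV"
        for cp, old in zip(qa.control_points, plan.control_points):
            assert cp.dwell_time == old.dwell_time and cp.collimator == old.collimator

    def test_chamber_at_centroid_is_identity(self):
        plan = self._toy_plan()
        qa = gpqa.make_qa_plan(plan, plan.targets[0].centroid)
        for cp, old in zip(qa.control_points, plan.control_points):
            assert (cp.x, cp.y, cp.z) == (old.x, old.y, old.z)

    def test_shifted_target_centroid_lands_on_chamber(self):
        plan = self._toy_plan()
        chamber = (-3.0, 55.0, 7.0)
        qa = gpqa.make_qa_plan(plan, chamber, centroid_of="GTV")
        # recompute: target centroid must now coincide with the chamber
        assert np.allclose(qa.target("GTV").centroid, chamber)

    def test_shift_preserves_pairwise_distances(self):
        plan = gpqa.generate_synthetic_plan(
            gpqa.PlanGeneratorSpec(n_control_points=(30.0, 35.0, 40.0)), seed=5
        )
        qa = gpqa.make_qa_plan(plan, (0.0, plan.target("GTV").centroid[1], 0.0))
        p0 = np.array([cp.position for cp in plan.control_points])
        p1 = np.array([cp.position for cp in qa.control_points])
        d0 = np.linalg.norm(p0[:, None] - p0[None, :], axis=-1)
        d1 = np.linalg.norm(p1[:, None] - p1[None, :], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)

    def test_missing_target_raises(self):
        plan = self._toy_plan()
        with pytest.raises(KeyError, match="PTV"):
            gpqa.make_qa_plan(plan, (0, 0, 0), centroid_of="PTV")


class TestJigCoordinates:
    @pytest.mark.parametrize(
        "point,expected",
        [((0.0, 50.0, 0.0), (0.0, 0.0, 50.0)),
         ((10.0, 0.0, 0.0), (10.0, 0.0, 0.0)),
         ((0.0, 0.0, 10.0), (10.0, 90.0, 0.0))],
    )
    def test_conventions(self, point, expected):
        assert gpqa.to_jig_coordinates(point) == pytest.approx(expected)

    def test_round_trip_on_random_points(self, rng):
        pts = rng.uniform(-60, 60, size=(10_000, 3))
        for p in pts[:: max(1, len(pts) // 10_000)]:
            back = gpqa.from_jig_coordinates(gpqa.to_jig_coordinates(tuple(p)))
            assert np.allclose(back, p, atol=1e-9)


def _uniform_grid(value=5.0, n=21, spacing=1.0):
    return DoseGrid(origin=(0.0, 0.0, 0.0), spacing=(spacing,) * 3,
                    values=np.full((n, n, n), value))


class TestLowGradientPoint:
    def _structure(self, grid, centroid, volume=4.0):
        mask = gpqa.sphere_mask(grid, centroid, volume)
        return gpqa.TargetStructure(label="GTV", volume=volume, centroid=centroid, mask=mask)

    def test_uniform_dose_returns_centroid_voxel(self):
        grid = _uniform_grid()
        s = self._structure(grid, (10.0, 10.0, 10.0))
        ref = gpqa.find_low_gradient_point(grid, s)
        assert ref.position == (10.0, 10.0, 10.0)

    def test_steep_linear_gradient_has_no_qualifying_voxel(self):
        grid = _uniform_grid()
        x = grid.axes()[0]
        grid.values = 1.0 * (1.0 + 0.02 * x)[:, None, None] * np.ones_like(grid.values)
        s = self._structure(grid, (10.0, 10.0, 10.0))
        with pytest.raises(ValueError, match="no low-gradient point"):
            gpqa.find_low_gradient_point(grid, s)

    def test_plateau_plus_penumbra_matches_brute_force(self):
        # synthetic blob: flat-ish top with steep shoulders
        grid = _uniform_grid(n=31)
        X, Y, Z = grid.meshgrid()
        r = np.sqrt((X - 15) ** 2 + (Y - 15) ** 2 + (Z - 15) ** 2)
        grid.values = 1.0 / (1.0 + np.exp((r - 8.0) / 1.5))
        s = self._structure(grid, (15.0, 15.0, 15.0), volume=3.0)
        ref = gpqa.find_low_gradient_point(grid, s)

        # independent exhaustive scan
        best = None
        sp = grid.spacing
        for i, j, k in np.asarray(s.mask["voxels"]):
            if min(i, j, k) < 1 or max(i, j, k) > 29:
                continue
            d = grid.values[i, j, k]
            g = max(
                abs(grid.values[i + 1, j, k] - grid.values[i - 1, j, k]) / (2 * sp[0]),
                abs(grid.values[i, j + 1, k] - grid.values[i, j - 1, k]) / (2 * sp[1]),
                abs(grid.values[i, j, k + 1] - grid.values[i, j, k - 1]) / (2 * sp[2]),
            ) / d
            if g >= 0.005:
                continue
            pos = grid.origin + np.array([i, j, k]) * sp
            dist = np.linalg.norm(pos - np.array(s.centroid))
            key = (-d, dist)
            if best is None or key < best[0]:
                best = (key, tuple(pos))
        assert best is not None
        assert ref.position == pytest.approx(best[1])


class TestSyntheticGenerator:
    def test_same_seed_reproduces_plan(self, small_plan_spec):
        a = gpqa.generate_synthetic_plan(small_plan_spec, seed=11)
        b = gpqa.generate_synthetic_plan(small_plan_spec, seed=11)
        assert a == b

    def test_attribute_draws_stay_within_cohort_envelopes(self, rng):
        spec = gpqa.PlanGeneratorSpec()
        for name in ("gtv_cc", "ptv_cc", "breast_cc", "n_control_points"):
            lo, _, hi = getattr(spec, name)
            draws = np.array([
                _draw_pinned_beta(rng, getattr(spec, name), spec.concentration)
                for _ in range(1000)
            ])
            assert draws.min() >= lo and draws.max() <= hi

    def test_attribute_means_converge_to_cohort_averages(self, rng):
        # Monte-Carlo mean of the configured Beta distributions
        spec = gpqa.PlanGeneratorSpec()
        for name in ("gtv_cc", "ptv_cc", "breast_cc", "n_control_points"):
            lo, mean, hi = getattr(spec, name)
            draws = np.array([
                _draw_pinned_beta(rng, getattr(spec, name), spec.concentration)
                for _ in range(20_000)
            ])
            se = draws.std() / np.sqrt(len(draws))
            assert abs(draws.mean() - mean) < 4 * se + 1e-9

    def test_generated_plan_is_geometrically_valid(self):
        plan = gpqa.generate_synthetic_plan(seed=2)
        plan.validate_geometry()
        spec = gpqa.PlanGeneratorSpec()
        assert spec.gtv_cc[0] <= plan.target("GTV").volume <= spec.gtv_cc[2]
        assert spec.n_control_points[0] <= plan.n_control_points <= spec.n_control_points[2]
        lo, hi = spec.dwell_time_s
        for cp in plan.control_points:
            assert lo - 1e-12 <= cp.dwell_time <= hi + 1e-12
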