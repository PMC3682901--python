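"""Isodose volumes, overlaps, margin expansion and location classification."""

import numpy as np
import pytest

from rtrecur import (
    ImageVolume,
    VoxelMask,
    classify_location,
    expand_margin,
    isodose_mask,
    max_extension,
    overlap,
    voxelize,
)
from rtrecur.phantoms import make_recurrence_fixture, sphere_roi, sphere_volume_ml

from conftest import make_grid


def ball_mask(grid, center, radius_mm, name="ball") -> VoxelMask:
    pts = grid.voxel_center_points()
    inside = np.sum((pts - np.asarray(center, float)) ** 2, axis=-1) <= radius_mm**2
    return VoxelMask(
        inside.astype(float), grid.origin, grid.spacing, grid.orientation, name=name
    )


def box_mask(grid, lo, hi) -> VoxelMask:
    pts = grid.voxel_center_points()
    inside = np.all((pts >= np.asarray(lo, float)) & (pts <= np.asarray(hi, float)), axis=-1)
    return VoxelMask(inside.astype(float), grid.origin, grid.spacing, grid.orientation)


class TestIsodoseMask:
    def test_uniform_dose_at_reference_covers_whole_grid(self, coarse_grid):
        dose = ImageVolume(np.full(coarse_grid.shape, 44.5), coarse_grid.origin,
                           coarse_grid.spacing)
        with pytest.warns(UserWarning, match="whole grid"):
            mask = isodose_mask(dose, 80.0, 44.5)
        assert mask.occupancy.all()

    def test_linear_gradient_top_fraction(self, coarse_grid):
        """80% of the 0->50 Gy ramp: exactly the top 20% of the axis extent."""
        ny = coarse_grid.shape[1]
        ramp = np.linspace(0.0, 50.0, ny)[None, :, None]
        dose = ImageVolume(np.broadcast_to(ramp, coarse_grid.shape).copy(),
                           coarse_grid.origin, coarse_grid.spacing)
        mask = isodose_mask(dose, 80.0, 50.0)
        rows = np.nonzero(mask.occupancy[0, :, 0])[0]
        expected_first = int(np.ceil(0.8 * (ny - 1)))
        assert abs(rows[0] - expected_first) <= 1
        assert rows[-1] == ny - 1

    def test_threshold_above_range_gives_empty_mask(self, coarse_grid):
        dose = ImageVolume(np.full(coarse_grid.shape, 10.0), coarse_grid.origin,
                           coarse_grid.spacing)
        with pytest.warns(UserWarning, match="empty"):
            mask = isodose_mask(dose, 100.0, 20.0)
        assert not mask.occupancy.any()

    def test_invalid_arguments(self, coarse_grid):
        dose = ImageVolume(np.ones(coarse_grid.shape), coarse_grid.origin,
                           coarse_grid.spacing)
        with pytest.raises(ValueError):
            isodose_mask(dose, 0.0, 50.0)
        with pytest.raises(ValueError):
            isodose_mask(dose, 80.0, -1.0)


class TestOverlap:
    def test_containment_and_disjointness(self, coarse_grid):
        rec = ball_mask(coarse_grid, (0, 0, 0), 10.0)
        superset = ball_mask(coarse_grid, (0, 0, 0), 20.0)
        assert overlap(rec, superset).overlap_pct == pytest.approx(100.0)
        far = ball_mask(coarse_grid, (35, 35, 30), 8.0)
        assert overlap(rec, far).overlap_pct == 0.0

    def test_half_overlapping_boxes(self, coarse_grid):
        a = box_mask(coarse_grid, (-20, -20, -15), (0, 20, 15))
        b = box_mask(coarse_grid, (-10, -20, -15), (10, 20, 15))
        result = overlap(a, b)
        assert result.overlap_pct == pytest.approx(50.0, abs=0.5)

    def test_symmetric_in_ml_not_in_pct(self, coarse_grid):
        a = ball_mask(coarse_grid, (0, 0, 0), 15.0)
        b = ball_mask(coarse_grid, (10, 0, 0), 10.0)
        ab, ba = overlap(a, b), overlap(b, a)
        assert ab.overlap_ml == pytest.approx(ba.overlap_ml, rel=1e-12)
        assert ab.overlap_pct < ba.overlap_pct

    def test_zero_recurrence_rejected(self, coarse_grid):
        empty = VoxelMask(np.zeros(coarse_grid.shape), coarse_grid.origin,
                          coarse_grid.spacing)
        other = ball_mask(coarse_grid, (0, 0, 0), 10.0)
        with pytest.raises(ValueError, match="zero volume"):
            overlap(empty, other)

    def test_grid_mismatch_rejected(self, coarse_grid, fine_grid):
        a = ball_mask(coarse_grid, (0, 0, 0), 10.0)
        b = ball_mask(fine_grid, (0, 0, 0), 10.0)
        with pytest.raises(ValueError, match="same grid"):
            overlap(a, b)


class TestExpandMargin:
    def test_zero_margin_is_binarization(self, coarse_grid):
        occ = np.zeros(coarse_grid.shape)
        occ[10:14, 20:24, 20:24] = 0.7
        occ[14, 20, 20] = 0.2  # below the binarization threshold
        mask = VoxelMask(occ, coarse_grid.origin, coarse_grid.spacing)
        out = expand_margin(mask, 0.0)
        np.testing.assert_array_equal(out.occupancy, (occ >= 0.5).astype(float))

    def test_ball_dilation_matches_closed_form(self):
        """20 mm ball + 10 mm margin vs the 30 mm ball: 113.10 ml."""
        grid = make_grid((40, 72, 72), (1.5, 1.5, 2.0))
        ball = ball_mask(grid, (0, 0, 0), 20.0)
        grown = expand_margin(ball, 10.0)
        truth = sphere_volume_ml(30.0)
        assert truth == pytest.approx(113.10, abs=0.005)
        assert grown.volume_ml == pytest.approx(truth, rel=0.02)

    def test_two_step_equals_one_step_within_2pct(self):
        grid = make_grid((40, 72, 72), (1.5, 1.5, 2.0))
        ball = ball_mask(grid, (0, 0, 0), 15.0)
        once = expand_margin(ball, 20.0)
        twice = expand_margin(expand_margin(ball, 10.0), 10.0)
        assert twice.volume_ml == pytest.approx(once.volume_ml, rel=0.02)

    @pytest.mark.parametrize("margin", [0.0, 3.0, 7.5, 12.0])
    def test_extensive_and_monotone(self, coarse_grid, margin):
        """Expansion contains the binarized input and grows with the margin."""
        rng = np.random.default_rng(11)
        occ = (rng.random(coarse_grid.shape) > 0.995).astype(float)
        occ[15, 24, 24] = 1.0
        mask = VoxelMask(occ, coarse_grid.origin, coarse_grid.spacing)
        grown = expand_margin(mask, margin)
        assert np.all(grown.occupancy >= mask.binarized().occupancy)
        larger = expand_margin(mask, margin + 4.0)
        assert np.all(larger.occupancy >= grown.occupancy)

    def test_negative_margin_rejected(self, coarse_grid):
        mask = ball_mask(coarse_grid, (0, 0, 0), 10.0)
        with pytest.raises(ValueError, match="non-negative"):
            expand_margin(mask, -1.0)


class TestMaxExtension:
    def test_zero_inside_boost(self, coarse_grid):
        rec = ball_mask(coarse_grid, (0, 0, 0), 10.0)
        boost = ball_mask(coarse_grid, (0, 0, 0), 20.0)
        assert max_extension(rec, boost, "3d") == 0.0
        assert max_extension(rec, boost, "axial") == 0.0

    def test_point_30mm_from_ball_surface(self):
        grid = make_grid((30, 64, 64), (2.0, 2.0, 3.0))
        boost = ball_mask(grid, (0, 0, 0), 15.0)
        occ = np.zeros(grid.shape)
        # single voxel at x = 45 mm, i.e. 30 mm beyond the 15 mm ball surface
        idx = np.round(grid.physical_to_index([[45.0, 1.0, 1.5]])[0]).astype(int)
        occ[idx[2], idx[1], idx[0]] = 1.0
        rec = VoxelMask(occ, grid.origin, grid.spacing)
        diag_cm = np.linalg.norm(grid.spacing) / 10.0
        assert max_extension(rec, boost, "3d") == pytest.approx(3.0, abs=diag_cm)

    def test_axial_never_exceeds_3d(self, coarse_grid):
        """In-plane distance to the boost's axial projection <= 3D distance."""
        rng = np.random.default_rng(5)
        boost = ball_mask(coarse_grid, (0, 0, -15), 12.0)
        for _ in range(10):
            c = rng.uniform((-40, -40, -20), (40, 40, 25))
            rec = ball_mask(coarse_grid, c, 6.0)
            if not rec.occupancy.any():
                continue
            assert max_extension(rec, boost, "axial") <= (
                max_extension(rec, boost, "3d") + 1e-9
            )

    def test_empty_boost_rejected(self, coarse_grid):
        rec = ball_mask(coarse_grid, (0, 0, 0), 10.0)
        empty = VoxelMask(np.zeros(coarse_grid.shape), coarse_grid.origin,
                          coarse_grid.spacing)
        with pytest.raises(ValueError, match="empty"):
            max_extension(rec, empty)


class TestClassifyLocation:
    def test_recurrence_inside_boost(self, coarse_grid):
        rec = ball_mask(coarse_grid, (0, 0, 0), 10.0)
        boost = ball_mask(coarse_grid, (0, 0, 0), 18.0)
        cls = classify_location(rec, boost)
        assert all(cls.membership.values())
        assert cls.outfield_volume_ml == pytest.approx(0.0, abs=1e-9)
        assert cls.max_extension_cm_3d == 0.0

    def test_shell_at_12mm_belongs_to_15_and_20_not_10(self):
        """The boost grown to a +12 mm shell: inside +1.5 and +2 cm only."""
        grid = make_grid((40, 72, 72), (1.5, 1.5, 2.0))
        boost = ball_mask(grid, (0, 0, 0), 20.0)
        rec = expand_margin(boost, 12.0)
        rec.name = "Recurrence"
        cls = classify_location(rec, boost, containment_threshold=0.95)
        assert not cls.membership["boost"]
        assert not cls.membership["boost+10mm"]
        assert cls.membership["boost+15mm"]
        assert cls.membership["boost+20mm"]
        # coverage of boost+10mm matches the (30/32)^3 ball-volume ratio
        assert cls.coverage["boost+10mm"] == pytest.approx((30 / 32) ** 3, abs=0.02)

    def test_unsorted_margins_rejected(self, coarse_grid):
        rec = ball_mask(coarse_grid, (0, 0, 0), 10.0)
        boost = ball_mask(coarse_grid, (0, 0, 0), 15.0)
        with pytest.raises(ValueError, match="ascending"):
            classify_location(rec, boost, margins_mm=(15.0, 10.0))

    @pytest.mark.parametrize("seed", range(12))
    def test_coverage_nesting_monotonicity_randomized(self, seed):
        """Coverage never decreases across nested shells, whatever the geometry."""
        rng = np.random.default_rng(seed)
        grid = make_grid((24, 40, 40), (2.5, 2.5, 3.0))
        boost = ball_mask(grid, rng.uniform(-10, 10, 3), rng.uniform(8, 16))
        rec = ball_mask(grid, rng.uniform(-25, 25, 3), rng.uniform(5, 20))
        if not rec.occupancy.any() or not boost.occupancy.any():
            pytest.skip("degenerate random draw")
        cls = classify_location(rec, boost)
        values = [cls.coverage[k] for k in cls.shell_labels()]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_directional_extension_identifies_protrusion_axis(self):
        grid = make_grid((30, 64, 64), (2.0, 2.0, 3.0))
        fixture = make_recurrence_fixture(
            grid, boost_radius_mm=15.0, extension_mm=20.0, direction=(0, 1, 0)
        )
        rec = voxelize(fixture["recurrence"], grid, max_level=1)
        boost = voxelize(fixture["boost"], grid, max_level=1)
        cls = classify_location(rec, boost)
        directions = cls.directional_extension_cm
        assert directions["y+"] == pytest.approx(2.0, abs=0.4)
        assert directions["y+"] >= max(v for k, v in directions.items() if k != "y+")


class TestRecurrenceFixture:
    def test_zero_extension_expectations(self, coarse_grid):
        fixture = make_recurrence_fixture(coarse_grid, extension_mm=0.0)
        assert all(fixture["expected"]["membership"].values())
        assert fixture["expected"]["max_extension_cm"] == 0.0

    @pytest.mark.parametrize("extension_mm", [8.0, 12.0, 25.0])
    def test_classification_matches_closed_form_metadata(self, extension_mm):
        """Pipeline classification reproduces the fixture's analytic coverage."""
        grid = make_grid((30, 72, 72), (2.0, 2.0, 3.0))
        fixture = make_recurrence_fixture(
            grid, boost_radius_mm=18.0, extension_mm=extension_mm,
            lobe_radius_mm=9.0,
        )
        rec = voxelize(fixture["recurrence"], grid, max_level=2)
        boost = voxelize(fixture["boost"], grid, max_level=2)
        cls = classify_location(rec, boost)
        expected = fixture["expected"]
        assert rec.volume_ml == pytest.approx(
            expected["recurrence_vol_ml"], rel=0.02
        )
        for label, value in expected["coverage"].items():
            assert cls.coverage[label] == pytest.approx(value, abs=0.02), label
        assert cls.max_extension_cm_3d == pytest.approx(
            expected["max_extension_cm"], abs=np.linalg.norm(grid.spacing) / 10.0
        )
        # containment is exact once the margin reaches the extension
        for label, margin in zip(
            ["boost+10mm", "boost+15mm", "boost+20mm"], [10.0, 15.0, 20.0]
        ):
            if extension_mm <= margin:
                assert cls.membership[label], label

    def test_6_26cm_extension_reproduced(self):
        """A 62.6 mm protrusion is measured as a 6.26 cm extension."""
        grid = make_grid((30, 110, 110), (2.0, 2.0, 3.0))
        fixture = make_recurrence_fixture(
            grid, boost_radius_mm=20.0, extension_mm=62.6, direction=(1, 0, 0)
        )
        rec = voxelize(fixture["recurrence"], grid, max_level=1)
        boost = voxelize(fixture["boost"], grid, max_level=1)
        cls = classify_location(rec, boost)
        assert cls.max_extension_cm_3d == pytest.approx(6.26, abs=0.2)
        assert cls.max_extension_cm_axial == pytest.approx(6.26, abs=0.2)
        assert cls.outfield_volume_ml > 0
        assert not cls.membership["boost+20mm"]
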