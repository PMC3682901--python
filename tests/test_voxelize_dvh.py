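"""Subvoxel voxelization, dose sampling, DVHs and descriptive statistics."""

import numpy as np
import pytest

from rtrecur import (
    ImageVolume,
    ROI,
    RigidTransform,
    VoxelMask,
    compute_dvh,
    dose_stats,
    sample_dose,
    voxelize,
)
from rtrecur.dvh import DoseSamples
from rtrecur.phantoms import sphere_roi, sphere_volume_ml
from rtrecur.structures import Contour

from conftest import make_grid
from oracles import brute_force_dose_stats


def box_roi(x0, x1, y0, y1, slice_z, name="box"):
    contours = [
        Contour(np.array([[x0, y0, z], [x1, y0, z], [x1, y1, z], [x0, y1, z]]))
        for z in slice_z
    ]
    return ROI(name=name, contours=contours)


def uniform_dose(grid, value):
    return ImageVolume(
        np.full(grid.shape, float(value)), grid.origin, grid.spacing,
        grid.orientation,
    )


def gradient_dose(grid, max_gy=50.0, y_span=None):
    """Linear ramp along y: 0 at y_span[0] to max_gy at y_span[1].

    Defaults to the grid's voxel-center extent.
    """
    nz, ny, nx = grid.shape
    ys = grid.origin[1] + np.arange(ny) * grid.spacing[1]
    y0, y1 = y_span if y_span is not None else (ys[0], ys[-1])
    ramp = (max_gy * (ys - y0) / (y1 - y0))[None, :, None]
    return ImageVolume(
        np.broadcast_to(ramp, grid.shape).copy(), grid.origin, grid.spacing
    )


class TestVoxelize:
    def test_lattice_aligned_box_is_exact(self, coarse_grid):
        """Box edges on voxel boundaries: occupancy exactly 0/1, volume exact."""
        # voxel centers at odd x in [-47, 47]; boundaries at even coordinates
        roi = box_roi(-20.0, 20.0, -10.0, 14.0, coarse_grid.slice_positions()[5:10])
        mask = voxelize(roi, coarse_grid, max_level=2, tolerance=0.0)
        inside = mask.occupancy > 0
        assert np.all(np.isin(mask.occupancy[inside], 1.0))
        expected = 40.0 * 24.0 * 5 * 3.0 / 1000.0
        assert mask.volume_ml == pytest.approx(expected, rel=1e-9)

    def test_sphere_volume_converges_within_1pct(self, fine_grid):
        """25 mm sphere on a 1 x 1 x 3 mm grid: converged volume near 65.45 ml."""
        roi = sphere_roi("s", (0, 0, 0), 25.0, fine_grid.slice_positions())
        mask = voxelize(roi, fine_grid)
        truth = sphere_volume_ml(25.0)
        assert truth == pytest.approx(65.45, abs=0.005)
        assert abs(mask.volume_ml - truth) / truth < 0.01
        assert mask.level >= 1

    def test_refinement_moves_volume_toward_closed_form(self, fine_grid):
        """The converged estimate is closer to the closed form than level 0."""
        roi = sphere_roi("s", (0, 0, 0), 25.0, fine_grid.slice_positions())
        truth = sphere_volume_ml(25.0)
        coarse = voxelize(roi, fine_grid, max_level=0).volume_ml
        converged = voxelize(roi, fine_grid).volume_ml
        assert abs(converged - truth) < abs(coarse - truth)

    def test_achieved_level_reported_and_convergence_stops_early(self, fine_grid):
        roi = sphere_roi("s", (0, 0, 0), 25.0, fine_grid.slice_positions())
        loose = voxelize(roi, fine_grid, max_level=3, tolerance=0.5)
        tight = voxelize(roi, fine_grid, max_level=3, tolerance=0.0)
        assert loose.level < tight.level == 3

    def test_off_plane_contour_assigned_to_nearest_slice(self, coarse_grid):
        z = coarse_grid.slice_positions()[-1] + 2.5  # beyond half a thickness
        roi = box_roi(-10, 10, -10, 10, [z])
        with pytest.warns(UserWarning, match="nearest slice"):
            mask = voxelize(roi, coarse_grid, max_level=0)
        assert mask.occupancy[-1].sum() > 0

    def test_empty_roi_rejected(self, coarse_grid):
        with pytest.raises(ValueError, match="no contours"):
            voxelize(ROI(name="empty"), coarse_grid)

    def test_self_intersecting_polygon_warns_but_runs(self, coarse_grid):
        z = coarse_grid.slice_positions()[5]
        bowtie = Contour(
            np.array([[-10, -10, z], [10, 10, z], [10, -10, z], [-10, 10, z]])
        )
        with pytest.warns(UserWarning, match="self-intersecting"):
            mask = voxelize(ROI(name="bowtie", contours=[bowtie]), coarse_grid,
                            max_level=1)
        # even-odd rule fills the two opposing triangles: half the 20x20 square
        assert mask.volume_ml == pytest.approx(0.6, rel=0.15)


class TestSampleDose:
    def test_uniform_field_sampled_exactly(self, coarse_grid):
        roi = sphere_roi("s", (0, 0, 0), 15.0, coarse_grid.slice_positions())
        mask = voxelize(roi, coarse_grid, max_level=1)
        samples = sample_dose(uniform_dose(coarse_grid, 44.5), mask)
        np.testing.assert_allclose(samples.dose_gy, 44.5)
        assert samples.undefined_volume_ml == 0.0
        assert samples.total_volume_ml == pytest.approx(mask.volume_ml)

    def test_centered_box_in_linear_gradient_has_mean_at_midpoint(self, coarse_grid):
        roi = box_roi(-20, 20, -24, 24, coarse_grid.slice_positions()[8:22])
        mask = voxelize(roi, coarse_grid, max_level=1)
        samples = sample_dose(gradient_dose(coarse_grid, 50.0), mask)
        mean = np.average(samples.dose_gy, weights=samples.volume_ml)
        assert mean == pytest.approx(25.0, abs=0.1)

    def test_mask_half_outside_dose_grid_reported_as_undefined(self, coarse_grid):
        # dose grid covering only y >= 0 (upper half of the mask)
        nz, ny, nx = coarse_grid.shape
        half = ImageVolume(
            np.full((nz, ny // 2, nx), 10.0),
            (coarse_grid.origin[0], 0.0, coarse_grid.origin[2]),
            coarse_grid.spacing,
        )
        roi = box_roi(-20, 20, -24, 24, coarse_grid.slice_positions()[8:22])
        mask = voxelize(roi, coarse_grid, max_level=0)
        samples = sample_dose(half, mask, max_undefined_fraction=0.9)
        assert samples.undefined_volume_ml == pytest.approx(
            0.5 * samples.total_volume_ml, rel=0.02
        )

    def test_grid_mismatch_beyond_half_raises(self, coarse_grid):
        far = ImageVolume(
            np.full((4, 4, 4), 10.0), (500.0, 500.0, 500.0), (2, 2, 3)
        )
        roi = box_roi(-20, 20, -24, 24, coarse_grid.slice_positions()[8:22])
        mask = voxelize(roi, coarse_grid, max_level=0)
        with pytest.raises(ValueError, match="outside the dose grid"):
            sample_dose(far, mask)


class TestDVH:
    def test_uniform_dose_gives_step_function(self):
        samples = DoseSamples(
            dose_gy=np.full(100, 20.0), volume_ml=np.full(100, 0.1),
            undefined_volume_ml=0.0, total_volume_ml=10.0,
        )
        dvh = compute_dvh(samples, bin_width=0.5)
        at_or_below = dvh.dose_edges <= 20.0
        np.testing.assert_allclose(dvh.volume[at_or_below], 10.0, atol=1e-9)
        np.testing.assert_allclose(dvh.volume[~at_or_below], 0.0, atol=1e-9)

    def test_cumulative_non_increasing_and_starts_at_total(self, coarse_grid):
        roi = box_roi(-20, 20, -24, 24, coarse_grid.slice_positions()[8:22])
        mask = voxelize(roi, coarse_grid, max_level=1)
        samples = sample_dose(gradient_dose(coarse_grid, 50.0), mask)
        dvh = compute_dvh(samples)
        assert np.all(np.diff(dvh.volume) <= 1e-12)
        assert dvh.volume[0] == pytest.approx(dvh.total_volume_ml)

    def test_linear_gradient_gives_linear_cumulative_dvh(self, coarse_grid):
        """Uniform dose density over the box: DVH(d) falls linearly in d."""
        roi = box_roi(-20, 20, -24, 24, coarse_grid.slice_positions()[8:22])
        mask = voxelize(roi, coarse_grid, max_level=1)
        samples = sample_dose(gradient_dose(coarse_grid, 50.0), mask)
        dvh = compute_dvh(samples, bin_width=0.5)
        d0, d1 = samples.dose_gy.min(), samples.dose_gy.max()
        interior = (dvh.dose_edges > d0 + 1) & (dvh.dose_edges < d1 - 1)
        expected = dvh.total_volume_ml * (d1 - dvh.dose_edges[interior]) / (d1 - d0)
        # the sampled DVH is a staircase with one step per distinct dose level
        step = dvh.total_volume_ml * coarse_grid.spacing[1] * 50.0 / 94.0 / (d1 - d0)
        np.testing.assert_allclose(dvh.volume[interior], expected, atol=step)

    def test_two_point_distribution_differential(self):
        samples = DoseSamples(
            dose_gy=np.array([10.0] * 50 + [40.0] * 50),
            volume_ml=np.full(100, 0.2),
            undefined_volume_ml=0.0, total_volume_ml=20.0,
        )
        dvh = compute_dvh(samples, bin_width=1.0)
        diff = dvh.to_differential(samples)
        nonzero = np.nonzero(diff.volume)[0]
        assert len(nonzero) == 2
        np.testing.assert_allclose(diff.volume[nonzero], [10.0, 10.0])
        assert diff.volume.sum() == pytest.approx(20.0, rel=1e-9)

    def test_union_of_disjoint_masks_adds_binwise(self, coarse_grid):
        """DVH(A ∪ B) = DVH(A) + DVH(B) for disjoint masks."""
        dose = gradient_dose(coarse_grid, 50.0)
        zs = coarse_grid.slice_positions()
        roi_a = box_roi(-30, -6, -20, 20, zs[8:18])
        roi_b = box_roi(6, 30, -20, 20, zs[8:18])
        roi_ab = ROI(name="union", contours=(
            box_roi(-30, -6, -20, 20, zs[8:18]).contours
            + box_roi(6, 30, -20, 20, zs[8:18]).contours
        ))
        def dvh_of(roi):
            mask = voxelize(roi, coarse_grid, max_level=1)
            return compute_dvh(sample_dose(dose, mask), bin_width=0.5)
        a, b, ab = dvh_of(roi_a), dvh_of(roi_b), dvh_of(roi_ab)
        n = min(len(a.volume), len(b.volume), len(ab.volume))
        np.testing.assert_allclose(
            ab.volume[:n], a.volume[:n] + b.volume[:n], rtol=1e-9, atol=1e-9
        )

    def test_export_csv_round_trip(self, tmp_path, coarse_grid):
        roi = box_roi(-20, 20, -20, 20, coarse_grid.slice_positions()[8:12])
        mask = voxelize(roi, coarse_grid, max_level=0)
        dvh = compute_dvh(sample_dose(uniform_dose(coarse_grid, 30.0), mask))
        path = dvh.export_csv(tmp_path / "dvh.csv", structure="box", plan="base")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("# kind=cumulative")
        data = np.loadtxt(lines[2:], delimiter=",")
        np.testing.assert_allclose(data[0, 1], dvh.total_volume_ml, atol=1e-6)


class TestDoseStats:
    def test_uniform_dose_statistics(self, coarse_grid):
        roi = sphere_roi("s", (0, 0, 0), 15.0, coarse_grid.slice_positions())
        mask = voxelize(roi, coarse_grid, max_level=1)
        samples = sample_dose(uniform_dose(coarse_grid, 44.5), mask)
        stats = dose_stats(samples, isodose_threshold_gy=35.6)
        assert stats.min_gy == stats.max_gy == stats.median_gy == 44.5
        assert stats.vol_in_isodose_ml == pytest.approx(stats.recurrence_vol_ml)
        below = dose_stats(samples, isodose_threshold_gy=44.6)
        assert below.vol_in_isodose_ml == 0.0

    def test_gradient_box_median_and_isodose_fraction(self, coarse_grid):
        """Box in a ramp running 0 -> 50 Gy across it: median 25 Gy,
        volume at or above 80% of 50 Gy = 20% of the box volume."""
        roi = box_roi(-20, 20, -20, 20, coarse_grid.slice_positions()[8:22])
        mask = voxelize(roi, coarse_grid, max_level=1)
        dose = gradient_dose(coarse_grid, 50.0, y_span=(-20.0, 20.0))
        samples = sample_dose(dose, mask)
        stats = dose_stats(samples, isodose_threshold_gy=40.0)
        assert stats.median_gy == pytest.approx(25.0, abs=0.25)
        fraction = stats.vol_in_isodose_ml / stats.recurrence_vol_ml
        assert fraction == pytest.approx(0.20, abs=0.01)

    def test_stats_match_brute_force_oracle_on_small_grid(self):
        """Implementation vs independent 10x-supersampled enumeration (<=32^3)."""
        grid = make_grid((20, 28, 28), (2.0, 2.0, 2.0))
        dose = gradient_dose(grid, 50.0)
        # box faces through voxel-center planes so both estimators see the
        # same continuum boundary
        zs = grid.slice_positions()[5:15]
        roi = box_roi(-13.0, 13.0, -17.0, 17.0, zs)
        mask = voxelize(roi, grid, max_level=2, tolerance=0.0)
        samples = sample_dose(dose, mask)
        # isodose plane on a voxel boundary (y = 6 mm) so both estimators
        # resolve the same surface instead of straddling one voxel slab
        threshold = 50.0 * 33.0 / 54.0
        stats = dose_stats(samples, isodose_threshold_gy=threshold)

        def inside(pts):
            return (
                (np.abs(pts[:, 0]) <= 13.0)
                & (np.abs(pts[:, 1]) <= 17.0)
                & (pts[:, 2] >= zs[0] - 1.0)
                & (pts[:, 2] <= zs[-1] + 1.0)
            )

        oracle = brute_force_dose_stats(
            dose.voxels, dose.origin, dose.spacing,
            grid.origin, grid.spacing, grid.shape,
            inside, threshold_gy=threshold, supersample=10,
        )
        dose_range = float(dose.voxels.max() - dose.voxels.min())
        assert abs(stats.min_gy - oracle["min_gy"]) <= 0.01 * dose_range
        assert abs(stats.max_gy - oracle["max_gy"]) <= 0.01 * dose_range
        assert abs(stats.median_gy - oracle["median_gy"]) <= 0.01 * dose_range
        assert stats.vol_in_isodose_ml == pytest.approx(
            oracle["vol_in_isodose_ml"], rel=0.01
        )
        assert stats.recurrence_vol_ml == pytest.approx(
            oracle["total_volume_ml"], rel=0.01
        )

    def test_stats_invariant_under_simultaneous_rigid_motion(self, coarse_grid):
        """Moving mask and dose together must not change the statistics."""
        dose = gradient_dose(coarse_grid, 50.0)
        zs = coarse_grid.slice_positions()
        roi = box_roi(-16, 16, -20, 20, zs[8:20])
        mask = voxelize(roi, coarse_grid, max_level=1)
        base = dose_stats(sample_dose(dose, mask), 40.0)

        shift = RigidTransform(3.0, -7.0, 6.0)
        moved_dose = ImageVolume(
            dose.voxels, shift.apply(dose.origin[None])[0], dose.spacing
        )
        moved_roi = roi.transformed(shift)
        moved_grid = ImageVolume(
            np.zeros(coarse_grid.shape),
            shift.apply(coarse_grid.origin[None])[0], coarse_grid.spacing,
        )
        moved_mask = voxelize(moved_roi, moved_grid, max_level=1)
        moved = dose_stats(sample_dose(moved_dose, moved_mask), 40.0)
        dose_range = 50.0
        assert abs(moved.median_gy - base.median_gy) <= 0.005 * dose_range
        assert moved.recurrence_vol_ml == pytest.approx(
            base.recurrence_vol_ml, rel=0.01
        )
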