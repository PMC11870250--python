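"""Interval detection, peak tracking, plane construction and reformatting."""

import dataclasses

import numpy as np
import pytest

from jetquant import (ChamberMask, detect_mr_interval, estimate_plane_normal,
                      find_peak_velocity_voxel, place_planes,
                      reformat_throughplane)
from jetquant.phantom import analytic_jet_velocity
from jetquant.planes import DegenerateNormalError, JetPlane, NoJetError

from conftest import uniform_study


def full_mask(study):
    return ChamberMask(mask=np.ones(study.grid_shape, dtype=bool))


class TestInterval:
    def test_phantom_systole_detected(self, clean_phantom):
        cfg, study, mask, _ = clean_phantom
        interval = detect_mr_interval(study, mask, speed_threshold_cm_s=100.0)
        # half-sine over 300 ms at 30 ms frames: frames 1..9 exceed 100 cm/s
        assert (interval.t0, interval.t_end) == (1, 9)

    def test_zero_velocity_raises_no_jet(self):
        study = uniform_study((0.0, 0.0, 0.0))
        with pytest.raises(NoJetError):
            detect_mr_interval(study, full_mask(study))

    def test_override_wins(self, clean_phantom):
        _, study, mask, _ = clean_phantom
        interval = detect_mr_interval(study, mask, override=(3, 5))
        assert (interval.t0, interval.t_end) == (3, 5)


class TestPeakTracking:
    def test_single_spike_found(self):
        study = uniform_study((0.0, 0.0, 0.0))
        study.velocity[3, 4, 5, 1, 2] = 300.0
        assert find_peak_velocity_voxel(study, full_mask(study), 1) == (3, 4, 5)

    def test_tie_broken_by_previous_peak(self):
        study = uniform_study((0.0, 0.0, 0.0), shape=(10, 10, 10))
        study.velocity[2, 2, 2, 0, 2] = 300.0
        study.velocity[7, 7, 7, 0, 2] = 300.0
        near_a = find_peak_velocity_voxel(study, full_mask(study), 0,
                                          prev_peak=(2, 2, 3))
        near_b = find_peak_velocity_voxel(study, full_mask(study), 0,
                                          prev_peak=(7, 7, 6))
        assert near_a == (2, 2, 2)
        assert near_b == (7, 7, 7)

    def test_phantom_peak_on_centerline_at_orifice(self, clean_phantom):
        cfg, study, mask, _ = clean_phantom
        ci = (cfg.grid_shape[0] - 1) // 2
        peak = find_peak_velocity_voxel(study, mask, cfg.n_frames // 2)
        assert peak == (ci, ci, cfg.orifice_axial_index)

    def test_tracking_is_temporally_smooth(self, clean_phantom):
        cfg, study, mask, _ = clean_phantom
        prev = None
        for t in range(1, 10):
            peak = find_peak_velocity_voxel(study, mask, t, prev_peak=prev)
            if prev is not None:
                assert np.linalg.norm(np.subtract(peak, prev)) < 2
            prev = peak

    def test_seed_point_confines_search(self):
        """With two high-speed blobs, the seed picks its own region's max."""
        study = uniform_study((0.0, 0.0, 0.0), shape=(16, 16, 16))
        study.velocity[3, 3, 3, 0, 2] = 200.0
        study.velocity[12, 12, 12, 0, 2] = 300.0
        peak = find_peak_velocity_voxel(study, full_mask(study), 0,
                                        seed_world_mm=np.array([3.0, 3.0, 3.0]))
        assert peak == (3, 3, 3)


class TestNormalEstimation:
    def test_uniform_field(self):
        study = uniform_study((0.0, 0.0, 50.0))
        n = estimate_plane_normal(study, (4, 4, 4), 0)
        assert np.allclose(n, [0, 0, 1])

    def test_median_rejects_outlier(self):
        study = uniform_study((0.0, 0.0, 50.0))
        study.velocity[4, 4, 4, 0] = [50.0, 0.0, 0.0]  # outlier at the center
        n = estimate_plane_normal(study, (4, 4, 4), 0)
        # brute-force component medians over the 27 vectors: (0, 0, 50)
        assert np.allclose(n, [0, 0, 1])

    def test_sign_follows_center_velocity(self):
        study = uniform_study((0.0, 0.0, -50.0))
        n = estimate_plane_normal(study, (4, 4, 4), 0)
        assert np.allclose(n, [0, 0, -1])

    def test_phantom_normal_within_5deg_of_axis(self, clean_phantom):
        cfg, study, _, truth = clean_phantom
        ci = (cfg.grid_shape[0] - 1) // 2
        n = estimate_plane_normal(study, (ci, ci, cfg.orifice_axial_index),
                                  cfg.n_frames // 2)
        angle = np.degrees(np.arccos(np.clip(n @ truth.axis_direction, -1, 1)))
        assert angle < 5.0

    def test_zero_field_degenerate(self):
        study = uniform_study((0.0, 0.0, 0.0))
        with pytest.raises(DegenerateNormalError):
            estimate_plane_normal(study, (4, 4, 4), 0)


class TestPlaneFan:
    def test_default_offsets(self, clean_phantom):
        _, study, _, _ = clean_phantom
        planes = place_planes(study, np.zeros(3), np.array([0, 0, 1.0]), 5)
        assert [p.offset_mm for p in planes] == [-7.5, -5.0, -2.5, 0.0, 2.5, 5.0, 7.5]
        assert all(p.usable for p in planes)

    def test_custom_spacing_and_count(self, clean_phantom):
        _, study, _, _ = clean_phantom
        planes = place_planes(study, np.zeros(3), np.array([0, 0, 1.0]), 5,
                              spacing_mm=1.0, count=3)
        assert [p.offset_mm for p in planes] == [-1.0, 0.0, 1.0]

    def test_uniform_flow_keeps_normals_identical(self):
        study = uniform_study((0.0, 0.0, 80.0), shape=(24, 24, 24))
        planes = place_planes(study, np.full(3, 12.0), np.array([0, 0, 1.0]), 0)
        for p in planes:
            assert np.allclose(p.normal, [0, 0, 1])
            assert abs(p.basis_u @ p.normal) < 1e-12
            assert abs(p.basis_v @ p.normal) < 1e-12

    def test_phantom_normals_within_10deg_of_axis(self, clean_phantom):
        cfg, study, mask, truth = clean_phantom
        ci = (cfg.grid_shape[0] - 1) // 2
        t = cfg.n_frames // 2
        n0 = estimate_plane_normal(study, (ci, ci, cfg.orifice_axial_index), t)
        planes = place_planes(study, np.zeros(3), n0, t)
        for p in planes:
            ang = np.degrees(np.arccos(np.clip(p.normal @ truth.axis_direction,
                                               -1, 1)))
            assert ang < 10.0

    def test_out_of_grid_plane_flagged_not_dropped(self, clean_phantom):
        _, study, _, _ = clean_phantom
        edge = study.world_from_voxel(np.array([23.0, 23.0, 1.0]))
        planes = place_planes(study, edge, np.array([0, 0, 1.0]), 5)
        assert len(planes) == 7
        assert not planes[0].usable          # x = −7.5 leaves the grid
        assert planes[-1].usable

    def test_even_count_rejected(self, clean_phantom):
        _, study, _, _ = clean_phantom
        with pytest.raises(ValueError, match="odd"):
            place_planes(study, np.zeros(3), np.array([0, 0, 1.0]), 5, count=6)


class TestReformat:
    def _plane(self, center, normal, extent=5.0, pitch=0.5):
        normal = np.asarray(normal, dtype=float)
        normal /= np.linalg.norm(normal)
        axis = np.zeros(3)
        axis[np.argmin(np.abs(normal))] = 1.0
        u = np.cross(normal, axis)
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        return JetPlane(center_mm=np.asarray(center, float), normal=normal,
                        offset_mm=0.0, basis_u=u, basis_v=v,
                        extent_mm=extent, pitch_mm=pitch)

    def test_uniform_field_through_plane(self):
        study = uniform_study((0.0, 0.0, 100.0), shape=(16, 16, 16))
        tpm = reformat_throughplane(study, self._plane([7.5] * 3, [0, 0, 1]), 0)
        inside = ~tpm.outside
        assert np.allclose(tpm.values[inside], 100.0)
        assert tpm.pixel_area_mm2 == 0.25

    def test_oblique_plane_projects_cosine(self):
        study = uniform_study((0.0, 0.0, 100.0), shape=(16, 16, 16))
        normal = [np.sin(np.radians(60)), 0.0, np.cos(np.radians(60))]
        tpm = reformat_throughplane(study, self._plane([7.5] * 3, normal), 0)
        assert np.allclose(tpm.values[~tpm.outside], 50.0, atol=1e-9)

    def test_exact_for_linear_fields(self):
        """Trilinear interpolation reproduces affine velocity fields exactly."""
        rng = np.random.default_rng(11)
        study = uniform_study((0, 0, 0), shape=(20, 20, 20))
        A = rng.normal(size=(3, 3)) * 0.5
        c0 = rng.normal(size=3) * 10
        idx = np.stack(np.meshgrid(*[np.arange(20)] * 3, indexing="ij"), axis=-1)
        world = study.world_from_voxel(idx.astype(float))
        lin = world @ A.T + c0
        study.velocity[:] = lin[..., None, :]
        normal = np.array([0.3, -0.5, 0.8])
        normal /= np.linalg.norm(normal)
        plane = self._plane([9.5] * 3, normal, extent=3.0)
        tpm = reformat_throughplane(study, plane, 0)
        n_half = int(round(plane.extent_mm / plane.pitch_mm))
        coords = (np.arange(2 * n_half + 1) - n_half) * plane.pitch_mm
        a, b = np.meshgrid(coords, coords, indexing="ij")
        pts = plane.center_mm + a[..., None] * plane.basis_u + b[..., None] * plane.basis_v
        expected = (pts @ A.T + c0) @ normal
        inside = ~tpm.outside
        assert np.allclose(tpm.values[inside], expected[inside], atol=1e-9)

    def test_phantom_profile_matches_analytic_within_5pct_rms(self, clean_phantom):
        cfg, study, _, _ = clean_phantom
        t = cfg.n_frames // 2
        plane = self._plane([0.0, 0.0, 0.0], [0, 0, 1], extent=10.0)
        tpm = reformat_throughplane(study, plane, t)
        n_half = int(round(plane.extent_mm / plane.pitch_mm))
        coords = (np.arange(2 * n_half + 1) - n_half) * plane.pitch_mm
        a, b = np.meshgrid(coords, coords, indexing="ij")
        pts = np.stack([a, b, np.zeros_like(a)], axis=-1)
        expected = analytic_jet_velocity(pts, t * cfg.dt_ms, cfg)[..., 2]
        rms_err = np.sqrt(np.mean((tpm.values - expected) ** 2))
        rms_ref = np.sqrt(np.mean(expected ** 2))
        assert rms_err / rms_ref < 0.05

    def test_out_of_volume_pixels_flagged_zero(self):
        study = uniform_study((0.0, 0.0, 100.0), shape=(10, 10, 10))
        tpm = reformat_throughplane(study, self._plane([0.5, 0.5, 0.5], [0, 0, 1],
                                                       extent=10.0), 0)
        assert tpm.outside.any()
        assert np.all(tpm.values[tpm.outside] == 0.0)
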