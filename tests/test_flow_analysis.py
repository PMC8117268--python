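import numpy as np
import pytest
from scipy import ndimage

from flumen.flow_analysis import (
    AccelerationTrace,
    AnalysisPlane,
    CardiacPhases,
    antegrade_retrograde_volumes,
    centerline_length,
    compute_flow_trace,
    detect_cardiac_phases,
    differentiate_trace,
    estimate_vnr,
    extract_fl_subsection,
    mean_speed_trace,
    perturb_mask,
    perturb_plane,
)
from flumen.io import FL, TL, FlowTrace, FlumenError, LumenMask, VelocityField
from flumen.phantom import WaveformSpec, add_velocity_noise


def uniform_axial_field(shape=(20, 20, 10), speed=10.0, nt=2, voxel=1.0):
    data = np.zeros(shape + (nt, 3))
    data[..., 2] = speed
    return VelocityField(data=data, voxel_size=(voxel,) * 3,
                         frame_interval=47.0, venc=200.0)


class TestComputeFlowTrace:
    def test_uniform_speed_through_unit_area(self):
        # 10 cm/s through a 1 cm^2 disk ROI -> 10 ml/s
        fld = uniform_axial_field(shape=(40, 40, 10), speed=10.0, voxel=0.5)
        r_mm = np.sqrt(100.0 / np.pi)  # area 100 mm^2 = 1 cm^2
        plane = AnalysisPlane(origin=(10.0, 10.0, 2.5), normal=(0, 0, 1), roi_radius=r_mm)
        trace = compute_flow_trace(fld, plane)
        np.testing.assert_allclose(trace.flow_rate, 10.0, rtol=0.03)

    def test_zero_field_gives_zero_trace(self):
        fld = uniform_axial_field(speed=0.0)
        plane = AnalysisPlane(origin=(10, 10, 5), normal=(0, 0, 1), roi_radius=5.0)
        np.testing.assert_array_equal(compute_flow_trace(fld, plane).flow_rate, 0.0)

    def test_antegrade_sign_flip_negates(self):
        fld = uniform_axial_field(speed=10.0)
        kw = dict(origin=(10, 10, 5), normal=(0, 0, 1), roi_radius=5.0)
        q_pos = compute_flow_trace(fld, AnalysisPlane(antegrade_sign=1, **kw)).flow_rate
        q_neg = compute_flow_trace(fld, AnalysisPlane(antegrade_sign=-1, **kw)).flow_rate
        np.testing.assert_allclose(q_neg, -q_pos)

    def test_plane_outside_grid_errors(self):
        fld = uniform_axial_field()
        plane = AnalysisPlane(origin=(500, 500, 500), normal=(0, 0, 1), roi_radius=2.0)
        with pytest.raises(FlumenError):
            compute_flow_trace(fld, plane)


class TestDetectCardiacPhases:
    def test_half_sine_then_zeros(self):
        t = np.arange(20) * 0.05
        q = np.zeros(20)
        q[:10] = np.sin(np.pi * np.arange(10) / 9)
        q[0] = 0.0
        phases = detect_cardiac_phases(FlowTrace(time=t, flow_rate=q))
        assert phases.systole == (0, 9)

    def test_constant_positive_flow_falls_back_to_minimum(self):
        t = np.arange(10) * 0.1
        q = np.full(10, 5.0)
        q[7] = 4.0  # global minimum, no zero crossing
        phases = detect_cardiac_phases(FlowTrace(time=t, flow_rate=q))
        assert phases.systole[1] == 7

    def test_prescribed_systolic_fraction_recovered(self):
        wf = WaveformSpec(n_frames=20, systolic_fraction=0.35)
        t = np.arange(20) * wf.period / 20
        phases = detect_cardiac_phases(FlowTrace(time=t, flow_rate=wf.tl_inflow(t)))
        n_sys = phases.systole_frames.size
        assert abs(n_sys - 7) <= 1

    def test_all_zero_trace_errors(self):
        with pytest.raises(FlumenError):
            detect_cardiac_phases(FlowTrace(time=np.arange(5.0), flow_rate=np.zeros(5)))


class TestVolumes:
    def make_trace(self, q, dt=0.05):
        return FlowTrace(time=np.arange(len(q)) * dt, flow_rate=np.asarray(q, float))

    def test_nonnegative_trace_has_zero_retrograde(self):
        q = np.clip(np.sin(np.linspace(0, 2 * np.pi, 20)), 0, None)
        trace = self.make_trace(q)
        phases = detect_cardiac_phases(trace)
        _, retro = antegrade_retrograde_volumes(trace, phases)
        assert retro == 0.0

    def test_doubling_flow_doubles_volumes(self):
        rng = np.random.default_rng(0)
        q = np.sin(np.linspace(0, 2 * np.pi, 20)) + 0.1 * rng.normal(size=20)
        trace1 = self.make_trace(q)
        trace2 = self.make_trace(2 * q)
        phases = detect_cardiac_phases(trace1)
        a1, r1 = antegrade_retrograde_volumes(trace1, phases)
        a2, r2 = antegrade_retrograde_volumes(trace2, phases)
        assert a2 == pytest.approx(2 * a1)
        assert r2 == pytest.approx(2 * r1)

    def test_prescribed_phantom_volumes(self):
        wf = WaveformSpec(antegrade_tear_volume=10.0, diastolic_retrograde_volume=4.9)
        t = np.arange(wf.n_frames) * wf.period / wf.n_frames
        trace = self.make_trace(wf.tear_flow(t), dt=wf.period / wf.n_frames)
        phases = detect_cardiac_phases(trace)
        ante, retro = antegrade_retrograde_volumes(trace, phases)
        assert ante == pytest.approx(10.0, rel=0.02)
        assert retro == pytest.approx(4.9, rel=0.02)


class TestSubsection:
    def test_default_five_cm_window(self, dissection_mask):
        sub = extract_fl_subsection(dissection_mask, tear_axial_position=100.0)
        z = np.nonzero(sub.labels.any(axis=(0, 1)))[0] * 2.5 + 1.25
        assert z.min() >= 75.0 - 2.5 and z.max() <= 125.0 + 2.5
        assert sub.count(FL) > 0 and sub.count(TL) == 0

    def test_landmark_window(self, dissection_mask):
        sub = extract_fl_subsection(dissection_mask, 100.0, landmark_axial_position=60.0)
        z = np.nonzero(sub.labels.any(axis=(0, 1)))[0] * 2.5 + 1.25
        assert z.min() >= 60.0 - 2.5 and z.max() <= 100.0 + 2.5

    def test_edge_tear_truncates_with_warning(self, dissection_mask):
        with pytest.warns(UserWarning, match="truncated"):
            sub = extract_fl_subsection(dissection_mask, tear_axial_position=10.0)
        assert sub.count(FL) > 0

    def test_empty_subsection_errors(self, dissection_mask):
        mask = LumenMask(labels=(dissection_mask.labels == TL).astype(np.uint8),
                         voxel_size=dissection_mask.voxel_size)
        with pytest.raises(FlumenError):
            extract_fl_subsection(mask, 100.0)


class TestSpeedAndAcceleration:
    def test_constant_field_zero_acceleration(self):
        fld = uniform_axial_field(speed=30.0, nt=5)
        sel = np.ones(fld.grid_shape, bool)
        trace = differentiate_trace(mean_speed_trace(fld, sel))
        np.testing.assert_allclose(trace.acceleration, 0.0, atol=1e-12)

    def test_sinusoid_max_acceleration(self):
        # s(t) = V sin(2 pi t / T): max ds/dt ~ 2 pi V / T
        V, T, n = 50.0, 1.0, 40
        t = np.arange(n) * T / n
        trace = AccelerationTrace(time=t, mean_speed=V * np.sin(2 * np.pi * t / T) + 2 * V)
        acc = differentiate_trace(trace).acceleration
        assert acc.max() == pytest.approx(2 * np.pi * V / T, rel=0.02)

    def test_cyclic_acceleration_integrates_to_zero(self):
        rng = np.random.default_rng(1)
        t = np.arange(25) * 0.04
        trace = AccelerationTrace(time=t, mean_speed=rng.uniform(10, 50, 25))
        acc = differentiate_trace(trace).acceleration
        assert acc.sum() * 0.04 == pytest.approx(0.0, abs=1e-10)

    def test_leapfrog_reintegration_recovers_speed(self):
        # the discrete inverse of the cyclic central difference: even/odd chains
        rng = np.random.default_rng(2)
        n, dt = 24, 0.05
        s = rng.uniform(10, 50, n)
        t = np.arange(n) * dt
        acc = differentiate_trace(AccelerationTrace(time=t, mean_speed=s)).acceleration
        rec = np.empty(n)
        rec[0], rec[1] = s[0], s[1]
        for i in range(2, n):
            rec[i] = rec[i - 2] + 2 * dt * acc[i - 1]
        np.testing.assert_allclose(rec, s, atol=1e-10)

    def test_single_frame_derivative_errors(self):
        trace = AccelerationTrace(time=np.array([0.0]), mean_speed=np.array([5.0]))
        with pytest.raises(FlumenError):
            differentiate_trace(trace)


class TestCenterline:
    def test_straight_tube_length(self, tube_mask, tube_geometry):
        L = tube_geometry.axial_extent  # 60 mm
        length = centerline_length(tube_mask, TL, 0.0, L)
        assert length == pytest.approx(L * 1e-3, rel=0.05)

    def test_same_station_gives_zero(self, tube_mask):
        assert centerline_length(tube_mask, TL, 30.0, 30.0) == 0.0

    def test_ubend_longer_than_chord(self):
        # C-shaped tube: semicircle radius 25 mm in the x-z plane
        shape = (70, 13, 70)
        labels = np.zeros(shape, dtype=np.uint8)
        theta = np.linspace(0, np.pi, 200)
        cx, cz, r, tube_r = 32.0, 32.0, 25.0, 4.0
        xs, zs = cx + r * np.cos(theta), cz - r * np.sin(theta)
        X, Y, Z = np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij")
        for x0, z0 in zip(xs, zs):
            d2 = (X - x0) ** 2 + (Y - 6.5) ** 2 + (Z - z0) ** 2
            labels[d2 <= tube_r**2] = TL
        mask = LumenMask(labels=labels, voxel_size=(1, 1, 1))
        end_a, end_b = cx - r, cx + r
        length = centerline_length(mask, TL, end_a, end_b, axis=0)
        chord = (end_b - end_a) * 1e-3
        assert length > chord
        assert length == pytest.approx(np.pi * r * 1e-3, rel=0.15)

    def test_disconnected_lumen_errors(self, tube_mask):
        labels = tube_mask.labels.copy()
        labels[:, :, 10:12] = 0
        broken = LumenMask(labels=labels, voxel_size=tube_mask.voxel_size)
        with pytest.raises(FlumenError, match="disconnected"):
            centerline_length(broken, TL, 0.0, 60.0)


class TestEstimateVnr:
    def test_noise_free_is_infinite(self):
        fld = uniform_axial_field(speed=0.0)
        roi = np.zeros(fld.grid_shape, bool)
        roi[:5, :5, :] = True
        assert estimate_vnr(fld, roi) == np.inf

    def test_recovers_generator_vnr(self, pulsatile):
        fld, _ = pulsatile
        noisy = add_velocity_noise(fld, vnr=40.0, seed=3)
        roi = np.zeros(fld.grid_shape, bool)
        roi[:, :4, :] = True  # background margin (outside both lumens), static
        assert estimate_vnr(noisy, roi) == pytest.approx(40.0, rel=0.05)

    def test_roi_size_invariance(self, pulsatile):
        fld, _ = pulsatile
        noisy = add_velocity_noise(fld, vnr=40.0, seed=4)
        small = np.zeros(fld.grid_shape, bool)
        small[:, :2, :20] = True
        large = np.zeros(fld.grid_shape, bool)
        large[:, :4, :] = True
        v1, v2 = estimate_vnr(noisy, small), estimate_vnr(noisy, large)
        assert v1 == pytest.approx(v2, rel=0.10)

    def test_empty_roi_errors(self, pulsatile):
        fld, _ = pulsatile
        with pytest.raises(FlumenError):
            estimate_vnr(fld, np.zeros(fld.grid_shape, bool))


class TestPerturbMask:
    def test_smaller_is_subset(self, dissection_mask):
        out = perturb_mask(dissection_mask, "smaller", magnitude=1)
        for label in (TL, FL):
            assert np.all(out.lumen(label) <= dissection_mask.lumen(label))
            assert out.count(label) < dissection_mask.count(label)

    def test_larger_is_superset_and_disjoint(self, dissection_mask):
        out = perturb_mask(dissection_mask, "larger", magnitude=1)
        for label in (TL, FL):
            assert np.all(dissection_mask.lumen(label) <= out.lumen(label))
        assert not np.any(out.lumen(TL) & out.lumen(FL))

    def test_mixed_deterministic_by_seed(self, dissection_mask):
        a = perturb_mask(dissection_mask, "mixed", magnitude=1, seed=9)
        b = perturb_mask(dissection_mask, "mixed", magnitude=1, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)
        c = perturb_mask(dissection_mask, "mixed", magnitude=1, seed=10)
        assert not np.array_equal(a.labels, c.labels)

    def test_erosion_emptying_lumen_errors(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[4, 4, :] = TL  # 1-voxel-thick line: any erosion empties it
        labels[2, 2, :] = FL
        mask = LumenMask(labels=labels, voxel_size=(1, 1, 1))
        with pytest.raises(FlumenError, match="emptied"):
            perturb_mask(mask, "smaller", magnitude=1)


class TestPerturbPlane:
    def plane(self):
        return AnalysisPlane(origin=(10, 10, 10), normal=(0, 0, 1), roi_radius=5.0)

    def test_zero_bounds_is_identity(self):
        out = perturb_plane(self.plane(), max_tilt_deg=0.0, max_shift_mm=0.0, seed=0)
        np.testing.assert_allclose(out.origin, (10, 10, 10))
        np.testing.assert_allclose(out.normal, (0, 0, 1))

    @pytest.mark.parametrize("seed", range(5))
    def test_tilt_within_bound(self, seed):
        out = perturb_plane(self.plane(), max_tilt_deg=5.0, max_shift_mm=2.0, seed=seed)
        cos_angle = np.clip(np.dot(out.normal, (0, 0, 1)), -1, 1)
        assert np.degrees(np.arccos(cos_angle)) <= 5.0 + 1e-9
        assert np.linalg.norm(out.origin - np.array((10, 10, 10))) <= 2.0 + 1e-9
        assert np.linalg.norm(out.normal) == pytest.approx(1.0)

    def test_deterministic_by_seed(self):
        a = perturb_plane(self.plane(), 5.0, 2.0, seed=3)
        b = perturb_plane(self.plane(), 5.0, 2.0, seed=3)
        np.testing.assert_array_equal(a.origin, b.origin)
        np.testing.assert_array_equal(a.normal, b.normal)
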