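"""Synthetic-data generator: dipole physics, rotation regimes, recordings,
cohorts and the rejection-event injector."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pearlrot.pipeline import angular_speed
from pearlrot.simulate import (
    CLASSES,
    OrientationTrajectory,
    default_magnet_position,
    dipole_field,
    inject_rejection_event,
    simulate_clock_scene,
    simulate_cohort,
    simulate_recording,
    simulate_trajectory,
)


class TestDipoleField:
    def test_on_axis_field_is_twice_equatorial(self):
        d = 0.1
        on_axis = dipole_field([0, 0, 1], [0, 0, d])
        equatorial = dipole_field([0, 0, 1], [d, 0, 0])
        assert np.allclose(on_axis, [0, 0, 2 / d**3])
        assert np.allclose(equatorial, [0, 0, -1 / d**3])

    @given(st.integers(0, 2**31 - 1))
    def test_linear_in_moment(self, seed):
        rng = np.random.default_rng(seed)
        m, r = rng.normal(size=3), rng.normal(size=3)
        if np.linalg.norm(r) < 1e-3:
            return
        assert np.allclose(dipole_field(-m, r), -dipole_field(m, r))
        assert np.allclose(dipole_field(3.5 * m, r), 3.5 * dipole_field(m, r))

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError):
            dipole_field([0, 0, 1], [0, 0, 0])


class TestSimulateTrajectory:
    @pytest.mark.parametrize("cls", CLASSES)
    def test_unit_norm_everywhere(self, cls):
        traj = simulate_trajectory(cls, duration_s=7200, rate_hz=1 / 60, seed=5)
        assert np.max(np.abs(np.linalg.norm(traj.u, axis=1) - 1)) < 1e-9

    def test_other_without_wobble_is_static(self):
        traj = simulate_trajectory("Other", duration_s=3600, jitter=0.0, seed=0)
        assert np.allclose(traj.u, traj.u[0])
        assert angular_speed(traj).mean == pytest.approx(0.0, abs=1e-3)

    def test_other_wobble_speed_is_negligible(self):
        traj = simulate_trajectory("Other", duration_s=86400, rate_hz=1 / 60, seed=3)
        assert angular_speed(traj).mean < 0.05

    def test_atypical_closes_after_one_revolution(self):
        # speed 6 deg/min about a fixed axis: back to the start after 1 h
        traj = simulate_trajectory(
            "Atypical", duration_s=3600, speed_deg_min=6.0, jitter=0.0, axis=[0, 0, 1], seed=0
        )
        assert np.allclose(traj.u[-1], traj.u[0], atol=1e-6)
        assert angular_speed(traj).mean == pytest.approx(6.0, abs=1e-6)

    def test_round_mean_step_matches_requested_speed(self):
        traj = simulate_trajectory("Round", duration_s=604800, rate_hz=1 / 60, speed_deg_min=0.69, seed=11)
        assert angular_speed(traj).mean == pytest.approx(0.69, abs=0.02)

    def test_round_axis_disperses_much_more_than_atypical(self):
        def axis_dispersion(traj):
            axes = np.cross(traj.u[:-1], traj.u[1:])
            axes = axes / np.linalg.norm(axes, axis=1, keepdims=True)
            return 1.0 - np.linalg.norm(axes.mean(axis=0))

        rnd = simulate_trajectory("Round", duration_s=604800, rate_hz=1 / 60, seed=2)
        atyp = simulate_trajectory("Atypical", duration_s=604800, rate_hz=1 / 60, seed=2)
        assert axis_dispersion(rnd) > 0.3
        assert axis_dispersion(atyp) < 0.2

    def test_seed_determinism(self):
        a = simulate_trajectory("Round", duration_s=3600, seed=42)
        b = simulate_trajectory("Round", duration_s=3600, seed=42)
        assert np.array_equal(a.u, b.u)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            simulate_trajectory("Baroque", duration_s=10)


class TestClockScene:
    def test_perpendicular_sweeps_full_circle(self):
        traj, true_speed = simulate_clock_scene("perpendicular", duration_s=3600)
        assert true_speed == 6.0
        phi = np.unwrap(np.arctan2(traj.u[:, 1], traj.u[:, 0]))
        assert np.degrees(phi[-1] - phi[0]) == pytest.approx(360.0, abs=1e-9)

    def test_parallel_rotation_is_unobservable(self):
        traj, _ = simulate_clock_scene("parallel", duration_s=600)
        assert np.allclose(traj.u, [0, 0, 1])

    def test_diagonal_traces_quarter_arc_of_45_degree_cone(self):
        traj, _ = simulate_clock_scene("diagonal", duration_s=900)
        assert np.allclose(traj.u[:, 2], np.cos(np.radians(45)))
        # closed-form cone kinematics: points 90 deg apart in azimuth on a
        # 45-degree cone subtend arccos(cos^2 45) = 60 degrees
        expected = np.degrees(np.arccos(np.cos(np.radians(45)) ** 2))
        actual = np.degrees(np.arccos(np.clip(traj.u[0] @ traj.u[-1], -1, 1)))
        assert actual == pytest.approx(expected, abs=1e-9)

    def test_magnet_sits_at_requested_ring_height(self, dome):
        traj, _ = simulate_clock_scene("perpendicular", ring_position=3, duration_s=60)
        assert traj.magnet_position[2] == pytest.approx(dome.radius * np.sin(np.radians(60)))

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            simulate_clock_scene("sideways")


class TestSimulateRecording:
    def test_static_noiseless_channels_are_constant(self, dome):
        traj = simulate_trajectory("Other", duration_s=600, jitter=0.0, seed=0)
        rec = simulate_recording(traj, dome, noise_frac=0.0)
        assert np.allclose(rec.values, rec.values[0])

    def test_linearity_under_direction_flip(self, dome):
        traj = simulate_trajectory("Atypical", duration_s=600, jitter=0.0, seed=1)
        rec = simulate_recording(traj, dome, noise_frac=0.0)
        flipped = OrientationTrajectory(t=traj.t, u=-traj.u, magnet_position=traj.magnet_position)
        rec_f = simulate_recording(flipped, dome, noise_frac=0.0)
        assert np.allclose(rec_f.values, -rec.values, atol=1e-12)

    def test_clock_recording_is_hour_periodic(self, dome):
        traj, _ = simulate_clock_scene("perpendicular", duration_s=7200, rate_hz=1 / 60)
        rec = simulate_recording(traj, dome, noise_frac=0.0)
        first, second = rec.values[:60], rec.values[60:120]
        assert np.max(np.abs(first - second)) < 1e-9

    def test_seed_determinism_and_noise_level(self, dome):
        traj = simulate_trajectory("Round", duration_s=3600, rate_hz=1 / 60, seed=4)
        a = simulate_recording(traj, dome, noise_frac=0.05, seed=9)
        b = simulate_recording(traj, dome, noise_frac=0.05, seed=9)
        assert np.array_equal(a.values, b.values)
        clean = simulate_recording(traj, dome, noise_frac=0.0)
        resid = a.values - clean.values
        rms = np.sqrt(np.mean(clean.values**2))
        assert np.std(resid) == pytest.approx(0.05 * rms, rel=0.1)

    def test_csv_round_trip(self, dome):
        traj = simulate_trajectory("Other", duration_s=120, seed=0)
        rec = simulate_recording(traj, dome, noise_frac=0.05, seed=1)
        from pearlrot.simulate import SensorRecording

        restored = SensorRecording.from_csv(rec.to_csv(), dome)
        assert np.allclose(restored.values, rec.values)


class TestSimulateCohort:
    def test_cohort_structure_and_metadata(self):
        cohort = simulate_cohort(30, seed=7, acquisition_s=1200, sample_interval_s=60)
        assert len(cohort) == 30
        for rec in cohort:
            assert rec.true_class in CLASSES
            assert rec.culture_days >= rec.acq_offset_days >= 0
            if rec.true_class == "Other":
                assert rec.speed_deg_min == 0.0
            else:
                assert rec.speed_deg_min > 0
        groups = {r.harvest_date_group for r in cohort}
        assert len(groups) >= 2  # terciles of cultivation time

    def test_rotating_speeds_recover_generating_mean(self):
        cohort = simulate_cohort(200, seed=21, acquisition_s=120, sample_interval_s=60)
        speeds = [r.speed_deg_min for r in cohort if r.true_class != "Other"]
        se = 0.13 / np.sqrt(len(speeds))
        assert np.mean(speeds) == pytest.approx(0.69, abs=3 * se)

    def test_empty_cohort(self):
        assert simulate_cohort(0, seed=0) == []

    def test_invalid_probs(self):
        with pytest.raises(ValueError):
            simulate_cohort(5, class_probs=(0.5, 0.5, 0.5), seed=0)

    def test_seed_determinism(self):
        a = simulate_cohort(5, seed=3, acquisition_s=600)
        b = simulate_cohort(5, seed=3, acquisition_s=600)
        assert [r.true_class for r in a] == [r.true_class for r in b]
        assert all(np.array_equal(x.trajectory.u, y.trajectory.u) for x, y in zip(a, b))


class TestRejectionEvent:
    def test_onset_at_end_is_identity(self):
        traj = simulate_trajectory("Atypical", duration_s=600, jitter=0.0, seed=0)
        out = inject_rejection_event(traj, onset_s=traj.t[-1])
        assert np.array_equal(out.u, traj.u)

    def test_pre_onset_unchanged_and_peak_reached(self):
        traj = simulate_trajectory("Other", duration_s=7200, jitter=0.0, seed=0)
        out = inject_rejection_event(traj, onset_s=1800, peak_speed=4.8, ramp_s=600)
        i0 = int(np.searchsorted(traj.t, 1800))
        assert np.array_equal(out.u[: i0 + 1], traj.u[: i0 + 1])
        # after the ramp the speed holds at the peak
        post = OrientationTrajectory(t=out.t[3000:], u=out.u[3000:])
        assert angular_speed(post).mean == pytest.approx(4.8, rel=0.01)

    def test_onset_out_of_range(self):
        traj = simulate_trajectory("Other", duration_s=60, seed=0)
        with pytest.raises(ValueError):
            inject_rejection_event(traj, onset_s=1e6)


def test_default_magnet_position_is_second_ring_height(dome):
    pos = default_magnet_position(dome)
    assert pos[2] == pytest.approx(dome.radius * np.sin(np.radians(30)))
    assert pos[0] == pos[1] == 0.0
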