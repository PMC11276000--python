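"""Localization, linking, drift correction and MSD estimator correctness."""

import numpy as np
import pandas as pd
import pytest

import condkit as ck
from condkit.tracking import (
    EmptyProfileError,
    InvalidParameterError,
    TrajectorySet,
    _tamsd_direct,
    _tamsd_fft,
)
from conftest import brute_force_msd


def _spot_frame(centers_um, pixel_size=0.1, n=128, sigma_um=0.25, amp=100.0):
    y, x = np.mgrid[0:n, 0:n] * pixel_size
    img = np.zeros((n, n))
    for cx, cy in centers_um:
        img += amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma_um**2))
    return img


class TestDetection:
    def test_single_spot_localized_to_subpixel(self):
        frame = _spot_frame([(5.0, 7.0)])
        locs = ck.detect_particles(frame, 0.1, expected_diameter=1.0, min_intensity=10.0)
        assert len(locs) == 1
        assert locs.loc[0, "x_um"] == pytest.approx(5.0, abs=0.02)
        assert locs.loc[0, "y_um"] == pytest.approx(7.0, abs=0.02)

    def test_uniform_frame_yields_nothing(self):
        locs = ck.detect_particles(np.full((64, 64), 3.0), 0.1, 1.0, min_intensity=10.0)
        assert len(locs) == 0

    def test_well_separated_spots_all_found(self):
        frame = _spot_frame([(3.0, 3.0), (9.0, 9.0)])
        locs = ck.detect_particles(frame, 0.1, 1.0, min_intensity=10.0)
        assert len(locs) == 2

    def test_too_small_diameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            ck.detect_particles(np.zeros((16, 16)), 0.5, expected_diameter=0.5)


class TestLinking:
    def test_single_particle_single_track(self):
        frames = [
            pd.DataFrame({"x_um": [1.0 + 0.01 * f], "y_um": [2.0], "mass": [1.0]})
            for f in range(20)
        ]
        traj, report = ck.link_trajectories(frames, max_disp=0.5)
        assert report["n_tracks"] == 1
        assert len(traj.data) == 20

    def test_identities_preserved_when_swap_exceeds_max_disp(self):
        # two particles 1 um apart stepping 0.1 um: swapping costs ~1 um
        frames = []
        for f in range(10):
            frames.append(
                pd.DataFrame(
                    {"x_um": [0.0 + 0.1 * f, 1.0 + 0.1 * f], "y_um": [0.0, 0.0], "mass": [1, 1]}
                )
            )
        traj, report = ck.link_trajectories(frames, max_disp=0.5)
        assert report["n_tracks"] == 2
        for pid, grp in traj.iter_tracks():
            assert np.all(np.abs(np.diff(grp["x_um"])) < 0.2)

    def test_memory_bridges_a_missed_detection(self):
        frames = []
        for f in range(9):
            if f == 4:
                frames.append(pd.DataFrame(columns=["x_um", "y_um", "mass"]))
            else:
                frames.append(pd.DataFrame({"x_um": [1.0], "y_um": [1.0], "mass": [1.0]}))
        traj, report = ck.link_trajectories(frames, max_disp=0.5, memory=2)
        assert report["n_tracks"] == 1
        frames_seen = traj.data["frame"].to_numpy()
        assert set(frames_seen) == set(range(9)) - {4}

    def test_without_memory_gap_starts_new_track(self):
        frames = [
            pd.DataFrame({"x_um": [1.0], "y_um": [1.0], "mass": [1.0]})
            if f != 2
            else pd.DataFrame(columns=["x_um", "y_um", "mass"])
            for f in range(5)
        ]
        _, report = ck.link_trajectories(frames, max_disp=0.5, memory=0)
        assert report["n_tracks"] == 2


class TestDriftCorrection:
    def test_pure_common_drift_removed_exactly(self):
        traj = ck.gen_trajectories(
            ck.MaterialModel("arrested"), 6, 40, 1.0, drift_per_frame=(0.05, 0.02), seed=0
        )
        prof = ck.compute_msd(ck.correct_drift(traj))
        assert np.all(prof.msd < 1e-24)

    def test_relative_displacements_unchanged(self):
        traj = ck.gen_trajectories(
            ck.MaterialModel("newtonian", viscosity=5.0), 4, 30, 1.0,
            drift_per_frame=(0.1, 0.0), seed=2,
        )
        corr = ck.correct_drift(traj)
        for f in (0, 15, 29):
            a = traj.data[traj.data["frame"] == f][["x_um", "y_um"]].to_numpy()
            b = corr.data[corr.data["frame"] == f][["x_um", "y_um"]].to_numpy()
            assert np.allclose(a - a[0], b - b[0])

    def test_single_particle_warns_and_freezes(self):
        traj = ck.gen_trajectories(ck.MaterialModel("newtonian", viscosity=1.0), 1, 20, 1.0, seed=1)
        with pytest.warns(UserWarning):
            corr = ck.correct_drift(traj)
        assert np.ptp(corr.positions(0), axis=0) == pytest.approx((0, 0), abs=1e-12)

    def test_drift_plus_diffusion_recovers_undrifted_msd(self):
        model = ck.MaterialModel("newtonian", viscosity=1.0)
        clean = ck.gen_trajectories(model, 50, 200, 1.0, seed=9)
        drifted = ck.gen_trajectories(model, 50, 200, 1.0, drift_per_frame=(0.05, 0.05), seed=9)
        p_clean = ck.compute_msd(clean)
        p_fixed = ck.compute_msd(ck.correct_drift(drifted))
        sel = p_clean.lags <= 20
        assert np.allclose(p_fixed.msd[sel], p_clean.msd[sel], rtol=0.15)


class TestMSD:
    def test_ballistic_motion_exact(self):
        v = 0.3
        frames = np.arange(40)
        df = pd.DataFrame(
            {
                "particle_id": 0,
                "frame": frames,
                "t_s": frames * 1.0,
                "x_um": v * frames,
                "y_um": 5.0,
            }
        )
        prof = ck.compute_msd(TrajectorySet(df, dt=1.0))
        assert np.allclose(prof.msd, v**2 * prof.lags**2, rtol=1e-12)

    def test_static_error_plateau_is_four_sigma_squared(self):
        sigma = 0.03
        traj = ck.gen_trajectories(
            ck.MaterialModel("arrested"), 200, 400, 1.0, loc_noise_sd=sigma, seed=21
        )
        prof = ck.compute_msd(traj)
        assert np.mean(prof.msd) == pytest.approx(4 * sigma**2, rel=0.05)

    def test_matches_brute_force_double_loop(self):
        model = ck.MaterialModel("maxwell", viscosity=2.0, confinement_sd=0.05, relaxation_time=1.0)
        traj = ck.gen_trajectories(model, 5, 50, 0.7, loc_noise_sd=0.01, seed=33)
        prof = ck.compute_msd(traj)
        lags, msd, n_obs = brute_force_msd(traj)
        assert np.allclose(prof.lags, lags)
        assert np.array_equal(prof.n_obs, n_obs)
        assert np.allclose(prof.msd, msd, rtol=1e-10)

    def test_fft_and_direct_estimators_agree(self):
        rng = np.random.default_rng(5)
        xy = np.cumsum(rng.normal(0, 0.1, (700, 2)), axis=0)
        assert np.allclose(_tamsd_fft(xy, 170), _tamsd_direct(xy, 170), rtol=1e-9)

    def test_invariance_under_translation_and_rotation(self):
        model = ck.MaterialModel("newtonian", viscosity=3.0)
        traj = ck.gen_trajectories(model, 4, 60, 1.0, seed=8)
        base = ck.compute_msd(traj).msd
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        df = traj.data.copy()
        xy = df[["x_um", "y_um"]].to_numpy() @ rot.T + np.array([12.0, -4.0])
        df[["x_um", "y_um"]] = xy
        moved = ck.compute_msd(TrajectorySet(df, dt=1.0)).msd
        assert np.allclose(base, moved, rtol=1e-9)

    def test_ensemble_convergence_with_particle_number(self):
        model = ck.MaterialModel("newtonian", viscosity=1.0)

        def spread(n, seeds=8):
            vals = [
                ck.compute_msd(ck.gen_trajectories(model, n, 100, 1.0, seed=s)).msd[4]
                for s in range(seeds)
            ]
            return np.std(vals)

        # SD across seeds should shrink roughly like 1/sqrt(N)
        ratio = spread(10) / spread(100)
        assert 1.5 < ratio < 7.0

    def test_short_trajectories_rejected(self):
        df = pd.DataFrame(
            {"particle_id": 0, "frame": range(5), "t_s": range(5), "x_um": 0.0, "y_um": 0.0}
        )
        with pytest.raises(EmptyProfileError):
            ck.compute_msd(TrajectorySet(df, dt=1.0))

    def test_bad_lag_fraction_rejected(self):
        traj = ck.gen_trajectories(ck.MaterialModel("arrested"), 2, 20, 1.0, seed=0)
        with pytest.raises(InvalidParameterError):
            ck.compute_msd(traj, max_lag_fraction=0.9)

    def test_weighted_mode_differs_only_for_unequal_tracks(self):
        traj = ck.gen_trajectories(ck.MaterialModel("newtonian", viscosity=1.0), 6, 80, 1.0, seed=4)
        a = ck.compute_msd(traj, averaging_mode="ensemble_of_time_averages")
        b = ck.compute_msd(traj, averaging_mode="all_displacements")
        # equal-length tracks: the two averaging conventions coincide
        assert np.allclose(a.msd, b.msd, rtol=1e-12)


class TestTrajectorySetValidation:
    def test_non_monotone_frames_rejected(self):
        df = pd.DataFrame(
            {"particle_id": 0, "frame": [0, 2, 1], "t_s": [0, 2, 1], "x_um": 0.0, "y_um": 0.0}
        )
        with pytest.raises(InvalidParameterError):
            TrajectorySet(df, dt=1.0)

    def test_nonfinite_coordinates_rejected(self):
        df = pd.DataFrame(
            {"particle_id": 0, "frame": [0, 1], "t_s": [0, 1], "x_um": [0.0, np.nan], "y_um": 0.0}
        )
        with pytest.raises(InvalidParameterError):
            TrajectorySet(df, dt=1.0)
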