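"""Tests of flat-field correction, drift registration, detection and extraction."""

import numpy as np
import pytest

from smolkin import imageproc, simulate
from smolkin.errors import DegenerateInputError, ParameterError


def make_movie(stack, dt=0.5):
    return imageproc.Movie(stack=np.asarray(stack, float), frame_interval=dt)


class TestIllumination:
    def test_uniform_movie_gives_unit_profile(self):
        movie = make_movie(np.full((5, 40, 40), 7.0))
        profile = imageproc.estimate_illumination(movie, smoothing_sigma=10)
        np.testing.assert_allclose(profile.field, 1.0, atol=1e-9)
        corrected = profile.correct(movie)
        np.testing.assert_allclose(corrected.stack, movie.stack, atol=1e-9)

    def test_known_beam_profile_is_flattened(self):
        # smoothing sigma well below the beam scale but above any spot size
        yy, xx = np.mgrid[:128, :128]
        beam = np.exp(-((yy - 63.5) ** 2 + (xx - 63.5) ** 2) / (2 * 80.0 ** 2))
        stack = np.tile(100.0 * beam, (4, 1, 1))
        movie = make_movie(stack)
        corrected = imageproc.estimate_illumination(movie, 4).correct(movie)
        flat = corrected.stack[0]
        assert flat.std() / flat.mean() < 0.01

    def test_bright_spot_leakage_is_bounded(self):
        rng = np.random.default_rng(4)
        frame = np.full((128, 128), 50.0)
        yy, xx = np.mgrid[:128, :128]
        frame += 500.0 * np.exp(-((yy - 60) ** 2 + (xx - 70) ** 2) / 2.0)
        movie = make_movie(np.tile(frame, (3, 1, 1)))
        corrected = imageproc.estimate_illumination(movie, 50).correct(movie)
        bg = corrected.stack[0][np.hypot(yy - 60, xx - 70) > 10]
        assert np.abs(bg / 50.0 - 1.0).max() < 0.02

    def test_all_zero_movie_rejected(self):
        with pytest.raises(DegenerateInputError):
            imageproc.estimate_illumination(make_movie(np.zeros((3, 20, 20))))


class TestDriftCorrection:
    def _spot_movie(self, drift, n_frames=40, noise=2.0, seed=0):
        scene = simulate.SceneConfig(
            field_size=(64, 64), spot_density=0.05, n_frames=n_frames,
            frame_interval=0.5, photon_scale=300.0, background=10.0,
            read_noise_sigma=noise, drift_per_frame=drift, seed=seed)
        progs = [simulate.KineticProgram(kind="displacement_event", fpt=1e6)
                 for _ in range(8)]
        movies, _ = simulate.simulate_movie(scene, progs,
                                            allow_density_mismatch=True)
        return movies["dna"]

    def test_zero_drift_estimates_near_zero(self):
        shifts, _ = imageproc.correct_drift(self._spot_movie((0.0, 0.0)))
        assert np.abs(shifts).max() < 0.05

    def test_linear_drift_recovered(self):
        n = 40
        shifts, _ = imageproc.correct_drift(self._spot_movie((0.2, 0.0), n))
        per_frame = shifts[-1] / (n - 1)
        assert abs(per_frame[0] - 0.2) < 0.1
        assert abs(per_frame[1]) < 0.1

    def test_registration_restores_spot_positions(self):
        movie = self._spot_movie((0.3, 0.1), n_frames=20)
        _, registered = imageproc.correct_drift(movie)
        # after registration the last frame matches the first
        corr = np.corrcoef(registered.stack[0].ravel(),
                           registered.stack[-1].ravel())[0, 1]
        corr_raw = np.corrcoef(movie.stack[0].ravel(),
                               movie.stack[-1].ravel())[0, 1]
        assert corr > corr_raw and corr > 0.9

    def test_single_frame_movie_rejected(self):
        with pytest.raises(ParameterError):
            imageproc.correct_drift(make_movie(np.zeros((1, 20, 20))))

    def test_featureless_movie_returns_zero_shifts(self):
        shifts, _ = imageproc.correct_drift(make_movie(np.full((5, 20, 20), 3.0)))
        assert np.all(shifts == 0.0)


class TestDetectSpots:
    def test_pure_noise_has_negligible_false_positives(self):
        rng = np.random.default_rng(17)
        total = 0
        for _ in range(100):
            frame = rng.normal(100.0, 3.0, (100, 100))
            total += len(imageproc.detect_spots(frame, k_sigma=5.0, min_area=3))
        # < 1e-3 expected spots per 1e4 px^2 -> at most ~1 over 100 frames
        assert total <= 1

    def test_simulated_spots_found_with_subpixel_centroids(self):
        scene = simulate.SceneConfig(
            field_size=(96, 96), spot_density=0.05, n_frames=4,
            photon_scale=40.0, background=10.0, read_noise_sigma=2.0,
            min_separation=10.0, seed=23)
        progs = [simulate.KineticProgram(kind="displacement_event", fpt=1e6)
                 for _ in range(10)]
        movies, truth = simulate.simulate_movie(scene, progs,
                                                allow_density_mismatch=True)
        mean_frame = movies["dna"].stack.mean(axis=0)
        spots = imageproc.detect_spots(mean_frame, k_sigma=5.0, min_area=3)
        assert len(spots) == 10
        ty = np.array([m.y for m in truth.molecules])
        tx = np.array([m.x for m in truth.molecules])
        for sy, sx in zip(spots.y, spots.x):
            assert np.hypot(ty - sy, tx - sx).min() < 1.0

    def test_adjacent_spots_merge_into_one_component(self):
        frame = np.zeros((40, 40))
        yy, xx = np.mgrid[:40, :40]
        for cx in (19.0, 21.0):   # 2 px apart
            frame += 100.0 * np.exp(-((yy - 20) ** 2 + (xx - cx) ** 2) / 2.0)
        frame += np.random.default_rng(0).normal(10.0, 1.0, frame.shape)
        spots = imageproc.detect_spots(frame, k_sigma=5.0, min_area=3,
                                       max_area=500)
        assert len(spots) == 1

    def test_empty_result_is_valid(self):
        spots = imageproc.detect_spots(np.zeros((50, 50)), k_sigma=5.0)
        assert len(spots) == 0


class TestExtractTrajectories:
    def test_static_spot_extraction_is_constant(self):
        scene = simulate.SceneConfig(
            field_size=(48, 48), spot_density=0.02, n_frames=30,
            frame_interval=0.5, photon_scale=500.0, background=5.0,
            read_noise_sigma=0.0, shot_noise=False, seed=5)
        progs = [simulate.KineticProgram(kind="displacement_event", fpt=1e6)]
        movies, _ = simulate.simulate_movie(scene, progs,
                                            allow_density_mismatch=True)
        spots = imageproc.detect_spots(movies["dna"].stack[0], min_area=3)
        trajs = imageproc.extract_trajectories(movies["dna"], spots)
        assert len(trajs) == 1
        y = trajs[0].primary
        assert np.ptp(y) / y.mean() < 1e-3

    def test_digestion_trace_correlates_with_ground_truth(self):
        scene = simulate.SceneConfig(
            field_size=(48, 48), spot_density=0.02, n_frames=60,
            frame_interval=0.5, photon_scale=500.0, background=5.0,
            read_noise_sigma=0.0, shot_noise=False, seed=6)
        prog = simulate.KineticProgram(kind="digestion", rate=100.0,
                                       start_time=2.0)
        movies, truth = simulate.simulate_movie(scene, [prog],
                                                allow_density_mismatch=True)
        spots = imageproc.detect_spots(movies["dna"].stack[0], min_area=3)
        trajs = imageproc.extract_trajectories(movies["dna"], spots)
        times = trajs[0].times
        expected = truth.molecules[0].piecewise.predict(times)
        r = np.corrcoef(trajs[0].primary, expected)[0, 1]
        assert r > 0.99

    def test_edge_spot_excluded(self):
        stack = np.full((5, 40, 40), 10.0)
        stack[:, 2, 2] = 500.0
        spots = imageproc.SpotSet(y=np.array([2.0]), x=np.array([2.0]),
                                  area=np.array([4.0]), peak=np.array([500.0]))
        trajs = imageproc.extract_trajectories(make_movie(stack), spots)
        assert trajs == []

    def test_second_channel_uses_identical_rois(self):
        stack = np.full((5, 40, 40), 0.0)
        stack[:, 20, 20] = 100.0
        dna = make_movie(stack)
        rpa = imageproc.Movie(stack=2 * stack, frame_interval=0.5, channel="rpa")
        spots = imageproc.SpotSet(y=np.array([20.0]), x=np.array([20.0]),
                                  area=np.array([4.0]), peak=np.array([100.0]))
        trajs = imageproc.extract_trajectories(dna, spots, second_channel=rpa)
        np.testing.assert_allclose(trajs[0].channels["rpa"],
                                   2 * trajs[0].channels["dna"])

    def test_csv_roundtrip_preserves_trajectories(self, tmp_path):
        times = np.arange(10) * 0.2
        trajs = [imageproc.Trajectory(molecule_id=i, times=times,
                                      channels={"dna": np.linspace(1, 0, 10),
                                                "rpa": np.linspace(0, 1, 10)})
                 for i in range(3)]
        path = tmp_path / "traj.csv"
        imageproc.write_trajectories(trajs, path)
        back = imageproc.read_trajectories(path)
        assert len(back) == 3
        for orig, new in zip(trajs, back):
            assert new.molecule_id == orig.molecule_id
            np.testing.assert_allclose(new.times, orig.times)
            np.testing.assert_allclose(new.channels["rpa"], orig.channels["rpa"])
            assert list(new.channels) == ["dna", "rpa"]


class TestFlatFieldInvariance:
    def test_detection_recall_insensitive_to_beam_profile(self):
        base = dict(field_size=(96, 96), spot_density=0.05, n_frames=10,
                    frame_interval=0.5, photon_scale=40.0, background=10.0,
                    read_noise_sigma=2.0, min_separation=8.0, seed=31)
        progs = [simulate.KineticProgram(kind="displacement_event", fpt=1e6)
                 for _ in range(12)]
        recalls = []
        for beam_sigma in (0.0, 50.0):
            scene = simulate.SceneConfig(**base, beam_profile_sigma=beam_sigma)
            movies, truth = simulate.simulate_movie(scene, progs,
                                                    allow_density_mismatch=True)
            movie = movies["dna"]
            movie = imageproc.estimate_illumination(movie, 25).correct(movie)
            mean = movie.stack.mean(axis=0)
            spots = imageproc.detect_spots(mean, k_sigma=5.0, min_area=3)
            ty = np.array([m.y for m in truth.molecules])
            tx = np.array([m.x for m in truth.molecules])
            found = sum(
                1 for y0, x0 in zip(ty, tx)
                if len(spots) and np.hypot(spots.y - y0, spots.x - x0).min() < 2.0)
            recalls.append(found / len(progs))
        assert abs(recalls[0] - recalls[1]) < 0.05 + 1e-9
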