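"""Generator contracts: protocols, kernel model, movies, vibration, leg scenes."""

import numpy as np
import pytest

from fecomap import preprocessing as pre
from fecomap import synthetic_data as syn
from fecomap.exceptions import (
    InvalidParameterError,
    RenderError,
    RoiLayoutError,
)


class TestStimulusProtocol:
    def test_default_protocol_pulse_spacing(self):
        p = syn.gen_stimulus_protocol()
        assert len(p.pulses) == 6
        assert p.pulses[1].onset == pytest.approx(35.0)  # 5 s pulse + 30 s gap
        assert tuple(p.intensities) == (0.02, 0.04, 0.12, 0.28, 0.37, 0.68)

    def test_single_pulse_span(self):
        p = syn.gen_stimulus_protocol((1.0,), pulse_duration=5.0)
        assert p.total_span == pytest.approx(5.0)

    def test_onsets_follow_arithmetic_progression(self):
        p = syn.gen_stimulus_protocol((1, 2, 3), pulse_duration=2.0, inter_pulse=3.0)
        # oracle: onset_k = k * (duration + gap)
        assert np.allclose(p.onsets, [k * 5.0 for k in range(3)])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"intensities": ()},
            {"intensities": (0.0,)},
            {"intensities": (-1.0,)},
            {"pulse_duration": 0.0},
            {"pulse_duration": -2.0},
            {"inter_pulse": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        defaults = {"intensities": (0.1,), "pulse_duration": 5.0, "inter_pulse": 30.0}
        defaults.update(kwargs)
        with pytest.raises(InvalidParameterError):
            syn.gen_stimulus_protocol(**defaults)

    def test_json_round_trip(self, tmp_path):
        p = syn.gen_stimulus_protocol(t0=4.0)
        p.to_json(tmp_path / "protocol.json")
        assert syn.StimulusProtocol.from_json(tmp_path / "protocol.json") == p


class TestGcampModel:
    def test_long_pulse_reaches_amplitude_map_steady_state(self, model):
        # closed-form steady state of the unit-area kernel: filtered
        # intensity -> I, response -> A(I)
        prot = syn.gen_stimulus_protocol(
            (0.28,), pulse_duration=60.0, inter_pulse=1.0, duty_cycle=1.0
        )
        r_end = model.response(np.array([60.0]), prot)[0]
        assert r_end == pytest.approx(model.amplitude(0.28), rel=1e-6)

    def test_duty_cycle_scales_drive(self, model):
        full = syn.gen_stimulus_protocol((0.28,), 60.0, 1.0, duty_cycle=1.0)
        half = syn.gen_stimulus_protocol((0.28,), 60.0, 1.0, duty_cycle=0.5)
        t = np.array([60.0])
        assert model.response(t, half)[0] == pytest.approx(
            model.amplitude(0.14), rel=1e-6
        )
        assert model.response(t, half)[0] < model.response(t, full)[0]

    def test_amplitude_map_nondecreasing_and_bounded(self, model):
        i = np.linspace(0.0, 5.0, 200)
        a = model.amplitude(i)
        assert np.all(np.diff(a) >= 0)
        assert np.all(a <= model.amplitude_max)

    def test_peak_nondecreasing_across_escalating_pulses(self, model, six_pulse_protocol):
        t = np.arange(0, six_pulse_protocol.end + 8, 0.05)
        r = model.response(t, six_pulse_protocol)
        peaks = [
            r[(t >= p.onset) & (t <= p.offset)].max()
            for p in six_pulse_protocol.pulses
        ]
        assert np.all(np.diff(peaks) >= 0)

    def test_filtered_intensity_matches_numerical_convolution(self, model):
        # independent oracle: discrete convolution of the light waveform
        # with the sampled difference-of-exponentials kernel
        prot = syn.gen_stimulus_protocol((0.3,), pulse_duration=5.0, inter_pulse=10.0)
        dt = 0.001
        t = np.arange(0, 20, dt)
        drive = prot.effective_intensity(t)
        td, tr = model.decay_time_constant, model.rise_time_constant
        kern = (np.exp(-t / td) - np.exp(-t / tr)) / (td - tr)
        numeric = np.convolve(drive, kern)[: len(t)] * dt
        analytic = model.filtered_intensity(t, prot)
        assert np.allclose(numeric, analytic, atol=5e-4 * drive.max())

    def test_adaptation_envelope_decays_toward_plateau(self):
        m = syn.GcampModel(adaptation_time_constant=3.0, adaptation_plateau=0.2)
        prot = syn.gen_stimulus_protocol((0.3,), pulse_duration=30.0, inter_pulse=5.0)
        env = m.adaptation_envelope(np.array([0.0, 3.0, 300.0]), prot)
        assert env[0] == pytest.approx(1.0)
        assert env[1] == pytest.approx(0.2 + 0.8 * np.exp(-1.0))
        assert env[2] == pytest.approx(0.2, abs=1e-6)

    def test_equal_time_constants_rejected(self):
        with pytest.raises(InvalidParameterError):
            syn.GcampModel(rise_time_constant=1.0, decay_time_constant=1.0)


def _simple_layout():
    return [
        syn.DiskRoi("A", center=(16.0, 16.0), radius=6.0, post_label="A"),
        syn.DiskRoi("B", center=(46.0, 46.0), radius=6.0, post_label="B"),
    ]


def _planted(gains):
    return syn.PlantedConnectivity(
        np.asarray(gains, dtype=float), ("pre",), ("A", "B")
    )


class TestRoiMovie:
    def test_null_connectivity_gives_constant_movie(self, model):
        scene = syn.SceneParams(n_frames=20, noise_sd=0.0, seed=1)
        prot = syn.gen_stimulus_protocol((0.3,), 2.0, 2.0)
        movie, truth = syn.gen_roi_movie(
            scene, model, _planted([[0.0, 0.0]]), prot, _simple_layout()
        )
        assert np.all(truth["dff_true"] == 0.0)
        for frame in movie.frames:
            assert np.array_equal(frame, movie.frames[0])

    def test_roi_mean_matches_closed_form_response(self, model):
        scene = syn.SceneParams(n_frames=40, noise_sd=0.0, seed=1)
        prot = syn.gen_stimulus_protocol((0.28,), 8.0, 2.0, t0=2.0)
        movie, truth = syn.gen_roi_movie(
            scene, model, _planted([[1.0, 0.5]]), prot, _simple_layout()
        )
        r = model.response(scene.times, prot)
        for roi, gain in (("A", 1.0), ("B", 0.5)):
            got = truth.loc[truth["roi_id"] == roi, "dff_true"].to_numpy()
            assert np.allclose(got, gain * r)
            mask = _simple_layout()[0 if roi == "A" else 1].mask(movie.frame_shape)
            roi_mean = movie.frames[:, mask].mean(axis=1)
            expected = scene.baseline_fluorescence * (1.0 + gain * r)
            assert np.allclose(roi_mean, expected)

    def test_same_seed_is_bit_identical(self, model):
        scene = syn.SceneParams(n_frames=15, noise_sd=25.0, seed=7)
        prot = syn.gen_stimulus_protocol((0.3,), 2.0, 2.0)
        a, _ = syn.gen_roi_movie(scene, model, _planted([[1.0, 0.0]]), prot, _simple_layout())
        b, _ = syn.gen_roi_movie(scene, model, _planted([[1.0, 0.0]]), prot, _simple_layout())
        assert np.array_equal(a.frames, b.frames)

    def test_different_seed_differs(self, model):
        prot = syn.gen_stimulus_protocol((0.3,), 2.0, 2.0)
        a, _ = syn.gen_roi_movie(
            syn.SceneParams(n_frames=15, noise_sd=25.0, seed=7),
            model, _planted([[1.0, 0.0]]), prot, _simple_layout(),
        )
        b, _ = syn.gen_roi_movie(
            syn.SceneParams(n_frames=15, noise_sd=25.0, seed=8),
            model, _planted([[1.0, 0.0]]), prot, _simple_layout(),
        )
        assert not np.array_equal(a.frames, b.frames)

    def test_overlapping_rois_rejected(self, model):
        layout = [
            syn.DiskRoi("A", (20.0, 20.0), 8.0, post_label="A"),
            syn.DiskRoi("B", (24.0, 24.0), 8.0, post_label="B"),
        ]
        prot = syn.gen_stimulus_protocol((0.3,), 2.0, 2.0)
        with pytest.raises(RoiLayoutError):
            syn.gen_roi_movie(
                syn.SceneParams(n_frames=5), model, _planted([[1.0, 1.0]]), prot, layout
            )

    def test_roi_outside_frame_rejected(self, model):
        layout = [syn.DiskRoi("A", (2.0, 2.0), 8.0, post_label="A")]
        planted = syn.PlantedConnectivity(np.array([[1.0]]), ("pre",), ("A",))
        prot = syn.gen_stimulus_protocol((0.3,), 2.0, 2.0)
        with pytest.raises(RoiLayoutError):
            syn.gen_roi_movie(syn.SceneParams(n_frames=5), model, planted, prot, layout)


class TestVibration:
    def test_default_epoch_timing(self):
        v = syn.gen_vibration_epochs([200.0])
        assert len(v.epochs) == 2
        # 4 s epoch + 8 s inter-stimulus interval
        assert v.epochs[1].onset - v.epochs[0].onset == pytest.approx(12.0)

    def test_sample_count_and_phase(self):
        v = syn.gen_vibration_epochs([100.0])
        w = v.epochs[0].waveform()
        assert len(w) == 40_000  # 4 s at 10 kHz
        assert w[0] == 0.0
        # oracle: value at sample k is sin(2*pi*f*k/fs)
        k = 17
        assert w[k] == pytest.approx(np.sin(2 * np.pi * 100.0 * k / 10_000.0))

    @pytest.mark.parametrize("freqs", [(0.0,), (-5.0,), ()])
    def test_degenerate_frequencies_rejected(self, freqs):
        with pytest.raises(InvalidParameterError):
            syn.gen_vibration_epochs(freqs)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(InvalidParameterError):
            syn.gen_vibration_epochs([6000.0], sample_rate=10_000.0)


class TestLegVideo:
    def test_constant_trajectory_frames_identical_up_to_noise(self):
        scene = syn.LegSceneParams(angle_trajectory=np.full(4, 90.0), noise_sd=0.0)
        movie, truth = syn.gen_leg_video(scene)
        assert np.all(truth.angles == 90.0)
        for frame in movie.frames:
            assert np.array_equal(frame, movie.frames[0])

    def test_swing_ground_truth_span(self):
        # 180 deg/s from the ~18 deg flexion floor to full extension
        rate = 200.0
        n = int(round(0.9 * rate)) + 1
        traj = 18.0 + 180.0 * np.arange(n) / rate
        scene = syn.LegSceneParams(angle_trajectory=traj, camera_rate=rate)
        _, truth = syn.gen_leg_video(scene)
        assert truth.angles[-1] - truth.angles[0] == pytest.approx(162.0)
        assert truth.times[-1] == pytest.approx(0.9)

    def test_pin_exiting_frame_names_frame(self):
        scene = syn.LegSceneParams(
            angle_trajectory=[90.0, 90.0, 90.0],
            joint_center=(100.0, 100.0),
            pin_length=120.0,
        )
        with pytest.raises(RenderError, match="frame 0"):
            syn.gen_leg_video(scene)

    def test_trajectory_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            syn.LegSceneParams(angle_trajectory=[190.0])

    def test_same_seed_video_bit_identical(self):
        scene = syn.LegSceneParams(angle_trajectory=[45.0, 60.0], noise_sd=5.0, seed=3)
        a, _ = syn.gen_leg_video(scene)
        b, _ = syn.gen_leg_video(scene)
        assert np.array_equal(a.frames, b.frames)


class TestMovieIo:
    def test_tiff_round_trip(self, tmp_path, model):
        scene = syn.SceneParams(n_frames=8, noise_sd=10.0, seed=2)
        prot = syn.gen_stimulus_protocol((0.3,), 2.0, 2.0)
        movie, _ = syn.gen_roi_movie(scene, model, _planted([[1.0, 0.0]]), prot,
                                     _simple_layout())
        movie.to_tiff(tmp_path / "m.tif")
        back = pre.ImagingMovie.from_tiff(tmp_path / "m.tif")
        assert back.frame_interval == pytest.approx(movie.frame_interval)
        assert back.frames.shape == movie.frames.shape
        # 16-bit quantization only
        assert np.max(np.abs(back.frames - movie.frames)) <= 0.5
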