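"""Seeded synthetic movies, stimuli, and leg videos.

This module generates data with the statistical structure the analysis
assumes, so every downstream stage can be exercised and validated
without any recording:

* optogenetic pulse-train protocols (escalating intensities, 50 Hz
  square-wave modulation within each pulse),
* GCaMP6s-like calcium movies whose ROI signals follow a planted
  pre-subtype × post-class connectivity matrix,
* sinusoidal tibia-vibration epoch descriptors,
* high-speed leg videos of a dark pin rotating about the femur–tibia
  joint on a bright background, with the ground-truth angle trace.

The indicator model is linear–nonlinear: the duty-cycle-scaled light
intensity waveform is convolved with a unit-area difference-of-
exponentials kernel, then passed through a saturating (Michaelis–
Menten) amplitude map from intensity to steady-state ΔF/F. Because the
drive is piecewise constant, the convolution is evaluated exactly by
step-response superposition; the same closed form serves as the oracle
for kinetics tests. An optional multiplicative adaptation envelope
(exponential decay toward a plateau after each pulse onset) emulates
response adaptation during sustained stimulation.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical seeds and parameters give
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    InvalidParameterError,
    RenderError,
    RoiLayoutError,
)
from .preprocessing import ImagingMovie, RoiMask

if TYPE_CHECKING:
    from .leg_tracking import AngleTrace

__all__ = [
    "Pulse",
    "StimulusProtocol",
    "gen_stimulus_protocol",
    "SceneParams",
    "GcampModel",
    "PlantedConnectivity",
    "DiskRoi",
    "gen_roi_movie",
    "VibrationEpoch",
    "VibrationProtocol",
    "gen_vibration_epochs",
    "LegSceneParams",
    "gen_leg_video",
]

# ------------------------------------------------------------------ stimuli


@dataclass(frozen=True)
class Pulse:
    """One optogenetic light pulse with within-pulse square modulation."""

    onset: float  # s
    duration: float  # s
    intensity: float  # mW/mm^2, peak of the square wave
    modulation_hz: float = 50.0
    duty_cycle: float = 0.5

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    @property
    def effective_intensity(self) -> float:
        """Time-averaged intensity seen at imaging-frame resolution.

        Imaging frames are orders of magnitude longer than one 50 Hz
        modulation cycle, so each frame integrates the square wave; the
        pulse is therefore represented by its duty-cycle-scaled
        intensity.
        """
        return self.intensity * self.duty_cycle


@dataclass(frozen=True)
class StimulusProtocol:
    """A train of pulses defining stimulation and analysis windows."""

    pulses: tuple[Pulse, ...]

    @property
    def onsets(self) -> np.ndarray:
        return np.array([p.onset for p in self.pulses])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.pulses])

    @property
    def total_span(self) -> float:
        """Time from the first onset to the last offset, seconds."""
        return self.pulses[-1].offset - self.pulses[0].onset

    @property
    def end(self) -> float:
        return self.pulses[-1].offset

    def effective_intensity(self, times: np.ndarray) -> np.ndarray:
        """Duty-cycle-scaled light intensity at each time point."""
        t = np.asarray(times, dtype=float)
        out = np.zeros_like(t)
        for p in self.pulses:
            out[(t >= p.onset) & (t < p.offset)] = p.effective_intensity
        return out

    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema_version": 1,
            "pulses": [
                {
                    "onset": p.onset,
                    "duration": p.duration,
                    "intensity": p.intensity,
                    "modulation_hz": p.modulation_hz,
                    "duty_cycle": p.duty_cycle,
                }
                for p in self.pulses
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusProtocol":
        doc = json.loads(Path(path).read_text())
        return cls(pulses=tuple(Pulse(**p) for p in doc["pulses"]))


def gen_stimulus_protocol(
    intensities: Sequence[float] = (0.02, 0.04, 0.12, 0.28, 0.37, 0.68),
    pulse_duration: float = 5.0,
    inter_pulse: float = 30.0,
    modulation_hz: float = 50.0,
    duty_cycle: float = 0.5,
    t0: float = 0.0,
) -> StimulusProtocol:
    """Pulse train of escalating intensities.

    Pulse ``k`` (0-based) starts at ``t0 + k * (pulse_duration +
    inter_pulse)``. Defaults reproduce the standard mapping protocol:
    six 5-s pulses at (0.02, 0.04, 0.12, 0.28, 0.37, 0.68) mW/mm² with a
    30-s inter-pulse interval and 50 Hz, 50%-duty square modulation
    within each pulse.
    """
    intensities = list(intensities)
    if len(intensities) == 0:
        raise InvalidParameterError("intensities must be nonempty")
    if any(not i > 0 for i in intensities):
        raise InvalidParameterError("intensities must be strictly positive")
    if not pulse_duration > 0 or not inter_pulse >= 0:
        raise InvalidParameterError("pulse_duration must be > 0 and inter_pulse >= 0")
    if inter_pulse == 0 and len(intensities) > 1:
        raise InvalidParameterError("inter_pulse must be > 0 for multi-pulse protocols")
    if not modulation_hz > 0 or not 0 < duty_cycle <= 1:
        raise InvalidParameterError("modulation_hz must be > 0 and duty_cycle in (0, 1]")
    pulses = tuple(
        Pulse(
            onset=t0 + k * (pulse_duration + inter_pulse),
            duration=pulse_duration,
            intensity=float(i),
            modulation_hz=modulation_hz,
            duty_cycle=duty_cycle,
        )
        for k, i in enumerate(intensities)
    )
    return StimulusProtocol(pulses=pulses)


# ------------------------------------------------------------ imaging scenes


@dataclass(frozen=True)
class SceneParams:
    """Geometry, timing, and noise of a synthetic calcium movie."""

    image_height: int = 64
    image_width: int = 64
    frame_rate: float = 2.5  # frames/s, standard mapping acquisition
    n_frames: int = 100
    baseline_fluorescence: float = 1000.0  # counts inside labeled regions
    noise_sd: float = 0.0  # counts, per pixel per frame
    background_level: float = 50.0  # counts outside labeled regions
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise InvalidParameterError("frame_rate must be > 0")
        if self.n_frames < 1:
            raise InvalidParameterError("n_frames must be >= 1")
        if not self.baseline_fluorescence > 0:
            raise InvalidParameterError("baseline_fluorescence must be > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.background_level < 0:
            raise InvalidParameterError("background_level must be >= 0")

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class GcampModel:
    """Linear–nonlinear GCaMP6s-like response model.

    The duty-cycle-scaled light waveform is convolved with the unit-area
    kernel ``(exp(-t/τ_decay) - exp(-t/τ_rise)) / (τ_decay - τ_rise)``
    and the result is mapped through the saturating amplitude map
    ``A(i) = amplitude_max * i / (half_saturation + i)``. The kinetic
    constants are free parameters of the generator (defaults give
    GCaMP6s-like seconds-scale rise and decay); the saturation constant
    is set so responses visibly plateau near 0.3 mW/mm².
    """

    rise_time_constant: float = 0.2  # s
    decay_time_constant: float = 1.5  # s
    amplitude_max: float = 2.0  # ΔF/F at saturation
    half_saturation: float = 0.02  # mW/mm^2 (duty-scaled intensity)
    adaptation_time_constant: float | None = None  # s; None disables
    adaptation_plateau: float = 0.0  # fraction of peak retained at t → ∞

    def __post_init__(self) -> None:
        if not self.rise_time_constant > 0 or not self.decay_time_constant > 0:
            raise InvalidParameterError("time constants must be > 0")
        if self.rise_time_constant == self.decay_time_constant:
            raise InvalidParameterError(
                "rise and decay time constants must differ (difference-of-exponentials kernel)"
            )
        if not self.amplitude_max > 0 or not self.half_saturation > 0:
            raise InvalidParameterError("amplitude_max and half_saturation must be > 0")
        if self.adaptation_time_constant is not None and not self.adaptation_time_constant > 0:
            raise InvalidParameterError("adaptation_time_constant must be > 0 or None")
        if not 0 <= self.adaptation_plateau <= 1:
            raise InvalidParameterError("adaptation_plateau must be in [0, 1]")

    def amplitude(self, intensity: np.ndarray | float) -> np.ndarray | float:
        """Saturating map from (duty-scaled) intensity to steady-state ΔF/F."""
        i = np.asarray(intensity, dtype=float)
        out = self.amplitude_max * i / (self.half_saturation + i)
        return out if out.ndim else float(out)

    def _step_response(self, dt: np.ndarray) -> np.ndarray:
        """Response at lag ``dt`` to a unit intensity step at 0 (0 for dt<0)."""
        td, tr = self.decay_time_constant, self.rise_time_constant
        dt = np.asarray(dt, dtype=float)
        pos = np.clip(dt, 0.0, None)
        resp = 1.0 - (td * np.exp(-pos / td) - tr * np.exp(-pos / tr)) / (td - tr)
        return np.where(dt >= 0, resp, 0.0)

    def filtered_intensity(
        self, times: np.ndarray, protocol: StimulusProtocol
    ) -> np.ndarray:
        """Light waveform convolved with the kernel, in intensity units.

        Evaluated exactly by superposing step responses at each pulse's
        onset and offset.
        """
        t = np.asarray(times, dtype=float)
        out = np.zeros_like(t)
        for p in protocol.pulses:
            out += p.effective_intensity * (
                self._step_response(t - p.onset) - self._step_response(t - p.offset)
            )
        return np.clip(out, 0.0, None)

    def adaptation_envelope(
        self, times: np.ndarray, protocol: StimulusProtocol
    ) -> np.ndarray:
        """Multiplicative adaptation factor; 1 everywhere when disabled."""
        t = np.asarray(times, dtype=float)
        if self.adaptation_time_constant is None:
            return np.ones_like(t)
        onsets = protocol.onsets
        env = np.ones_like(t)
        # time since the most recent pulse onset at or before t
        idx = np.searchsorted(onsets, t, side="right") - 1
        has = idx >= 0
        dt = t[has] - onsets[idx[has]]
        p = self.adaptation_plateau
        env[has] = p + (1.0 - p) * np.exp(-dt / self.adaptation_time_constant)
        return env

    def response(self, times: np.ndarray, protocol: StimulusProtocol) -> np.ndarray:
        """Noise-free unit-gain ΔF/F response to the protocol."""
        r = np.asarray(self.amplitude(self.filtered_intensity(times, protocol)))
        return r * self.adaptation_envelope(times, protocol)


@dataclass(frozen=True)
class PlantedConnectivity:
    """Ground-truth gains between pre sources and post classes."""

    matrix: np.ndarray  # (n_pre, n_post), gains >= 0
    pre_labels: tuple[str, ...]
    post_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        if self.matrix.shape != (len(self.pre_labels), len(self.post_labels)):
            raise InvalidParameterError("matrix shape must match label counts")
        if not np.all(np.isfinite(self.matrix)) or np.any(self.matrix < 0):
            raise InvalidParameterError("gains must be finite and >= 0")
        if len(set(self.pre_labels)) != len(self.pre_labels) or len(
            set(self.post_labels)
        ) != len(self.post_labels):
            raise InvalidParameterError("labels must be unique")

    def gain(self, pre: str, post: str) -> float:
        return float(
            self.matrix[self.pre_labels.index(pre), self.post_labels.index(post)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.pre_labels), columns=list(self.post_labels)
        )


@dataclass(frozen=True)
class DiskRoi:
    """A disk-shaped labeled region in the imaging frame."""

    label: str
    center: tuple[float, float]  # (row, col)
    radius: float
    post_label: str = ""

    def mask(self, shape: tuple[int, int], shrink: float = 0.0) -> np.ndarray:
        """Boolean mask of pixels within ``radius - shrink`` of the center.

        ``shrink`` is used by analysis code to erode the extraction mask
        by the spatial-smoothing radius so filtered edge pixels (mixed
        with background) are excluded from the ROI mean.
        """
        r = self.radius - shrink
        if r <= 0:
            raise RoiLayoutError(f"ROI {self.label!r}: shrink {shrink} leaves no pixels")
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= r**2

    def roi_mask(self, shape: tuple[int, int], shrink: float = 0.0) -> RoiMask:
        return RoiMask.from_bool(self.label, self.mask(shape, shrink=shrink))


def gen_roi_movie(
    scene: SceneParams,
    model: GcampModel,
    planted: PlantedConnectivity,
    protocol: StimulusProtocol,
    roi_layout: Sequence[DiskRoi],
    pre_label: str | None = None,
) -> tuple[ImagingMovie, pd.DataFrame]:
    """Render a calcium movie with planted connectivity, plus ground truth.

    Each ROI disk carries the signal for one post class: its mean pixel
    time course is ``baseline * (1 + g * r(t)) + noise`` where ``r(t)``
    is the model's unit-gain response to the protocol and ``g`` is the
    planted gain for (``pre_label``, ROI's post class). Pixels outside
    every ROI sit at the dim ``background_level``. Gaussian pixel noise
    (sd ``noise_sd``, floored at 0) is independent per pixel per frame.

    Returns the movie and a long-format ground-truth table
    ``(time_s, roi_id, dff_true)`` of the noiseless ΔF/F per ROI.
    """
    if pre_label is None:
        if len(planted.pre_labels) != 1:
            raise InvalidParameterError(
                "pre_label is required when the planted matrix has several pre sources"
            )
        pre_label = planted.pre_labels[0]
    if pre_label not in planted.pre_labels:
        raise InvalidParameterError(f"unknown pre label {pre_label!r}")

    shape = (scene.image_height, scene.image_width)
    masks = []
    for roi in roi_layout:
        m = roi.mask(shape)
        if not m.any():
            raise RoiLayoutError(f"ROI {roi.label!r} contains no pixels")
        # disk must be fully inside the frame
        if (
            roi.center[0] - roi.radius < -0.5
            or roi.center[1] - roi.radius < -0.5
            or roi.center[0] + roi.radius > shape[0] - 0.5
            or roi.center[1] + roi.radius > shape[1] - 0.5
        ):
            raise RoiLayoutError(f"ROI {roi.label!r} extends outside the frame")
        masks.append(m)
    stacked = np.zeros(shape, dtype=int)
    for m in masks:
        stacked += m
    if np.any(stacked > 1):
        raise RoiLayoutError("ROIs overlap")

    times = scene.times
    r = model.response(times, protocol)

    frames = np.full((scene.n_frames,) + shape, scene.background_level, dtype=float)
    truth_parts = []
    for roi, m in zip(roi_layout, masks):
        post = roi.post_label or roi.label
        g = planted.gain(pre_label, post)
        dff = g * r
        frames[:, m] = scene.baseline_fluorescence * (1.0 + dff)[:, None]
        truth_parts.append(
            pd.DataFrame({"time_s": times, "roi_id": roi.label, "dff_true": dff})
        )

    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        frames = frames + rng.normal(0.0, scene.noise_sd, frames.shape)
        np.clip(frames, 0.0, None, out=frames)

    movie = ImagingMovie(
        frames=frames,
        frame_interval=scene.frame_interval,
        start_time=0.0,
        metadata={"pre_label": pre_label, "seed": scene.seed},
    )
    truth = pd.concat(truth_parts, ignore_index=True)
    return movie, truth


# --------------------------------------------------------------- vibration


@dataclass(frozen=True)
class VibrationEpoch:
    """One sinusoidal vibration epoch of the tibia."""

    frequency: float  # Hz
    onset: float  # s
    duration: float  # s
    sample_rate: float  # Hz
    amplitude: float = 1.0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    def waveform(self) -> np.ndarray:
        t = np.arange(self.n_samples) / self.sample_rate
        return self.amplitude * np.sin(2.0 * np.pi * self.frequency * t)


@dataclass(frozen=True)
class VibrationProtocol:
    """Per-frequency repeated vibration epochs."""

    epochs: tuple[VibrationEpoch, ...]

    def for_frequency(self, frequency: float) -> tuple[VibrationEpoch, ...]:
        return tuple(e for e in self.epochs if e.frequency == frequency)


def gen_vibration_epochs(
    frequencies: Sequence[float],
    epoch_duration: float = 4.0,
    n_reps: int = 2,
    isi: float = 8.0,
    sample_rate: float = 10_000.0,
    amplitude: float = 1.0,
) -> VibrationProtocol:
    """Sine-wave vibration epochs: per frequency, ``n_reps`` epochs of
    ``epoch_duration`` seconds separated by ``isi`` seconds.

    Defaults reproduce the standard stimulus: 4 s of vibration, twice,
    8 s inter-stimulus interval, synthesized at 10 kHz.
    """
    frequencies = list(frequencies)
    if len(frequencies) == 0:
        raise InvalidParameterError("frequencies must be nonempty")
    if any(not f > 0 for f in frequencies):
        raise InvalidParameterError("frequencies must be strictly positive")
    if not epoch_duration > 0 or not isi >= 0 or n_reps < 1:
        raise InvalidParameterError("epoch_duration > 0, isi >= 0, n_reps >= 1 required")
    if not sample_rate > 2.0 * max(frequencies):
        raise InvalidParameterError(
            f"sample_rate {sample_rate} Hz violates Nyquist for {max(frequencies)} Hz"
        )
    epochs = []
    t = 0.0
    for f in frequencies:
        for _ in range(n_reps):
            epochs.append(
                VibrationEpoch(
                    frequency=float(f),
                    onset=t,
                    duration=epoch_duration,
                    sample_rate=sample_rate,
                    amplitude=amplitude,
                )
            )
            t += epoch_duration + isi
    return VibrationProtocol(epochs=tuple(epochs))


# --------------------------------------------------------------- leg videos


@dataclass(frozen=True)
class LegSceneParams:
    """A high-speed video scene: a dark pin rotating about the joint.

    The pin (the painted tibia) is a ``pin_length`` × ``pin_width``
    rectangle anchored at ``joint_center`` and rotated to the femur–
    tibia angle of ``angle_trajectory`` frame by frame. Angles follow
    the biological convention: 180° is full extension, and passive
    stimulation flexes the joint only down to ~18°.

    Orientation convention: angles are measured from the +column axis,
    increasing toward decreasing row (right-handed with y = −row), so a
    recovered ellipse orientation can be compared to the rendered angle
    directly.
    """

    angle_trajectory: np.ndarray  # degrees, one per frame
    image_height: int = 200
    image_width: int = 200
    pin_length: float = 80.0
    pin_width: float = 6.0
    joint_center: tuple[float, float] = (100.0, 100.0)  # (row, col)
    femur_axis_angle: float = 0.0  # degrees, direction joint → femur
    hinge_side: str = "ccw"  # rotation sense from femur axis to tibia
    camera_rate: float = 200.0  # frames/s
    background: float = 200.0
    pin_intensity: float = 40.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        traj = np.asarray(self.angle_trajectory, dtype=float)
        object.__setattr__(self, "angle_trajectory", traj)
        if traj.ndim != 1 or len(traj) < 1:
            raise InvalidParameterError("angle_trajectory must be a nonempty 1-D series")
        if np.any(traj < 0) or np.any(traj > 180):
            raise InvalidParameterError("joint angles must lie in [0, 180] degrees")
        if self.hinge_side not in ("ccw", "cw"):
            raise InvalidParameterError("hinge_side must be 'ccw' or 'cw'")
        if not self.camera_rate > 0:
            raise InvalidParameterError("camera_rate must be > 0")
        if not self.pin_length > 0 or not self.pin_width > 0:
            raise InvalidParameterError("pin dimensions must be > 0")
        if not self.background > self.pin_intensity >= 0:
            raise InvalidParameterError("pin must be darker than the background")

    @property
    def n_frames(self) -> int:
        return len(self.angle_trajectory)

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.camera_rate

    def tibia_direction(self, joint_angle_deg: float) -> float:
        """Image-plane direction (degrees) of the tibia for a joint angle.

        At 0° the tibia folds back along the femur axis; at 180° it
        extends opposite the femur. ``hinge_side`` sets the rotation
        sense.
        """
        s = 1.0 if self.hinge_side == "ccw" else -1.0
        return self.femur_axis_angle + s * joint_angle_deg


def _render_pin_frame(scene: LegSceneParams, angle_deg: float, supersample: int = 4
                      ) -> np.ndarray:
    """Anti-aliased rendering of the pin at one joint angle.

    Pixel values are ``background - (background - pin_intensity) *
    coverage`` where coverage is the fraction of each pixel inside the
    rotated rectangle, estimated on a ``supersample``² subgrid.
    """
    h, w = scene.image_height, scene.image_width
    direction = np.deg2rad(scene.tibia_direction(angle_deg))
    dx, dy = np.cos(direction), np.sin(direction)
    r0, c0 = scene.joint_center

    # subpixel sample offsets centered on the pixel center
    n = supersample
    off = (np.arange(n) + 0.5) / n - 0.5
    rows = np.arange(h)[:, None] + off[None, :]  # (h, n)
    cols = np.arange(w)[:, None] + off[None, :]  # (w, n)
    # math coords: x = col, y = -row
    x = (cols - c0).reshape(1, 1, w, n)
    y = (r0 - rows).reshape(h, n, 1, 1)
    s_long = x * dx + y * dy
    s_perp = -x * dy + y * dx
    inside = (
        (s_long >= 0.0)
        & (s_long <= scene.pin_length)
        & (np.abs(s_perp) <= scene.pin_width / 2.0)
    )
    coverage = inside.mean(axis=(1, 3))
    return scene.background - (scene.background - scene.pin_intensity) * coverage


def gen_leg_video(
    scene: LegSceneParams, supersample: int = 4
) -> tuple[ImagingMovie, "AngleTrace"]:
    """Render the pin video and return it with the ground-truth angles.

    Raises :class:`RenderError` naming the first frame in which the pin
    would leave the image.
    """
    from .leg_tracking import AngleTrace  # local import to avoid a cycle

    h, w = scene.image_height, scene.image_width
    r0, c0 = scene.joint_center
    margin = scene.pin_width / 2.0 + 1.0
    frames = np.empty((scene.n_frames, h, w), dtype=float)
    for k, theta in enumerate(scene.angle_trajectory):
        direction = np.deg2rad(scene.tibia_direction(float(theta)))
        tip_row = r0 - scene.pin_length * np.sin(direction)
        tip_col = c0 + scene.pin_length * np.cos(direction)
        for rr, cc in ((r0, c0), (tip_row, tip_col)):
            if not (margin <= rr <= h - 1 - margin and margin <= cc <= w - 1 - margin):
                raise RenderError(
                    f"pin exits the {h}x{w} frame at frame {k} (angle {theta:.1f} deg)"
                )
        frames[k] = _render_pin_frame(scene, float(theta), supersample=supersample)

    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        frames = frames + rng.normal(0.0, scene.noise_sd, frames.shape)
        np.clip(frames, 0.0, None, out=frames)

    movie = ImagingMovie(
        frames=frames,
        frame_interval=scene.frame_interval,
        start_time=0.0,
        metadata={"seed": scene.seed, "femur_axis_angle": scene.femur_axis_angle,
                  "hinge_side": scene.hinge_side},
    )
    times = np.arange(scene.n_frames) * scene.frame_interval
    truth = AngleTrace(
        times=times,
        angles=scene.angle_trajectory.copy(),
        source_rate=scene.camera_rate,
    )
    return movie, truth
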