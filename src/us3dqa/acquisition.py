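"""Simulated motorized and freehand sweep acquisitions.

Motorized acquisition (MA): the probe rides a rail, stepping in the
elevation direction with zero lateral/axial/angular deviation, either
stepwise (one frame per step after a 0.5-s dwell, optionally with 5-frame
compound averaging) or continuously (step size = velocity / FPS).

Freehand acquisition (FA): a hand-held sweep at constant mean elevation
velocity plus physiological tremor (band-limited oscillation ~8–12 Hz and
a slow drift) on all axes, observed by a simulated electromagnetic
tracker (i.i.d. Gaussian pose noise at the sensor's specified RMS,
resampled at 40 Hz, with a constant clock offset between the tracking and
image streams).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .imaging import BeamProfile, ImageGeometry, render_frame
from .phantom import PhantomSpec

__all__ = [
    "ProbePose",
    "FrameStream",
    "TrackingStream",
    "AcquisitionConfig",
    "TremorModel",
    "TrackingNoise",
    "motorized_trajectory",
    "freehand_trajectory",
    "simulate_tracking",
    "acquire",
    "calibration_sweep",
]

ALLOWED_STEP_SIZES_MM = (0.1, 0.2, 0.5, 1.0)


@dataclass(frozen=True)
class ProbePose:
    """Rigid probe pose: ``position`` = (lateral x, axial y, elevation z) mm,
    ``orientation`` = small-angle rotations (rx, ry, rz) deg, ``timestamp`` s."""

    position: tuple[float, float, float]
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    timestamp: float = 0.0


@dataclass
class FrameStream:
    """Ordered 8-bit frames with timestamps on the image clock."""

    frames: np.ndarray  # (N, rows, cols) uint8
    timestamps: np.ndarray  # (N,) s
    geometry: ImageGeometry
    poses: list[ProbePose] | None = None  # ground-truth poses, if known
    seed: int | None = None

    def __post_init__(self):
        if len(self.frames) < 2:
            raise ValueError("a frame stream needs at least 2 frames")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("frame timestamps must be strictly increasing")


@dataclass
class TrackingStream:
    """Probe pose samples on the (independent) tracker clock."""

    timestamps: np.ndarray  # (M,) s
    positions: np.ndarray  # (M, 3) mm
    orientations: np.ndarray  # (M, 3) deg

    def __post_init__(self):
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("tracking timestamps must be strictly increasing")

    def shifted(self, dt_s: float) -> "TrackingStream":
        """Return a copy with ``dt_s`` added to every timestamp."""
        return TrackingStream(
            self.timestamps + dt_s, self.positions.copy(), self.orientations.copy()
        )


@dataclass
class TremorModel:
    """Hand-tremor parameters.

    ``amplitude_mm`` is the displacement standard deviation per axis
    (lateral, axial, elevation), realized as a sum of three sinusoids
    with random frequencies in ``band_hz`` and random phases; ``drift``
    is integrated white noise scaled by ``drift_rate_mm_s``. Zero
    amplitudes reproduce an ideal constant-velocity sweep.
    """

    amplitude_mm: tuple[float, float, float] = (0.3, 0.3, 0.2)
    band_hz: tuple[float, float] = (8.0, 12.0)
    drift_rate_mm_s: float = 0.05
    angular_jitter_deg: float = 0.5

    def __post_init__(self):
        if any(a < 0 for a in self.amplitude_mm) or self.angular_jitter_deg < 0:
            raise ValueError("tremor amplitudes must be >= 0")


@dataclass
class TrackingNoise:
    """EM-sensor noise: 3D position error RMS, orientation RMS, sample
    rate, and the constant offset of the tracker clock vs the image clock."""

    position_rms_mm: float = 0.48
    orientation_rms_deg: float = 0.30
    measurement_rate_hz: float = 40.0
    temporal_offset_ms: float = -30.0


@dataclass
class AcquisitionConfig:
    """One acquisition of the experiment grid."""

    method: str = "motorized"  # 'motorized' | 'freehand'
    movement: str = "stepwise"  # 'stepwise' | 'continuous' | 'freehand-sweep'
    step_size_mm: float | None = 0.5
    velocity_mm_s: float | None = None
    compounding: bool = False
    n_compound: int = 5
    dwell_s: float = 0.5
    sweep_length_mm: float = 60.0
    sweep_start_mm: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.method not in ("motorized", "freehand"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "freehand":
            self.movement = "freehand-sweep"
            if self.compounding:
                raise ValueError("compound imaging is only available for "
                                 "motorized stepwise acquisitions")
            if self.velocity_mm_s is None:
                self.velocity_mm_s = 3.0
        else:
            if self.movement not in ("stepwise", "continuous"):
                raise ValueError(f"unknown motorized movement {self.movement!r}")
            if self.compounding and self.movement != "stepwise":
                raise ValueError("compound imaging is only available for "
                                 "motorized stepwise acquisitions")


def _validate_step(step: float) -> float:
    if not any(np.isclose(step, s, atol=1e-9) for s in ALLOWED_STEP_SIZES_MM):
        raise ValueError(
            f"step size {step} mm not in allowed set {ALLOWED_STEP_SIZES_MM}"
        )
    return float(step)


def motorized_trajectory(
    config: AcquisitionConfig, geom: ImageGeometry
) -> list[ProbePose]:
    """Exact rail trajectory: elevation steps with zero deviation.

    Stepwise poses are spaced by the dwell time; continuous poses by one
    frame interval with the step size derived as velocity / FPS.
    """
    if config.method != "motorized":
        raise ValueError("motorized_trajectory requires a motorized config")
    if config.movement == "stepwise":
        step = _validate_step(config.step_size_mm)
        dt = config.dwell_s
    else:
        if config.velocity_mm_s is not None:
            step = config.velocity_mm_s / geom.fps
        else:
            step = _validate_step(config.step_size_mm)
        dt = 1.0 / geom.fps
    n = int(round(config.sweep_length_mm / step)) + 1
    z0 = config.sweep_start_mm
    return [
        ProbePose((0.0, 0.0, z0 + k * step), (0.0, 0.0, 0.0), k * dt)
        for k in range(n)
    ]


def _band_oscillation(
    t: np.ndarray, std: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Sum of 3 random-frequency sinusoids with overall std ``std``."""
    if std == 0:
        return np.zeros_like(t)
    out = np.zeros_like(t)
    peak = std * np.sqrt(2.0 / 3.0)
    for _ in range(3):
        f = rng.uniform(*band)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        out += peak * np.sin(2.0 * np.pi * f * t + phi)
    return out


def freehand_trajectory(
    config: AcquisitionConfig,
    tremor: TremorModel,
    geom: ImageGeometry,
    rng: np.random.Generator | int | None = None,
) -> list[ProbePose]:
    """Hand-held sweep: constant mean elevation velocity plus tremor.

    Deterministic given the generator state; zero tremor amplitudes give
    exactly equal elevation increments (an ideal sweep).
    """
    if config.method != "freehand":
        raise ValueError("freehand_trajectory requires a freehand config")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    v = config.velocity_mm_s
    duration = config.sweep_length_mm / v
    t = np.arange(0.0, duration + 0.5 / geom.fps, 1.0 / geom.fps)
    z_mean = config.sweep_start_mm + v * t

    dt = 1.0 / geom.fps
    disp = np.zeros((t.size, 3))
    for ax in range(3):
        disp[:, ax] = _band_oscillation(t, tremor.amplitude_mm[ax], tremor.band_hz, rng)
        if tremor.drift_rate_mm_s > 0:
            disp[:, ax] += tremor.drift_rate_mm_s * np.cumsum(
                rng.normal(0.0, np.sqrt(dt), t.size)
            )
    ang = np.zeros((t.size, 3))
    for ax in range(3):
        ang[:, ax] = _band_oscillation(t, tremor.angular_jitter_deg, tremor.band_hz, rng)

    return [
        ProbePose(
            (disp[k, 0], disp[k, 1], z_mean[k] + disp[k, 2]),
            tuple(ang[k]),
            float(t[k]),
        )
        for k in range(t.size)
    ]


def simulate_tracking(
    trajectory: Sequence[ProbePose],
    noise: TrackingNoise,
    rng: np.random.Generator | int | None = None,
) -> TrackingStream:
    """Observe a trajectory through the EM tracker.

    The true path is resampled at the measurement rate, i.i.d. Gaussian
    noise is added so the 3D position error RMS (sqrt of the mean squared
    error norm) matches ``position_rms_mm`` (likewise for orientation),
    and the stream's timestamps are shifted by the tracker-vs-image clock
    offset.
    """
    if not trajectory:
        raise ValueError("trajectory must be nonempty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t_true = np.array([p.timestamp for p in trajectory])
    pos = np.array([p.position for p in trajectory])
    ori = np.array([p.orientation for p in trajectory])
    ts = np.arange(t_true[0], t_true[-1] + 1e-12, 1.0 / noise.measurement_rate_hz)
    if ts[-1] < t_true[-1]:  # keep sampling through the end of the sweep
        ts = np.append(ts, ts[-1] + 1.0 / noise.measurement_rate_hz)
    sampled_p = np.column_stack([np.interp(ts, t_true, pos[:, a]) for a in range(3)])
    sampled_o = np.column_stack([np.interp(ts, t_true, ori[:, a]) for a in range(3)])
    # per-component sigma so that E|noise|^2 = rms^2
    sp = noise.position_rms_mm / np.sqrt(3.0)
    so = noise.orientation_rms_deg / np.sqrt(3.0)
    if sp > 0:
        sampled_p = sampled_p + rng.normal(0.0, sp, sampled_p.shape)
    if so > 0:
        sampled_o = sampled_o + rng.normal(0.0, so, sampled_o.shape)
    return TrackingStream(
        ts + noise.temporal_offset_ms / 1000.0, sampled_p, sampled_o
    )


def acquire(
    phantom: PhantomSpec,
    config: AcquisitionConfig,
    beam: BeamProfile | None = None,
    geom: ImageGeometry | None = None,
    tremor: TremorModel | None = None,
    noise: TrackingNoise | None = None,
    seed: int | None = None,
) -> tuple[FrameStream, TrackingStream | None]:
    """Run one simulated acquisition.

    Returns the frame stream and, for freehand acquisitions, the tracking
    stream (motorized sweeps need none — the rail controls the step
    size). With compounding on, each stored frame is the pixel-wise mean
    of ``n_compound`` renders at the identical pose. Bit-identical output
    for identical (config, seed).
    """
    beam = beam or BeamProfile()
    geom = geom or ImageGeometry()
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    ss = np.random.SeedSequence(seed)
    c_traj, c_track, c_frames = ss.spawn(3)
    traj_rng = np.random.default_rng(c_traj)
    track_rng = np.random.default_rng(c_track)

    if config.method == "motorized":
        trajectory = motorized_trajectory(config, geom)
        tracking = None
    else:
        tremor = tremor or TremorModel()
        noise = noise or TrackingNoise()
        trajectory = freehand_trajectory(config, tremor, geom, traj_rng)
        tracking = simulate_tracking(trajectory, noise, track_rng)

    n_renders = config.n_compound if config.compounding else 1
    frame_rngs = [np.random.default_rng(c) for c in c_frames.spawn(len(trajectory) * n_renders)]
    frames = np.empty((len(trajectory), geom.rows, geom.cols), dtype=np.uint8)
    for k, pose in enumerate(trajectory):
        if n_renders == 1:
            frames[k] = render_frame(phantom, pose, beam, geom, frame_rngs[k])
        else:
            acc = np.zeros((geom.rows, geom.cols), dtype=np.float64)
            for m in range(n_renders):
                acc += render_frame(
                    phantom, pose, beam, geom, frame_rngs[k * n_renders + m]
                )
            frames[k] = np.clip(np.rint(acc / n_renders), 0, 255).astype(np.uint8)

    stream = FrameStream(
        frames,
        np.array([p.timestamp for p in trajectory]),
        geom,
        poses=list(trajectory),
        seed=seed,
    )
    return stream, tracking


def calibration_sweep(
    phantom: PhantomSpec,
    beam: BeamProfile | None = None,
    geom: ImageGeometry | None = None,
    noise: TrackingNoise | None = None,
    duration_s: float = 6.0,
    bob_amplitude_mm: float = 4.0,
    bob_freq_hz: float = 0.8,
    elevation_mm: float = 10.0,
    seed: int | None = 0,
) -> tuple[FrameStream, TrackingStream]:
    """Dedicated temporal-calibration acquisition.

    Before a freehand sweep, the operator bobs the probe slowly up and
    down over the phantom surface; the axial motion visible in the images
    is later cross-correlated with the tracked axial position to estimate
    the tracker-vs-image clock offset. The bob frequency is far below the
    frame rate so the image-derived motion signal is not aliased.
    """
    beam = beam or BeamProfile()
    geom = geom or ImageGeometry()
    noise = noise or TrackingNoise()
    ss = np.random.SeedSequence(seed)
    c_track, c_frames = ss.spawn(2)
    t = np.arange(0.0, duration_s, 1.0 / geom.fps)
    poses = [
        ProbePose(
            (0.0, bob_amplitude_mm * np.sin(2.0 * np.pi * bob_freq_hz * tk),
             elevation_mm),
            (0.0, 0.0, 0.0),
            float(tk),
        )
        for tk in t
    ]
    tracking = simulate_tracking(poses, noise, np.random.default_rng(c_track))
    rngs = [np.random.default_rng(c) for c in c_frames.spawn(len(poses))]
    frames = np.stack(
        [render_frame(phantom, p, beam, geom, r) for p, r in zip(poses, rngs)]
    )
    stream = FrameStream(frames, t, geom, poses=poses, seed=seed)
    return stream, tracking
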