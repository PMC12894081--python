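"""Synthetic drive generation with known ground-truth coupling.

Everything downstream of the sensors is testable against these
generators: a kinematic bicycle model realises the course geometry as a
steering-angle trace; head yaw is a delayed-copy of steering (drivers
turn the head a configurable lead time *before* steering, the mechanism
the coordination analysis is built to detect); dual accelerometer
streams encode lever angle plus terrain tilt with shared vibration; and
noisy pinhole landmark projections feed the pose solver.

All stochastic outputs are driven by explicit integer seeds and are
bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .courses import DEFAULT_WHEELBASE_M, CourseSpec, Segment
from .imu import ImuStream
from .pose import CameraModel, HeadPose, LandmarkFrame, LandmarkModel, project
from .series import AngleSeries

log = logging.getLogger(__name__)

#: Scooter speed cap, m/s (4 km/h).
SPEED_CAP_MS = 4.0 / 3.6

#: Standard gravity, m/s^2 (for converting vibration amplitudes to g).
G_MS2 = 9.80665

#: First-order steering-actuator time constant, s.
DEFAULT_STEER_TAU_S = 0.3


@dataclass(frozen=True)
class DriveTrace:
    """Simulated kinematic state over time.

    t seconds; position (N, 2) metres; heading/steering/throttle degrees;
    speed m/s; grade percent.  Steering positive = leftward turn
    (counter-clockwise from above), matching the head-yaw sign
    convention so that coordinated turning correlates positively.
    """

    t: np.ndarray
    position: np.ndarray
    heading: np.ndarray
    steering: np.ndarray
    throttle: np.ndarray
    speed: np.ndarray
    grade: np.ndarray
    rate: float
    wheelbase: float

    def steering_series(self) -> AngleSeries:
        return AngleSeries(self.t, self.steering, self.rate, channel="steering")

    def throttle_series(self) -> AngleSeries:
        return AngleSeries(self.t, self.throttle, self.rate, channel="throttle")

    def grade_series(self) -> AngleSeries:
        """Terrain inclination in degrees (converted from percent grade)."""
        incl = np.degrees(np.arctan(self.grade / 100.0))
        return AngleSeries(self.t, incl, self.rate, channel="inclination")


def _segment_curvature(seg: Segment, s_local: float) -> float:
    if seg.kind == "arc":
        return seg.curvature
    if seg.kind == "slalom":
        # sinusoidal weave: lateral amplitude = half the path width,
        # spatial period = two obstacle intervals (one full oscillation
        # passes two gates)
        lam = 2.0 * seg.slalom_interval
        amp = seg.slalom_width / 2.0
        return -amp * (2.0 * math.pi / lam) ** 2 * math.sin(
            2.0 * math.pi * s_local / lam)
    return 0.0


def simulate_drive(course: CourseSpec, speed: float = 1.0,
                   rate: float = 10.0, wheelbase: float = DEFAULT_WHEELBASE_M,
                   steer_tau: float = DEFAULT_STEER_TAU_S) -> DriveTrace:
    """Drive the course at constant speed with a kinematic bicycle model.

    The commanded steering angle tracks the local path curvature,
    delta = atan(wheelbase * kappa), through a first-order actuator lag
    of time constant ``steer_tau`` (0 disables it); heading integrates
    speed * tan(delta) / wheelbase.  Speeds above the 4 km/h scooter cap
    are rejected.
    """
    if not (0.0 < speed <= SPEED_CAP_MS + 1e-12):
        raise ValueError(
            f"speed must be in (0, {SPEED_CAP_MS:.4f}] m/s "
            f"(the scooter is capped at 4 km/h); got {speed} m/s"
        )
    if rate < 2.0:
        raise ValueError("sampling rate must be at least 2 Hz")
    if not course.segments:
        raise ValueError("empty course")

    total_len = course.length
    duration = total_len / speed
    n = int(math.floor(duration * rate)) + 1
    t = np.arange(n) / rate
    dt = 1.0 / rate

    bounds = np.cumsum([seg.length for seg in course.segments])
    kappa = np.empty(n)
    grade = np.empty(n)
    for i, ti in enumerate(t):
        s = min(ti * speed, total_len - 1e-12)
        j = int(np.searchsorted(bounds, s, side="right"))
        j = min(j, len(course.segments) - 1)
        seg = course.segments[j]
        s_local = s - (bounds[j] - seg.length)
        kappa[i] = _segment_curvature(seg, s_local)
        grade[i] = seg.grade

    cmd = np.degrees(np.arctan(wheelbase * kappa))
    steering = np.empty(n)
    steering[0] = cmd[0]
    if steer_tau > 0:
        alpha = dt / steer_tau
        for i in range(1, n):
            steering[i] = steering[i - 1] + alpha * (cmd[i] - steering[i - 1])
    else:
        steering[:] = cmd

    yaw_rate = speed * np.tan(np.radians(steering)) / wheelbase  # rad/s
    heading = np.concatenate(([0.0], np.cumsum(yaw_rate[:-1] * dt)))
    pos = np.zeros((n, 2))
    pos[1:, 0] = np.cumsum(speed * np.cos(heading[:-1]) * dt)
    pos[1:, 1] = np.cumsum(speed * np.sin(heading[:-1]) * dt)

    throttle = np.full(n, 30.0 * speed / SPEED_CAP_MS)  # constant-speed hold
    return DriveTrace(t, pos, np.degrees(heading), steering, throttle,
                      np.full(n, speed), grade, rate, wheelbase)


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth head-steering coupling.

    head_yaw(t) = gain * steering(t + lead_time) + drift(t) + noise(t):
    the head anticipates the steering trace by ``lead_time`` seconds.
    ``noise_sd`` is white Gaussian (deg); ``drift_sd`` is the intensity of
    an integrated random-walk baseline wander (deg per sqrt-second).
    """

    lead_time: float = 0.6
    gain: float = 1.5
    noise_sd: float = 2.0
    drift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lead_time < 0:
            raise ValueError("lead_time must be >= 0")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise_sd and drift_sd must be >= 0")

    def is_fractional(self, rate: float) -> bool:
        """True when the lead is not a whole number of samples at ``rate``."""
        k = self.lead_time * rate
        return abs(k - round(k)) > 1e-9


def generate_head_yaw(steering: AngleSeries, coupling: CouplingSpec) -> AngleSeries:
    """Synthesise a head-yaw series that leads the steering series.

    The output lives on the steering time axis truncated to the overlap
    region [t0, t_end - lead_time]; fractional-sample leads are realised
    by linear interpolation (and logged).  Raises if the lead equals or
    exceeds the series duration.
    """
    if coupling.lead_time >= steering.duration:
        raise ValueError(
            f"lead_time {coupling.lead_time} s must be shorter than the "
            f"steering series duration {steering.duration} s"
        )
    if coupling.is_fractional(steering.rate):
        log.info("fractional-sample lead time %.4f s at %.1f Hz: interpolating",
                 coupling.lead_time, steering.rate)
    t_out = steering.t[steering.t <= steering.t[-1] - coupling.lead_time + 1e-9]
    advanced = np.interp(t_out + coupling.lead_time, steering.t, steering.value)
    rng = np.random.default_rng(coupling.seed)
    value = coupling.gain * advanced
    if coupling.drift_sd > 0:
        steps = rng.normal(0.0, coupling.drift_sd / math.sqrt(steering.rate),
                           t_out.size)
        value = value + np.cumsum(steps)
    if coupling.noise_sd > 0:
        value = value + rng.normal(0.0, coupling.noise_sd, t_out.size)
    return AngleSeries(t_out, value, steering.rate, channel="head_yaw")


def synthesize_imu(drive: DriveTrace, vibration_sd: float = 0.0,
                   sensor_noise_sd: float = 0.0, seed: int = 0,
                   steering_axis: str = "pitch") -> tuple[ImuStream, ImuStream]:
    """Dual accelerometer streams for a simulated drive, units of g.

    The body-mounted unit senses gravity tilted by the terrain grade;
    the lever-mounted unit senses grade plus the steering operating
    angle on ``steering_axis``.  ``vibration_sd`` (m/s^2, per axis) is
    common-mode road vibration added identically to both units;
    ``sensor_noise_sd`` (m/s^2) is independent noise on the lever unit.
    """
    if vibration_sd < 0 or sensor_noise_sd < 0:
        raise ValueError("noise standard deviations must be >= 0")
    if steering_axis not in ("pitch", "roll"):
        raise ValueError("steering_axis must be 'pitch' or 'roll'")
    n = drive.t.size
    slope = np.arctan(drive.grade / 100.0)  # rad
    steer = np.radians(drive.steering)

    def tilt_vec(pitch: np.ndarray, roll: np.ndarray) -> np.ndarray:
        return np.column_stack((np.sin(pitch),
                                np.cos(pitch) * np.sin(roll),
                                np.cos(pitch) * np.cos(roll)))

    zeros = np.zeros(n)
    body = tilt_vec(slope, zeros)
    if steering_axis == "pitch":
        lever = tilt_vec(slope + steer, zeros)
    else:
        lever = tilt_vec(slope, steer)

    rng = np.random.default_rng(seed)
    if vibration_sd > 0:
        vib = rng.normal(0.0, vibration_sd / G_MS2, (n, 3))
        body = body + vib
        lever = lever + vib
    if sensor_noise_sd > 0:
        lever = lever + rng.normal(0.0, sensor_noise_sd / G_MS2, (n, 3))
    return (ImuStream(drive.t, lever, drive.rate),
            ImuStream(drive.t, body, drive.rate))


def head_poses_from_yaw(yaw: AngleSeries,
                        distance_mm: float = 600.0) -> list[HeadPose]:
    """Pure vertical-axis head poses at a fixed camera distance."""
    return [HeadPose.from_euler(v, 0.0, 0.0, (0.0, 0.0, distance_mm))
            for v in yaw.value]


def render_landmarks(poses, model: LandmarkModel, camera: CameraModel,
                     pixel_noise_sd: float = 0.0,
                     seed: int = 0) -> list[LandmarkFrame]:
    """Project the landmark model under each pose, with pixel noise.

    Per frame: 2D points are the pinhole projection of the posed 3D
    model plus isotropic Gaussian pixel noise.  A point behind the
    camera raises an error naming the offending frame.
    """
    if pixel_noise_sd < 0:
        raise ValueError("pixel_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    frames: list[LandmarkFrame] = []
    for i, pose in enumerate(poses):
        try:
            frame = project(model, pose, camera, frame=i)
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
        uv = frame.uv
        if pixel_noise_sd > 0:
            uv = uv + rng.normal(0.0, pixel_noise_sd, uv.shape)
        frames.append(LandmarkFrame(i, frame.point_ids, uv))
    return frames
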