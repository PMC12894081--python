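"""Accelerometer tilt extraction and dual-IMU differential compensation.

One IMU rides on the steering/throttle lever and a second on the scooter
body.  Under the quasi-static assumption (valid at walking speeds) the
gravity direction in each sensor frame yields a tilt angle; subtracting
the body-mounted inclination from the lever-mounted angle cancels
terrain slope and common-mode vibration, leaving only the operator's
input.  No gyro fusion or filtering is applied by default; an optional
moving-average smoother is exposed for noisy recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .series import AngleSeries

log = logging.getLogger(__name__)

#: Quasi-static plausibility band on the specific-force norm, in g.
_NORM_BAND = (0.5, 1.5)


@dataclass(frozen=True)
class ImuStream:
    """3-axis accelerometer samples, units of g (x forward, y left, z up)."""

    t: np.ndarray  # (N,) seconds, uniform
    a: np.ndarray  # (N, 3) acceleration, g
    rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "a", a)
        if a.ndim != 2 or a.shape != (t.size, 3):
            raise ValueError("a must be (N, 3) matching t")
        if t.size == 0:
            raise ValueError("empty stream")
        if t.size > 1 and not np.allclose(np.diff(t), 1.0 / self.rate, atol=1e-6):
            raise ValueError("non-uniform sampling")
        norm = np.linalg.norm(a, axis=1)
        n_out = int(np.count_nonzero((norm < _NORM_BAND[0]) | (norm > _NORM_BAND[1])))
        if n_out:
            log.warning(
                "%d/%d samples outside the quasi-static norm band [%.1f, %.1f] g",
                n_out, t.size, *_NORM_BAND,
            )

    def __len__(self) -> int:
        return self.t.size


def tilt_from_accel(stream: ImuStream, axis: str = "pitch") -> AngleSeries:
    """Quasi-static tilt angle from the gravity direction, degrees.

    pitch = atan2(a_x, sqrt(a_y^2 + a_z^2)); roll = atan2(a_y,
    sqrt(a_x^2 + a_z^2)).  Scale-invariant in the acceleration vector.
    Raises on any zero-norm sample, naming its index.
    """
    if axis not in ("pitch", "roll"):
        raise ValueError(f"axis must be 'pitch' or 'roll', got {axis!r}")
    a = stream.a
    norm = np.linalg.norm(a, axis=1)
    zero = np.flatnonzero(norm == 0.0)
    if zero.size:
        raise ValueError(f"zero-norm acceleration sample at index {zero[0]}")
    if axis == "pitch":
        ang = np.arctan2(a[:, 0], np.hypot(a[:, 1], a[:, 2]))
    else:
        ang = np.arctan2(a[:, 1], np.hypot(a[:, 0], a[:, 2]))
    return AngleSeries(stream.t, np.degrees(ang), stream.rate, channel="inclination")


def align_streams(a: AngleSeries, b: AngleSeries) -> tuple[AngleSeries, AngleSeries]:
    """Resample both series onto the common time grid at the higher rate.

    Linear interpolation over the overlap of the two supports; raises on
    an empty overlap.  Series already on identical grids pass through
    unchanged.
    """
    if a.t.size == b.t.size and np.allclose(a.t, b.t, atol=1e-9):
        return a, b
    t_lo = max(a.t[0], b.t[0])
    t_hi = min(a.t[-1], b.t[-1])
    if t_hi < t_lo:
        raise ValueError("series time ranges do not overlap")
    rate = max(a.rate, b.rate)
    n = int(np.floor((t_hi - t_lo) * rate)) + 1
    grid = t_lo + np.arange(n) / rate
    va = np.interp(grid, a.t, a.value)
    vb = np.interp(grid, b.t, b.value)
    return (AngleSeries(grid, va, rate, a.channel),
            AngleSeries(grid, vb, rate, b.channel))


def compensate(lever: AngleSeries, body: AngleSeries,
               smooth_window: int | None = None,
               channel: str | None = None) -> AngleSeries:
    """Differential compensation: lever angle minus body inclination.

    Streams are aligned first (see :func:`align_streams`); the output is
    the elementwise difference, tagged ``channel`` (default: the lever's
    channel).  ``smooth_window`` applies a centred moving average of that
    many samples to the result.
    """
    la, ba = align_streams(lever, body)
    out = la.value - ba.value
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        out = np.convolve(out, kernel, mode="same")
    ch = channel or (lever.channel if lever.channel != "inclination" else "steering")
    return AngleSeries(la.t, out, la.rate, channel=ch)
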