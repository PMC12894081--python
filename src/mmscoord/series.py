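"""Uniformly sampled angle time series.

All signal channels in the pipeline -- steering, throttle, head yaw,
terrain inclination -- travel through :class:`AngleSeries`: a strictly
increasing, uniformly spaced time axis in seconds and values in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Valid channel tags.
CHANNELS = ("steering", "throttle", "head_yaw", "inclination")

#: Tolerance on the sample-interval uniformity check, seconds.
_DT_TOL = 1e-6


@dataclass(frozen=True)
class AngleSeries:
    """A uniformly sampled angle signal.

    Parameters
    ----------
    t : ndarray
        Sample times, seconds; strictly increasing, uniform spacing ``1/rate``.
    value : ndarray
        Angle at each sample, degrees.
    rate : float
        Sampling rate, Hz.
    channel : str
        One of :data:`CHANNELS`.
    """

    t: np.ndarray
    value: np.ndarray
    rate: float
    channel: str = "steering"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("t and value must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("empty series")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; valid: {CHANNELS}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.rate) >= _DT_TOL):
                raise ValueError(
                    f"non-uniform sampling: |dt - 1/{self.rate}| exceeds {_DT_TOL} s"
                )

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Time spanned by the series, seconds (last minus first sample)."""
        return float(self.t[-1] - self.t[0])

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    def with_values(self, value: np.ndarray, channel: str | None = None) -> "AngleSeries":
        """Return a copy carrying new values on the same time axis."""
        return AngleSeries(self.t, np.asarray(value, float), self.rate,
                           channel or self.channel)

    def crop(self, t_start: float, t_end: float) -> "AngleSeries":
        """Return the sub-series with t_start <= t <= t_end (inclusive, with
        half-sample tolerance at the ends)."""
        eps = 0.5 * self.dt
        m = (self.t >= t_start - eps) & (self.t <= t_end + eps)
        if not m.any():
            raise ValueError("crop interval does not overlap the series")
        return AngleSeries(self.t[m], self.value[m], self.rate, self.channel)


def uniform_time_axis(duration: float, rate: float, t0: float = 0.0) -> np.ndarray:
    """Time axis [t0, t0 + duration) sampled at ``rate`` Hz."""
    n = int(round(duration * rate))
    return t0 + np.arange(n) / rate
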