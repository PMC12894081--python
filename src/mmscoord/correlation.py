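"""Sliding-window head-steering cross-correlation analysis.

The central statistic is the windowed Pearson correlation between the
head-yaw signal x_h and the steering signal x_s,

    R_hs(l) = sum_i (x_h[i+l] - mean(x_h)) (x_s[i] - mean(x_s))
              / sqrt( sum (x_h - mean)^2 * sum (x_s - mean)^2 ),

evaluated over the maximal overlap at each integer-sample lag l.  A
negative peak lag means the head movement precedes the steering
operation -- the behavioural signature of visual confirmation before a
turn.  A rolling variant slides a 20-second window in 1-second steps to
expose how the lag evolves along a driving course; per-course lags are
summarised as mean +- sample SD, and correlation magnitudes are banded
on a conventional verbal strength scale.

Windows with zero variance in either signal have an undefined
correlation: they are flagged as NaN, never coerced to 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .series import AngleSeries

log = logging.getLogger(__name__)

#: Verbal strength bands on |r| (inclusive edges at two decimals).
STRENGTH_BANDS = (
    (0.00, 0.30, "very weak"),
    (0.31, 0.50, "weak"),
    (0.51, 0.70, "moderate"),
    (0.71, 0.90, "strong"),
    (0.91, 1.00, "very strong"),
)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry for the rolling analysis.

    window_s : epoch length, seconds (default 20 -- long enough to span
        several turning cycles)
    step_s : epoch stride, seconds (default 1)
    max_lag_s : half-width of the lag search range, seconds (default 5;
        must be under half the window)
    """

    window_s: float = 20.0
    step_s: float = 1.0
    max_lag_s: float = 5.0

    def __post_init__(self) -> None:
        if self.window_s <= 2.0 * self.max_lag_s:
            raise ValueError("window_s must exceed twice max_lag_s")
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")
        if self.max_lag_s <= 0:
            raise ValueError("max_lag_s must be positive")

    def n_samples(self, rate: float) -> int:
        n = int(round(self.window_s * rate))
        if n < 3:
            raise ValueError("window must span at least 3 samples")
        return n


@dataclass(frozen=True)
class CrossCorrelogram:
    """Correlation versus lag; negative lag = head leads steering."""

    lags: np.ndarray  # seconds, symmetric about 0, spaced 1/rate
    r: np.ndarray  # correlation per lag; NaN where undefined
    rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags", np.asarray(self.lags, float))
        object.__setattr__(self, "r", np.asarray(self.r, float))
        if self.lags.shape != self.r.shape:
            raise ValueError("lags and r must have equal shape")

    @property
    def peak(self) -> tuple[float, float]:
        return peak_lag(self)

    @property
    def peak_lag_s(self) -> float:
        return self.peak[0]

    @property
    def peak_r(self) -> float:
        return self.peak[1]


@dataclass(frozen=True)
class RollingCorrelogram:
    """Epochs x lags correlation matrix with the per-epoch peak trace."""

    epoch_starts: np.ndarray  # seconds
    lags: np.ndarray  # seconds
    r: np.ndarray  # (n_epochs, n_lags), NaN where undefined
    peak_lags: np.ndarray  # (n_epochs,) seconds, NaN for undefined epochs
    peak_r: np.ndarray  # (n_epochs,)
    defined: np.ndarray  # (n_epochs,) bool mask
    rate: float


@dataclass(frozen=True)
class LagSummary:
    """Per-course lag statistics across participants or trials."""

    course: str
    lags: tuple[float, ...]
    r_values: tuple[float, ...]
    lag_mean: float
    lag_sd: float  # NaN when only one entry
    r_mean: float
    r_sd: float


def windowed_pearson(xh, xs) -> float:
    """Pearson correlation of two equal-length windows.

    Centred dot product over the product of centred norms; returns NaN
    (the undefined flag) when either window has zero variance.
    """
    xh = np.asarray(xh, dtype=float)
    xs = np.asarray(xs, dtype=float)
    if xh.shape != xs.shape:
        raise ValueError(f"length mismatch: {xh.shape} vs {xs.shape}")
    if xh.ndim != 1 or xh.size < 3:
        raise ValueError("windows must be 1-D with at least 3 samples")
    dh = xh - xh.mean()
    ds = xs - xs.mean()
    denom = math.sqrt(float(dh @ dh) * float(ds @ ds))
    if denom == 0.0:
        return float("nan")
    r = float(dh @ ds) / denom
    return float(np.clip(r, -1.0, 1.0))


def _lagged_r(vh: np.ndarray, vs: np.ndarray, k: int) -> float:
    """Correlation of head advanced by k samples against steering,
    over the maximal overlap."""
    if k >= 0:
        a, b = vh[k:], vs[: vs.size - k] if k else vs
    else:
        a, b = vh[: vh.size + k], vs[-k:]
    if a.size < 3:
        return float("nan")
    return windowed_pearson(a, b)


def cross_correlogram(xh: AngleSeries, xs: AngleSeries,
                      spec: WindowSpec | None = None) -> CrossCorrelogram:
    """Correlogram over integer-sample lags within +-max_lag_s.

    The two series are trimmed to their common time support first.  For
    each lag l, the head series shifted forward by l is correlated with
    the steering series over their maximal overlap, so a head trace that
    anticipates steering by d seconds peaks at l = -d.
    """
    spec = spec or WindowSpec()
    if abs(xh.rate - xs.rate) > 1e-9:
        raise ValueError("series must share a sampling rate; resample first")
    t_lo = max(xh.t[0], xs.t[0])
    t_hi = min(xh.t[-1], xs.t[-1])
    if t_hi < t_lo:
        raise ValueError("series do not overlap in time")
    vh = xh.crop(t_lo, t_hi).value
    vs = xs.crop(t_lo, t_hi).value
    n = min(vh.size, vs.size)
    vh, vs = vh[:n], vs[:n]
    # duration counts whole samples (n * dt), so a 20 s window at 10 Hz
    # needs exactly 200 samples
    if n / xh.rate < spec.window_s - 1e-9:
        raise ValueError(
            f"series duration {n / xh.rate:.1f} s is shorter than the "
            f"{spec.window_s} s analysis window"
        )
    kmax = int(round(spec.max_lag_s * xh.rate))
    ks = np.arange(-kmax, kmax + 1)
    r = np.array([_lagged_r(vh, vs, int(k)) for k in ks])
    return CrossCorrelogram(ks / xh.rate, r, xh.rate)


def peak_lag(c: CrossCorrelogram, refine: bool = False) -> tuple[float, float]:
    """Lag and value of the correlogram maximum (signed r, not |r|).

    Ties break toward the smallest |lag|, then toward the negative lag.
    With ``refine``, a parabola through the peak and its two neighbours
    yields a sub-sample lag estimate.  Raises if every r is undefined.
    """
    defined = np.isfinite(c.r)
    if not defined.any():
        raise ValueError("correlogram has no defined correlation values")
    rmax = np.nanmax(c.r)
    cand = np.flatnonzero(defined & (c.r >= rmax - 1e-15))
    # tie-break: smallest |lag|, then negative sign
    order = sorted(cand, key=lambda i: (abs(c.lags[i]), c.lags[i]))
    i = int(order[0])
    lag, r = float(c.lags[i]), float(c.r[i])
    if refine and 0 < i < c.r.size - 1 and np.isfinite(c.r[i - 1]) \
            and np.isfinite(c.r[i + 1]):
        y0, y1, y2 = c.r[i - 1], c.r[i], c.r[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # proper maximum; skip degenerate flat triples
            delta = 0.5 * (y0 - y2) / denom
            if abs(delta) <= 1.0:
                lag = float(c.lags[i] + delta / c.rate)
                r = float(y1 - 0.25 * (y0 - y2) * delta)
    return lag, r


def rolling_cross_correlogram(xh: AngleSeries, xs: AngleSeries,
                              spec: WindowSpec | None = None,
                              refine: bool = False) -> RollingCorrelogram:
    """Per-epoch correlograms from a sliding window.

    Epoch count = floor((duration - window_s) / step_s) + 1.  Epochs
    where every lag is undefined (zero-variance windows) are masked.
    """
    spec = spec or WindowSpec()
    if abs(xh.rate - xs.rate) > 1e-9:
        raise ValueError("series must share a sampling rate; resample first")
    t_lo = max(xh.t[0], xs.t[0])
    t_hi = min(xh.t[-1], xs.t[-1])
    if t_hi < t_lo:
        raise ValueError("series do not overlap in time")
    ch = xh.crop(t_lo, t_hi)
    cs = xs.crop(t_lo, t_hi)
    n = min(len(ch), len(cs))
    duration = n / xh.rate  # whole-sample duration convention
    if duration < spec.window_s - 1e-9:
        raise ValueError("series shorter than the analysis window")
    n_epochs = int(math.floor((duration - spec.window_s) / spec.step_s + 1e-9)) + 1
    win = spec.n_samples(xh.rate)
    step = spec.step_s * xh.rate
    kmax = int(round(spec.max_lag_s * xh.rate))
    lags = np.arange(-kmax, kmax + 1) / xh.rate

    rmat = np.full((n_epochs, lags.size), np.nan)
    pk_lag = np.full(n_epochs, np.nan)
    pk_r = np.full(n_epochs, np.nan)
    starts = np.empty(n_epochs)
    defined = np.zeros(n_epochs, dtype=bool)
    for e in range(n_epochs):
        i0 = int(round(e * step))
        seg_h = ch.value[i0:i0 + win]
        seg_s = cs.value[i0:i0 + win]
        starts[e] = ch.t[i0]
        r = np.array([_lagged_r(seg_h, seg_s, int(k))
                      for k in range(-kmax, kmax + 1)])
        rmat[e] = r
        if np.isfinite(r).any():
            defined[e] = True
            c = CrossCorrelogram(lags, r, xh.rate)
            pk_lag[e], pk_r[e] = peak_lag(c, refine=refine)
    n_undef = int(np.count_nonzero(~defined))
    if n_undef:
        log.warning("%d of %d epochs undefined (zero-variance windows)",
                    n_undef, n_epochs)
    return RollingCorrelogram(starts, lags, rmat, pk_lag, pk_r, defined, xh.rate)


def average_correlogram(trials: list[CrossCorrelogram]
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Elementwise mean and sample SD of correlograms across trials.

    Undefined (NaN) cells are excluded pairwise; returns
    (lags, mean, sd, count).  SD is NaN where fewer than two trials
    contribute.  Trials must share the lag axis exactly.
    """
    if not trials:
        raise ValueError("no trials")
    lags = trials[0].lags
    for c in trials[1:]:
        if c.lags.shape != lags.shape or not np.allclose(c.lags, lags, atol=1e-12):
            raise ValueError("trials have mismatched lag axes")
    mat = np.vstack([c.r for c in trials])
    count = np.isfinite(mat).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isfinite(mat), mat, np.nan), axis=0)
        sd = np.full(lags.shape, np.nan)
        ok = count >= 2
        if ok.any():
            sd[ok] = np.nanstd(mat[:, ok], axis=0, ddof=1)
    mean[count == 0] = np.nan
    return lags, mean, sd, count


def classify_strength(r: float) -> str:
    """Verbal band for a correlation magnitude.

    |r| is rounded to two decimals first, so the printed band edges
    (0.30/0.31, 0.50/0.51, ...) partition the range exhaustively.
    """
    if not np.isfinite(r) or abs(r) > 1.0 + 1e-12:
        raise ValueError(f"|r| must be <= 1, got {r}")
    mag = round(min(abs(float(r)), 1.0), 2)
    for lo, hi, label in STRENGTH_BANDS:
        if lo <= mag <= hi:
            return label
    raise AssertionError("unreachable: bands cover [0, 1]")


def coefficient_of_determination(r: float, decimals: int = 3) -> float:
    """r squared, rounded for reporting (0.79 -> 0.624)."""
    if not np.isfinite(r) or abs(r) > 1.0 + 1e-12:
        raise ValueError(f"|r| must be <= 1, got {r}")
    return round(float(r) ** 2, decimals)


def normality_gate(x, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk normality check used before correlation analysis.

    Returns (W, p, passed) with passed <=> p >= alpha.  The analysis
    proceeds either way; a failure is logged as a warning.  Sample size
    must be within the test's supported range [3, 5000].
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    w, p = stats.shapiro(x)
    passed = bool(p >= alpha)
    if not passed:
        log.warning("normality rejected (W=%.4f, p=%.2e < alpha=%.2f); "
                    "proceeding anyway", w, p, alpha)
    return float(w), float(p), passed


def summarize_lags(per_unit, course: str = "") -> LagSummary:
    """Mean +- sample SD (n-1) of per-participant (lag, r) pairs.

    The sign convention is preserved: negative mean lag means the head
    preceded the steering on average.  SD is NaN for a single entry.
    """
    per_unit = list(per_unit)
    if not per_unit:
        raise ValueError("at least one (lag, r) entry is required")
    lags = np.array([p[0] for p in per_unit], dtype=float)
    rs = np.array([p[1] for p in per_unit], dtype=float)
    sd = lambda v: float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
    return LagSummary(
        course=course,
        lags=tuple(lags.tolist()),
        r_values=tuple(rs.tolist()),
        lag_mean=float(lags.mean()),
        lag_sd=sd(lags),
        r_mean=float(rs.mean()),
        r_sd=sd(rs),
    )
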