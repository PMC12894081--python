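"""Figures: correlogram, rolling heat map with peak trace, averaged envelope."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .correlation import CrossCorrelogram, RollingCorrelogram


def plot_correlogram(c: CrossCorrelogram, path, title: str = "Cross-correlogram") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(c.lags, c.r, lw=1.5)
    try:
        lag, r = c.peak
        ax.plot([lag], [r], "o", color="crimson")
        ax.annotate(f"peak r={r:.2f} @ {lag:+.2f} s", (lag, r),
                    textcoords="offset points", xytext=(8, -12))
    except ValueError:
        pass
    ax.axvline(0.0, color="grey", lw=0.6)
    ax.set_xlabel("time lag [s]  (negative: head leads steering)")
    ax.set_ylabel("cross-correlation R")
    ax.set_ylim(-1.05, 1.05)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rolling(rc: RollingCorrelogram, path,
                 title: str = "Rolling windowed cross-correlogram") -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    extent = (rc.epoch_starts[0], rc.epoch_starts[-1], rc.lags[0], rc.lags[-1])
    im = ax.imshow(rc.r.T, aspect="auto", origin="lower", extent=extent,
                   cmap="viridis", vmin=-1.0, vmax=1.0)
    ax.plot(rc.epoch_starts[rc.defined], rc.peak_lags[rc.defined],
            color="white", lw=1.5, label="max R position")
    ax.set_xlabel("epoch start [s]")
    ax.set_ylabel("time lag [s]")
    ax.set_title(title)
    ax.legend(loc="upper right")
    fig.colorbar(im, ax=ax, label="R")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_envelope(lags: np.ndarray, mean: np.ndarray, sd: np.ndarray, path,
                  title: str = "Averaged cross-correlogram") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(lags, mean, lw=1.5, label="mean across trials")
    band = np.where(np.isfinite(sd), sd, 0.0)
    ax.fill_between(lags, mean - band, mean + band, alpha=0.3,
                    label="±1 SD")
    ax.axvline(0.0, color="grey", lw=0.6)
    ax.set_xlabel("time lag [s]  (negative: head leads steering)")
    ax.set_ylabel("cross-correlation R")
    ax.set_ylim(-1.05, 1.05)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
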