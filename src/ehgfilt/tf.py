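"""Time-frequency inspection utilities.

The frequency marginal (spectrogram energy summed over time) is used for
qualitative comparison of filter outputs against the pure Alvarez-wave
signal; the spectrogram plot is provided for visual inspection only.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .signal import Signal

__all__ = ["frequency_marginal", "marginal_distance", "plot_spectrogram"]


def frequency_marginal(sig: Signal, nperseg: int | None = None) -> tuple:
    """Spectrogram energy per frequency bin, summed over time.

    Returns (frequencies, marginal).
    """
    if nperseg is None:
        nperseg = min(len(sig) // 8, int(round(256 * sig.fs)))
    nperseg = max(nperseg, 16)
    f, _, S = sps.spectrogram(
        sig.samples, fs=sig.fs, nperseg=nperseg, noverlap=nperseg // 2
    )
    return f, S.sum(axis=1)


def marginal_distance(a: Signal, ref: Signal, band: tuple = (0.05, 0.5), nperseg: int | None = None) -> float:
    """RMS difference between two signals' frequency marginals in ``band``."""
    fa, ma = frequency_marginal(a, nperseg)
    fr, mr = frequency_marginal(ref, nperseg)
    if fa.size != fr.size or not np.allclose(fa, fr):
        raise ValueError("signals must share length and fs for marginal comparison")
    sel = (fa >= band[0]) & (fa <= band[1])
    return float(np.sqrt(np.mean((ma[sel] - mr[sel]) ** 2)))


def plot_spectrogram(sig: Signal, ax=None, fmax: float | None = 1.0, nperseg: int | None = None):
    """Spectrogram image (dB scale) for visual inspection."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if nperseg is None:
        nperseg = max(min(len(sig) // 8, int(round(256 * sig.fs))), 16)
    f, t, S = sps.spectrogram(
        sig.samples, fs=sig.fs, nperseg=nperseg, noverlap=nperseg // 2
    )
    if fmax is not None:
        sel = f <= fmax
        f, S = f[sel], S[sel]
    if ax is None:
        _, ax = plt.subplots()
    ax.pcolormesh(t, f, 10 * np.log10(S + 1e-20), shading="auto")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    return ax
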