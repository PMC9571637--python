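"""ECG-derived respiration (EDR) from the maternal ECG inside an EHG channel.

The respiration reference the adaptive cancellers need is not recorded by a
dedicated sensor: it is estimated from the beat-to-beat modulation of the
maternal ECG that the abdominal EHG electrodes pick up.  The chain is
QRS detection -> per-beat QRS area -> cubic interpolation to the EHG grid ->
outlier removal -> zero-phase band-pass to 0.20-0.34 Hz -> z-score ->
rescaling to std(EHG)/4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal as sps

from .signal import Signal

__all__ = [
    "QrsAnnotations",
    "EdrEstimate",
    "detect_qrs",
    "edr_series",
    "postprocess_edr",
    "estimate_respiration",
]

RESP_BAND = (0.20, 0.34)  # Hz, typical adult breathing band


@dataclass
class QrsAnnotations:
    """Detected R peaks and the per-beat QRS areas (amplitude * s)."""

    peak_indices: np.ndarray
    areas: np.ndarray
    fs: float

    def __post_init__(self):
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.peak_indices.size != self.areas.size:
            raise ValueError("one area per peak required")
        if np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def peak_times(self) -> np.ndarray:
        return self.peak_indices / self.fs


@dataclass
class EdrEstimate:
    """Raw interpolated QRS-area series and the post-processed reference."""

    raw_edr: Signal
    resp_ref: Signal


def detect_qrs(
    ecg: Signal,
    band: tuple = (5.0, 40.0),
    integrate_win: float = 0.15,
    refractory: float = 0.3,
    area_halfwidth: float = 0.05,
    min_beats: int = 5,
) -> QrsAnnotations:
    """Energy-based QRS detection with per-beat area measurement.

    Band-pass -> differentiate -> square -> moving-window integrate ->
    threshold with a refractory period; each beat's area is the integral of
    the absolute band-passed ECG over +-``area_halfwidth`` s around the peak.
    """
    if ecg.fs < 100:
        raise ValueError("detect_qrs needs fs >= 100 Hz")
    if ecg.duration < 10:
        raise ValueError("detect_qrs needs a record of at least 10 s")
    fs = ecg.fs
    hi = min(band[1], 0.45 * fs)
    sos = sps.butter(3, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, ecg.samples)
    energy = np.diff(filt, prepend=filt[0]) ** 2
    win = max(int(round(integrate_win * fs)), 1)
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    scale = np.percentile(integ, 99)
    if scale <= 0:
        raise ValueError("signal has no QRS-band energy; unusable as ECG")
    peaks, _ = sps.find_peaks(
        integ, height=0.2 * scale, distance=max(int(round(refractory * fs)), 1)
    )
    # refine each detection to the local maximum of |filtered ECG|
    half = int(round(area_halfwidth * fs))
    refined = []
    for p in peaks:
        lo, hi_i = max(p - half, 0), min(p + half + 1, filt.size)
        refined.append(lo + int(np.argmax(np.abs(filt[lo:hi_i]))))
    refined = np.unique(refined)
    if refined.size < min_beats:
        raise ValueError(
            f"only {refined.size} beats found (< {min_beats}); unusable as ECG"
        )
    areas = np.array(
        [
            np.trapezoid(
                np.abs(filt[max(p - half, 0) : min(p + half + 1, filt.size)]), dx=1.0 / fs
            )
            for p in refined
        ]
    )
    return QrsAnnotations(refined, areas, fs)


def edr_series(ann: QrsAnnotations, fs_out: float, duration: float) -> Signal:
    """Cubic interpolation of (beat time, QRS area) onto a uniform grid.

    Beyond the first/last beat the series extrapolates as a constant.
    """
    if ann.peak_indices.size < 5:
        raise ValueError("need at least 5 beats to interpolate an EDR series")
    t = ann.peak_times()
    n = int(round(duration * fs_out))
    grid = np.arange(n) / fs_out
    f = interpolate.interp1d(
        t,
        ann.areas,
        kind="cubic",
        bounds_error=False,
        fill_value=(ann.areas[0], ann.areas[-1]),
    )
    return Signal(f(grid), fs_out)


def _despike(x: np.ndarray, nsigma: float = 3.0) -> np.ndarray:
    """Replace samples beyond median +- nsigma*1.4826*MAD by interpolation."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        return x.copy()
    bad = np.abs(x - med) > nsigma * robust_sd
    if not np.any(bad):
        return x.copy()
    out = x.copy()
    idx = np.arange(x.size)
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def bandpass_resp(x: np.ndarray, fs: float, band: tuple = RESP_BAND, order: int = 4) -> np.ndarray:
    """Zero-phase band-pass to the respiration band."""
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def postprocess_edr(raw_edr: Signal, ehg: Signal, band: tuple = RESP_BAND) -> Signal:
    """Outlier removal, band-limiting, z-score, and std(EHG)/4 rescaling.

    The output is the respiration reference handed to the adaptive filters;
    by construction std(out) = std(ehg)/4.
    """
    x = raw_edr.samples
    if raw_edr.fs != ehg.fs or len(raw_edr) != len(ehg):
        # resample onto the EHG grid first
        t_src = raw_edr.t0 + np.arange(len(raw_edr)) / raw_edr.fs
        t_dst = ehg.t0 + np.arange(len(ehg)) / ehg.fs
        x = np.interp(t_dst, t_src, x)
    if np.std(x) == 0:
        raise ValueError("EDR series has zero variance")
    x = _despike(x)
    x = bandpass_resp(x, ehg.fs, band)
    sd = np.std(x)
    if sd == 0:
        raise ValueError("band-limited EDR has zero variance")
    z = (x - np.mean(x)) / sd
    return Signal(z * np.std(ehg.samples) / 4.0, ehg.fs, ehg.t0)


def estimate_respiration(ehg_channel: Signal, ecg_fs_min: float = 100.0) -> EdrEstimate:
    """Full EDR chain on one EHG channel (which carries the maternal ECG)."""
    ann = detect_qrs(ehg_channel)
    raw = edr_series(ann, ehg_channel.fs, ehg_channel.duration)
    ref = postprocess_edr(raw, ehg_channel)
    return EdrEstimate(raw_edr=raw, resp_ref=ref)
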