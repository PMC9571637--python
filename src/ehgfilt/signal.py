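"""Uniformly sampled real-valued time series.

``Signal`` is the currency passed between every stage of the package: the
synthetic scenario generators produce them, the adaptive filters consume a
desired/reference pair of them, and the spectral-feature code analyses them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Signal"]


@dataclass
class Signal:
    """A real-valued, uniformly sampled time series.

    Parameters
    ----------
    samples : array-like of float
        Amplitudes, arbitrary units (nominally volts).
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def copy_with(self, samples: np.ndarray) -> "Signal":
        """A new Signal sharing this one's fs and t0."""
        return Signal(np.asarray(samples, dtype=np.float64), self.fs, self.t0)

    # -- I/O -----------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write a two-column (time_s, amplitude) CSV."""
        arr = np.column_stack([self.times(), self.samples])
        np.savetxt(path, arr, delimiter=",", header="time_s,amplitude", comments="")

    @classmethod
    def from_csv(cls, path) -> "Signal":
        """Read a two-column (time_s, amplitude) CSV written by :meth:`to_csv`."""
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        t, x = arr[:, 0], arr[:, 1]
        if t.size < 2:
            raise ValueError("need at least two samples to infer fs")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time column is not uniformly sampled")
        return cls(x, fs=1.0 / dt[0], t0=float(t[0]))


def require_compatible(a: Signal, b: Signal) -> None:
    """Raise ValueError unless the two signals share length and fs."""
    if len(a) != len(b):
        raise ValueError(f"signal lengths differ: {len(a)} vs {len(b)}")
    if not np.isclose(a.fs, b.fs):
        raise ValueError(f"sampling rates differ: {a.fs} vs {b.fs}")
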