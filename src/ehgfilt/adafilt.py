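"""The sixteen-filter adaptive noise-cancellation bank.

Topology: the desired signal d(n) (EHG = Alvarez waves + respiration
interference + noise) and an interference reference x(n) (the respiration
estimate) enter the canceller; the filter shapes x into y(n), an estimate of
the interference inside d, and the cleaned output is the error
e(n) = d(n) - y(n).

Architectures: the LMS family (LMS, NLMS, BLMS, FDAF, FXLMS, SELMS, SDLMS,
SSLMS), the recursive-least-squares family (RLS, HRLS, QRD-RLS, SWRLS,
HSWRLS), the least-squares lattice (LSL), the fast transversal filter (FTF)
and the block Wiener solution of the normal equations.  RLS, HRLS and
QRD-RLS solve the identical exponentially weighted least-squares problem by
different numerics and agree to rounding; so do SWRLS and HSWRLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

from . import _kernels
from .signal import Signal, require_compatible

__all__ = [
    "FilterSpec",
    "FilterRun",
    "FilterInstabilityError",
    "FILTER_NAMES",
    "run_filter",
    "rmse",
]

#: Canonical architecture names, addressable from configs and the CLI.
FILTER_NAMES = (
    "LMS",
    "NLMS",
    "FDAF",
    "BLMS",
    "FXLMS",
    "SELMS",
    "SDLMS",
    "SSLMS",
    "LSL",
    "FTF",
    "RLS",
    "HRLS",
    "SWRLS",
    "HSWRLS",
    "QRD-RLS",
    "Wiener",
)

#: Which scalar parameter each architecture searches ("mu", "lam" or None).
FILTER_PARAM = {
    "LMS": "mu",
    "NLMS": "mu",
    "FDAF": "mu",
    "BLMS": "mu",
    "FXLMS": "mu",
    "SELMS": "mu",
    "SDLMS": "mu",
    "SSLMS": "mu",
    "LSL": "lam",
    "FTF": "lam",
    "RLS": "lam",
    "HRLS": "lam",
    "SWRLS": "lam",
    "HSWRLS": "lam",
    "QRD-RLS": "lam",
    "Wiener": None,
}


class FilterInstabilityError(RuntimeError):
    """Raised when an adaptive recursion breaks down numerically."""


@dataclass
class FilterSpec:
    """Configuration of one adaptive-filter run.

    Parameters
    ----------
    name : str
        One of :data:`FILTER_NAMES`.
    L : int
        Filter length in taps.
    mu : float, optional
        Step size (LMS family).
    lam : float, optional
        Forgetting factor (RLS / lattice / FTF families).
    eps : float
        Normalisation / regularisation constant.
    delta : float
        Inverse-correlation (soft-constraint) initialisation scale for the
        RLS family.
    win : int, optional
        Sliding-window length in samples (SWRLS / HSWRLS); defaults to 4*L.
    block : int, optional
        Block length (BLMS / FDAF); defaults to L.
    soft : float
        Soft-start energy for the lattice and FTF recursions.
    secondary_path : ndarray, optional
        FIR secondary path for FXLMS (identity by default).
    """

    name: str
    L: int
    mu: float | None = None
    lam: float | None = None
    eps: float = 1e-6
    delta: float = 1e2
    win: int | None = None
    block: int | None = None
    soft: float = 0.01
    secondary_path: np.ndarray | None = None

    def __post_init__(self):
        if self.name not in FILTER_NAMES:
            raise ValueError(f"unknown filter {self.name!r}; expected one of {FILTER_NAMES}")
        if not (isinstance(self.L, (int, np.integer)) and self.L >= 1):
            raise ValueError(f"L must be an integer >= 1, got {self.L}")
        kind = FILTER_PARAM[self.name]
        if kind == "mu":
            # mu == 0 is admissible (a frozen, all-zero filter) so that grid
            # searches over [0, mu_max] are well defined
            if self.mu is None or self.mu < 0:
                raise ValueError(f"{self.name} requires a step size mu >= 0")
        elif kind == "lam":
            if self.lam is None or not 0 < self.lam <= 1:
                raise ValueError(f"{self.name} requires a forgetting factor in (0, 1]")
            if self.name == "FTF" and self.lam < 1.0 - 0.5 / self.L - 1e-12:
                raise ValueError(
                    f"FTF requires lam in [1 - 0.5/L, 1] = [{1 - 0.5 / self.L:.4f}, 1], "
                    f"got {self.lam}"
                )

    @property
    def window(self) -> int:
        return self.win if self.win is not None else 4 * self.L

    @property
    def block_len(self) -> int:
        return self.block if self.block is not None else self.L


@dataclass
class FilterRun:
    """Outputs of one canceller run: y + e = d sample-wise, exactly."""

    y: Signal
    e: Signal
    w_final: np.ndarray
    spec: FilterSpec = field(repr=False, default=None)
    rescues: int = 0


# ---------------------------------------------------------------------------
# block (non-adaptive) architectures


def _wiener(d: np.ndarray, x: np.ndarray, L: int, eps: float):
    """Single-shot solution of the length-L normal equations R w = p with
    biased sample correlations over the whole record, then fixed filtering."""
    n = d.size
    # biased autocorrelation of x, lags 0..L-1, consistent with prewindowing
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    X = np.fft.rfft(x, nfft)
    r = np.fft.irfft(np.abs(X) ** 2, nfft)[:L] / n
    # cross-correlation p[k] = mean(d[i] x[i-k])
    D = np.fft.rfft(d, nfft)
    p = np.fft.irfft(D * np.conj(X), nfft)[:L] / n
    R = sla.toeplitz(r)
    try:
        w = sla.solve(R, p, assume_a="pos")
    except sla.LinAlgError:
        w = sla.solve(R + eps * np.eye(L), p, assume_a="pos")
    y = sps.lfilter(w, [1.0], x)
    return y, d - y, w, 0


def _fdaf(d: np.ndarray, x: np.ndarray, L: int, mu: float, block: int, eps: float):
    """Overlap-save frequency-domain block LMS with per-bin power
    normalisation and gradient constraint."""
    with np.errstate(over="ignore", invalid="ignore"):
        return _fdaf_impl(d, x, L, mu, block, eps)


def _fdaf_impl(d: np.ndarray, x: np.ndarray, L: int, mu: float, block: int, eps: float):
    B = block
    nfft = 2 * B
    n = d.size
    nblocks = int(np.ceil(n / B))
    pad = nblocks * B - n
    dp = np.concatenate([d, np.zeros(pad)])
    xp = np.concatenate([x, np.zeros(pad)])
    W = np.zeros(nfft // 2 + 1, dtype=complex)
    # seed the per-bin power estimate at the record's mean power so the
    # first normalised steps are not wildly overscaled
    Pw = np.full(nfft // 2 + 1, max(np.mean(x**2) * nfft, eps))
    xbuf = np.zeros(nfft)
    y = np.empty(nblocks * B)
    lam_p = 0.9
    for kb in range(nblocks):
        xbuf[:B] = xbuf[B:]
        xbuf[B:] = xp[kb * B : (kb + 1) * B]
        X = np.fft.rfft(xbuf)
        yb = np.fft.irfft(X * W)[B:]
        y[kb * B : (kb + 1) * B] = yb
        eb = dp[kb * B : (kb + 1) * B] - yb
        E = np.fft.rfft(np.concatenate([np.zeros(B), eb]))
        Pw = lam_p * Pw + (1.0 - lam_p) * np.abs(X) ** 2
        G = np.conj(X) * E / (Pw + eps)
        g = np.fft.irfft(G)
        g[B:] = 0.0  # gradient constraint
        W = W + mu * np.fft.rfft(g)
    w_t = np.fft.irfft(W)[:B]
    w = np.zeros(L)
    w[: min(L, B)] = w_t[: min(L, B)]
    return y[:n], d - y[:n], w, 0


# ---------------------------------------------------------------------------
# dispatch

_LMS_MODES = {"LMS": 0, "SELMS": 1, "SDLMS": 2, "SSLMS": 3}


def _run_arrays(spec: FilterSpec, d: np.ndarray, x: np.ndarray):
    name, L = spec.name, int(spec.L)
    if name in _LMS_MODES:
        return _kernels.lms_family(d, x, L, float(spec.mu), _LMS_MODES[name])
    if name == "NLMS":
        return _kernels.nlms(d, x, L, float(spec.mu), float(spec.eps))
    if name == "BLMS":
        return _kernels.blms(d, x, L, float(spec.mu), int(spec.block_len))
    if name == "FXLMS":
        sec = (
            np.asarray(spec.secondary_path, dtype=np.float64)
            if spec.secondary_path is not None
            else np.array([1.0])
        )
        xf = np.convolve(x, sec)[: x.size]
        yraw = np.empty_like(d)
        return _kernels.fxlms(d, x, xf, yraw, sec, L, float(spec.mu))
    if name == "FDAF":
        return _fdaf(d, x, L, float(spec.mu), int(spec.block_len), float(spec.eps))
    if name == "RLS":
        return _kernels.rls(d, x, L, float(spec.lam), float(spec.delta))
    if name == "HRLS":
        return _kernels.hrls(d, x, L, float(spec.lam), float(spec.delta))
    if name == "QRD-RLS":
        return _kernels.qrd_rls(d, x, L, float(spec.lam), float(spec.delta))
    if name == "SWRLS":
        return _kernels.swrls(d, x, L, float(spec.lam), float(spec.delta), int(spec.window))
    if name == "HSWRLS":
        return _kernels.hswrls(d, x, L, float(spec.lam), float(spec.delta), int(spec.window))
    if name == "LSL":
        return _kernels.lsl(d, x, L, float(spec.lam), float(spec.soft))
    if name == "FTF":
        return _kernels.ftf(d, x, L, float(spec.lam), float(spec.soft))
    if name == "Wiener":
        return _wiener(d, x, L, float(spec.eps))
    raise ValueError(f"unhandled filter {name}")  # pragma: no cover


def run_filter(spec: FilterSpec, desired: Signal, reference: Signal) -> FilterRun:
    """Run one adaptive canceller over a desired/reference signal pair.

    Returns a :class:`FilterRun` with the interference estimate ``y``, the
    cleaned error ``e = desired - y`` (exact, sample-wise) and the final tap
    vector.  Raises :class:`FilterInstabilityError` if the recursion breaks
    down (FTF instead rescues itself and reports the rescue count).
    """
    require_compatible(desired, reference)
    d = np.ascontiguousarray(desired.samples, dtype=np.float64)
    x = np.ascontiguousarray(reference.samples, dtype=np.float64)
    y, e, w, status = _run_arrays(spec, d, x)
    rescues = 0
    if spec.name == "FTF":
        rescues = int(status)
    elif status != 0:
        raise FilterInstabilityError(
            f"{spec.name} (L={spec.L}, mu={spec.mu}, lam={spec.lam}) became "
            "numerically unstable"
        )
    if not np.all(np.isfinite(e)):
        raise FilterInstabilityError(
            f"{spec.name} (L={spec.L}, mu={spec.mu}, lam={spec.lam}) produced "
            "non-finite output (diverged)"
        )
    return FilterRun(
        y=desired.copy_with(y),
        e=desired.copy_with(e),
        w_final=np.asarray(w),
        spec=spec,
        rescues=rescues,
    )


def rmse(a: Signal | np.ndarray, b: Signal | np.ndarray) -> float:
    """Root-mean-square error between two equal-length signals."""
    av = a.samples if isinstance(a, Signal) else np.asarray(a, dtype=float)
    bv = b.samples if isinstance(b, Signal) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.shape} vs {bv.shape}")
    with np.errstate(over="ignore"):  # near-divergent runs legitimately overflow to inf
        return float(np.sqrt(np.mean((av - bv) ** 2)))
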