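"""Bipolar montage handling and Welch-periodogram Alvarez-wave features.

The real-data application works on bipolar channels (differences of two
monopolar electrodes on the 4x4 abdominal grid).  Adaptive filtering is
applied to each monopolar channel with its own respiration reference, and
the filtered monopolars are recombined into the bipolar arrangement in
which the Alvarez waves were annotated.  Each annotated segment is then
characterised by six spectral features from its Welch periodogram, and the
effect of filtering is summarised as the percent change of each feature.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import signal as sps

from .adafilt import FilterSpec, run_filter
from .signal import Signal, require_compatible

__all__ = [
    "BipolarMap",
    "AlvAnnotation",
    "PeriodogramFeatures",
    "FeatureDelta",
    "FEATURE_NAMES",
    "to_bipolar",
    "filter_monopolar_pair",
    "welch_features",
    "feature_delta",
    "default_bipolar_map",
]

FEATURE_NAMES = ("bw", "flo", "fhi", "power", "peak", "freq_peak")


@dataclass
class BipolarMap:
    """Bipolar arrangements over the 4x4 (channels 1-16) electrode grid."""

    pairs: list  # (bipolar_id, monopolar_a, monopolar_b)

    def __post_init__(self):
        seen = set()
        for bid, a, b in self.pairs:
            if not (1 <= a <= 16 and 1 <= b <= 16):
                raise ValueError(f"BP{bid}: monopolar channels must be in 1..16")
            if a == b:
                raise ValueError(f"BP{bid}: the two monopolar channels must differ")
            if bid in seen:
                raise ValueError(f"duplicate bipolar id {bid}")
            seen.add(bid)
            if not _grid_adjacent(a, b):
                raise ValueError(
                    f"BP{bid}: channels {a} and {b} are not adjacent on the 4x4 grid"
                )

    def monopolars(self, bipolar_id) -> tuple:
        for bid, a, b in self.pairs:
            if bid == bipolar_id:
                return a, b
        raise KeyError(f"unknown bipolar id {bipolar_id}")

    @classmethod
    def from_yaml(cls, path) -> "BipolarMap":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls([(p["id"], p["a"], p["b"]) for p in cfg["pairs"]])


def _grid_adjacent(a: int, b: int) -> bool:
    ra, ca = divmod(a - 1, 4)
    rb, cb = divmod(b - 1, 4)
    return abs(ra - rb) + abs(ca - cb) == 1


def default_bipolar_map() -> BipolarMap:
    """The bundled default (vertically adjacent pairs; an editable guess,
    since the published electrode diagram does not enumerate its arrows)."""
    ref = importlib.resources.files("ehgfilt.data") / "bipolar_map.yaml"
    cfg = yaml.safe_load(ref.read_text())
    return BipolarMap([(p["id"], p["a"], p["b"]) for p in cfg["pairs"]])


@dataclass
class AlvAnnotation:
    """One externally supplied Alvarez-wave segment annotation."""

    record_id: str
    bipolar_id: int | str
    t_start: float
    t_end: float

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")


@dataclass
class PeriodogramFeatures:
    """Six spectral features of one segment's Welch periodogram.

    ``bw`` is the occupied bandwidth: the band [flo, fhi] holding
    ``energy_fraction`` (default 75%) of the spectral energy, symmetric in
    cumulative energy; ``power`` the PSD integral over that band; ``peak``
    and ``freq_peak`` locate the PSD maximum.
    """

    bw: float
    flo: float
    fhi: float
    power: float
    peak: float
    freq_peak: float
    energy_fraction: float = 0.75
    welch_meta: dict = field(default_factory=dict, repr=False)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_NAMES}


@dataclass
class FeatureDelta:
    """Percent change of each feature, filtered relative to raw."""

    deltas: dict  # feature name -> percent (nan when raw == 0)

    def __getitem__(self, k):
        return self.deltas[k]


# ---------------------------------------------------------------------------


def to_bipolar(mono_a: Signal, mono_b: Signal) -> Signal:
    """Bipolar montage: sample-wise difference a - b."""
    require_compatible(mono_a, mono_b)
    return mono_a.copy_with(mono_a.samples - mono_b.samples)


def filter_monopolar_pair(
    spec: FilterSpec,
    mono_a: Signal,
    mono_b: Signal,
    resp_a: Signal,
    resp_b: Signal,
) -> Signal:
    """Filter each monopolar channel against its respiration reference,
    then recombine into the bipolar arrangement."""
    e_a = run_filter(spec, mono_a, resp_a).e
    e_b = run_filter(spec, mono_b, resp_b).e
    return to_bipolar(e_a, e_b)


def welch_features(
    segment: Signal,
    energy_fraction: float = 0.75,
    band: tuple | None = (0.1, 1.0),
    nperseg: int | None = None,
    window: str = "hann",
) -> PeriodogramFeatures:
    """Welch-periodogram features of one Alvarez-wave segment.

    The occupied band [flo, fhi] is delimited by the symmetric cumulative
    energy quantiles ((1-f)/2 and 1-(1-f)/2 of the total within the
    analysis ``band``), linearly interpolated between PSD bins, so
    power(flo..fhi) = f * power(band) by construction.
    """
    x = segment.samples
    fs = segment.fs
    if nperseg is None:
        nperseg = int(min(x.size // 4, round(256.0 * fs)))
    if nperseg < 8 or x.size < 2 * nperseg:
        raise ValueError(
            f"segment of {x.size} samples is too short for Welch analysis "
            f"(needs >= 2 windows of {max(nperseg, 8)})"
        )
    f, psd = sps.welch(x, fs=fs, window=window, nperseg=nperseg, noverlap=nperseg // 2)
    if band is not None:
        sel = (f >= band[0]) & (f <= band[1])
        if sel.sum() < 4:
            raise ValueError("analysis band holds fewer than 4 PSD bins")
        f, psd = f[sel], psd[sel]
    # cumulative energy with trapezoidal integration
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (psd[1:] + psd[:-1]) * np.diff(f))])
    total = cum[-1]
    if total <= 0:
        raise ValueError("segment has no spectral energy in the analysis band")
    q_lo = 0.5 * (1.0 - energy_fraction) * total
    q_hi = (1.0 - 0.5 * (1.0 - energy_fraction)) * total
    flo = float(np.interp(q_lo, cum, f))
    fhi = float(np.interp(q_hi, cum, f))
    power = float(q_hi - q_lo)  # = energy_fraction * total by construction
    ipk = int(np.argmax(psd))
    return PeriodogramFeatures(
        bw=fhi - flo,
        flo=flo,
        fhi=fhi,
        power=power,
        peak=float(psd[ipk]),
        freq_peak=float(f[ipk]),
        energy_fraction=energy_fraction,
        welch_meta={
            "window": window,
            "nperseg": int(nperseg),
            "noverlap": int(nperseg // 2),
            "band": band,
            "fs": fs,
        },
    )


def feature_delta(raw: PeriodogramFeatures, filt: PeriodogramFeatures) -> FeatureDelta:
    """Percent change per feature: 100*(filtered - raw)/raw."""
    if raw.welch_meta and filt.welch_meta and raw.welch_meta != filt.welch_meta:
        raise ValueError("features were computed with different Welch settings")
    deltas = {}
    for k in FEATURE_NAMES:
        r, fv = getattr(raw, k), getattr(filt, k)
        deltas[k] = 100.0 * (fv - r) / r if r != 0 else float("nan")
    return FeatureDelta(deltas)
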