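"""Synthetic EHG scenario generation.

Builds the three study scenarios used to optimise and rank the adaptive
filters: Gaussian-envelope Alvarez-wave atoms (narrow-band pulses with
spectral peaks in 0.2-0.4 Hz), a band-limited respiration interference in
0.20-0.34 Hz with chirp, triangular or random frequency modulation, and an
additive white-noise floor.  Also provides an amplitude-modulated synthetic
ECG used to exercise the ECG-derived-respiration (EDR) stage.

All generators are seed-reproducible: identical (scenario, seed) inputs give
byte-identical outputs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .signal import Signal

__all__ = [
    "AlvAtom",
    "RespirationSpec",
    "SimulationScenario",
    "make_alv_atom",
    "make_respiration",
    "compose_scenario",
    "make_synthetic_ecg",
    "load_scenario",
    "bundled_scenario",
    "BUNDLED_SCENARIO_IDS",
]


# ---------------------------------------------------------------------------
# parametric descriptions


@dataclass
class AlvAtom:
    """A Gaussian-envelope sinusoidal pulse modelling one Alvarez wave.

    The pulse is parameterised the way :func:`scipy.signal.gausspulse` is:
    the two-sided spectral width at ``fract_bw_r`` dB equals
    ``fract_bw * f_atom``, and the time support is truncated where the
    envelope falls below ``pulse_level`` dB (the -60 dB default gives time
    durations close to empirical Alvarez waves).
    """

    f_atom: float
    fract_bw: float
    t_center: float
    fract_bw_r: float = -6.0
    pulse_level: float = -60.0
    amplitude: float = 1.0

    def __post_init__(self):
        if not self.f_atom > 0:
            raise ValueError("f_atom must be > 0")
        if not 0 < self.fract_bw < 2:
            raise ValueError("fract_bw must be in (0, 2)")
        if not self.fract_bw_r < 0:
            raise ValueError("fract_bw_r must be negative (dB)")
        if not self.pulse_level < self.fract_bw_r:
            raise ValueError("pulse_level must be below fract_bw_r (dB)")
        if self.t_center < 0:
            raise ValueError("t_center must be >= 0")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")

    @property
    def cutoff(self) -> float:
        """Half-width (s) of the truncated support at ``pulse_level`` dB."""
        return float(
            sps.gausspulse(
                "cutoff",
                fc=self.f_atom,
                bw=self.fract_bw,
                bwr=self.fract_bw_r,
                tpr=self.pulse_level,
            )
        )


@dataclass
class RespirationSpec:
    """Band-limited respiration interference in [f_lo, f_hi] Hz.

    ``kind`` selects the frequency-modulation law:

    - ``chirp``: linear sweep f_lo -> f_hi across the whole record,
    - ``triangular``: symmetric triangle between the band edges with period
      ``cycle_period`` (nominally ``n_cycles`` cycles; the pattern continues
      periodically if the record outlasts them),
    - ``random``: a smooth, seed-reproducible trajectory through uniform
      draws in [f_lo, f_hi] taken every ``knot_interval`` seconds
      (PCHIP-interpolated, so the trajectory never leaves the band).
    """

    kind: str
    duration: float
    f_lo: float = 0.20
    f_hi: float = 0.34
    cycle_period: float = 250.0
    n_cycles: int = 8
    knot_interval: float = 30.0
    seed: int = 0
    amplitude: float = 1.0

    KINDS = ("chirp", "triangular", "random")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown respiration kind {self.kind!r}; expected one of {self.KINDS}")
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.amplitude < 0:  # 0 = interference-free degenerate case
            raise ValueError("amplitude must be >= 0")


@dataclass
class SimulationScenario:
    """A full synthetic EHG scenario: atoms + respiration + white noise."""

    atoms: list
    respiration: RespirationSpec
    fs: float = 20.0
    duration: float = 3500.0
    noise_std: float = 0.05
    seed: int = 0
    scenario_id: int | str = 0

    def __post_init__(self):
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        fmax = max((a.f_atom for a in self.atoms), default=0.0)
        if not self.fs > 2 * fmax:
            raise ValueError(f"fs={self.fs} violates fs > 2*max(f_atom)={2 * fmax}")
        for a in self.atoms:
            if a.t_center >= self.duration:
                raise ValueError(
                    f"atom at t_center={a.t_center}s lies outside the {self.duration}s record"
                )


@dataclass
class ScenarioSignals:
    """The four role-tagged signals composed from a scenario."""

    noisy: Signal  # d(n): atoms + respiration + noise
    clean: Signal  # s(n): atoms only
    interference: Signal  # N(n): respiration only
    noise: Signal
    scenario: SimulationScenario = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# generators


def make_alv_atom(atom: AlvAtom, fs: float, duration: float) -> Signal:
    """Synthesise one Alvarez atom on a uniform grid of length duration*fs.

    The returned signal is zero outside the truncated envelope support,
    symmetric about ``t_center``, with its spectral peak at ``f_atom``.
    """
    cut = atom.cutoff
    if atom.t_center - cut < 0 or atom.t_center + cut > duration:
        raise ValueError(
            f"atom (f_atom={atom.f_atom} Hz, t_center={atom.t_center}s) support "
            f"+-{cut:.1f}s exceeds [0, {duration}]s"
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    mask = np.abs(t - atom.t_center) <= cut
    x[mask] = atom.amplitude * sps.gausspulse(
        t[mask] - atom.t_center,
        fc=atom.f_atom,
        bw=atom.fract_bw,
        bwr=atom.fract_bw_r,
        tpr=atom.pulse_level,
    )
    return Signal(x, fs)


def _instantaneous_frequency(spec: RespirationSpec, t: np.ndarray) -> np.ndarray:
    if spec.kind == "chirp":
        return spec.f_lo + (spec.f_hi - spec.f_lo) * t / spec.duration
    if spec.kind == "triangular":
        frac = np.mod(t / spec.cycle_period, 1.0)
        tri = np.where(frac < 0.5, 2.0 * frac, 2.0 * (1.0 - frac))
        return spec.f_lo + (spec.f_hi - spec.f_lo) * tri
    # random: smooth trajectory through uniform draws at regular knots
    rng = np.random.default_rng(spec.seed)
    t_knots = np.arange(0.0, spec.duration + spec.knot_interval, spec.knot_interval)
    f_knots = rng.uniform(spec.f_lo, spec.f_hi, size=t_knots.size)
    return PchipInterpolator(t_knots, f_knots)(np.clip(t, 0.0, t_knots[-1]))


def make_respiration(spec: RespirationSpec, fs: float) -> Signal:
    """Phase-continuous FM sinusoid confined to [f_lo, f_hi]."""
    if not fs > 2 * spec.f_hi:
        raise ValueError(f"fs={fs} must exceed 2*f_hi={2 * spec.f_hi}")
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    f_inst = _instantaneous_frequency(spec, t)
    # phase-continuous: integrate instantaneous frequency (trapezoidal)
    phase = 2.0 * np.pi * np.concatenate(
        ([0.0], np.cumsum(0.5 * (f_inst[1:] + f_inst[:-1]) / fs))
    )
    return Signal(spec.amplitude * np.cos(phase), fs)


def compose_scenario(scn: SimulationScenario) -> ScenarioSignals:
    """Compose noisy = clean + interference + noise, sample-wise exactly."""
    n = int(round(scn.duration * scn.fs))
    clean = np.zeros(n)
    for atom in scn.atoms:
        clean += make_alv_atom(atom, scn.fs, scn.duration).samples
    interference = make_respiration(scn.respiration, scn.fs).samples
    rng = np.random.default_rng(scn.seed)
    noise = rng.normal(0.0, scn.noise_std, size=n) if scn.noise_std > 0 else np.zeros(n)
    noisy = clean + interference + noise
    # store the noise as the exact closure of the sum so that
    # noisy - clean - interference - noise == 0 holds sample-wise in floats
    noise = noisy - clean - interference
    return ScenarioSignals(
        noisy=Signal(noisy, scn.fs),
        clean=Signal(clean, scn.fs),
        interference=Signal(interference, scn.fs),
        noise=Signal(noise, scn.fs),
        scenario=scn,
    )


# ---------------------------------------------------------------------------
# synthetic ECG (fixture for the EDR stage)


def _qrs_template(fs: float) -> np.ndarray:
    # stylised QRS: narrow positive R wave flanked by small Q and S troughs
    t = np.arange(-0.06, 0.08, 1.0 / fs)
    r = np.exp(-0.5 * (t / 0.012) ** 2)
    q = -0.15 * np.exp(-0.5 * ((t + 0.025) / 0.010) ** 2)
    s = -0.30 * np.exp(-0.5 * ((t - 0.030) / 0.014) ** 2)
    return r + q + s


def make_synthetic_ecg(
    hr_bpm: float,
    resp_freq: float,
    mod_depth: float,
    fs: float = 200.0,
    duration: float = 300.0,
    seed: int = 0,
    noise_std: float = 0.0,
) -> Signal:
    """Impulse-train-plus-template ECG with respiration-modulated QRS height.

    Beat k at time t_k carries amplitude ``1 + mod_depth*sin(2*pi*resp_freq*t_k)``,
    emulating the beat-to-beat QRS-area modulation that EDR exploits.
    """
    if not 0 <= mod_depth < 1:
        raise ValueError("mod_depth must be in [0, 1)")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz for a resolvable QRS")
    if resp_freq >= hr_bpm / 120.0:
        raise ValueError(
            f"resp_freq={resp_freq} Hz is not below half the beat rate ({hr_bpm / 120.0} Hz)"
        )
    n = int(round(duration * fs))
    x = np.zeros(n)
    beat_interval = 60.0 / hr_bpm
    tmpl = _qrs_template(fs)
    half = tmpl.size // 2
    t_beat = 0.5
    while t_beat < duration - 0.1:
        amp = 1.0 + mod_depth * np.sin(2.0 * np.pi * resp_freq * t_beat)
        i0 = int(round(t_beat * fs)) - half
        lo, hi = max(i0, 0), min(i0 + tmpl.size, n)
        x[lo:hi] += amp * tmpl[lo - i0 : hi - i0]
        t_beat += beat_interval
    if noise_std > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_std, size=n)
    return Signal(x, fs)


# ---------------------------------------------------------------------------
# scenario files


def _scenario_from_dict(cfg: dict) -> SimulationScenario:
    fs = float(cfg.get("fs", 20.0))
    duration = float(cfg.get("duration", 3500.0))
    seed = int(cfg.get("seed", 0))
    atoms = []
    for a in cfg["atoms"]:
        f_atom = float(a["f_atom"])
        if "fract_bw" in a:
            fract_bw = float(a["fract_bw"])
        else:
            fract_bw = float(a["bandwidth"]) / f_atom  # absolute -6 dB width
        atoms.append(
            AlvAtom(
                f_atom=f_atom,
                fract_bw=fract_bw,
                t_center=float(a["t_center"]),
                amplitude=float(a.get("amplitude", 1.0)),
            )
        )
    r = cfg["respiration"]
    resp = RespirationSpec(
        kind=r["kind"],
        duration=duration,
        f_lo=float(r.get("f_lo", 0.20)),
        f_hi=float(r.get("f_hi", 0.34)),
        cycle_period=float(r.get("cycle_period", 250.0)),
        n_cycles=int(r.get("n_cycles", 8)),
        knot_interval=float(r.get("knot_interval", 30.0)),
        seed=int(r.get("seed", seed)),
        amplitude=float(r.get("amplitude", 1.0)),
    )
    return SimulationScenario(
        atoms=atoms,
        respiration=resp,
        fs=fs,
        duration=duration,
        noise_std=float(cfg.get("noise_std", 0.05)),
        seed=seed,
        scenario_id=cfg.get("id", 0),
    )


def load_scenario(path) -> SimulationScenario:
    """Load a scenario definition from a YAML (or JSON-subset) file."""
    with open(path) as fh:
        return _scenario_from_dict(yaml.safe_load(fh))


BUNDLED_SCENARIO_IDS = (1, 2, 3)


def bundled_scenario(scenario_id: int, seed: int | None = None, **overrides) -> SimulationScenario:
    """One of the three bundled study scenarios (chirp / triangular / random).

    ``seed`` overrides the noise and random-respiration seeds; other keyword
    overrides replace top-level scenario fields (fs, duration, noise_std ...).
    """
    if scenario_id not in BUNDLED_SCENARIO_IDS:
        raise ValueError(f"scenario_id must be one of {BUNDLED_SCENARIO_IDS}")
    ref = importlib.resources.files("ehgfilt.data") / f"scenario{scenario_id}.yaml"
    cfg = yaml.safe_load(ref.read_text())
    cfg.update(overrides)
    if seed is not None:
        cfg["seed"] = int(seed)
        cfg.setdefault("respiration", {})
        cfg["respiration"]["seed"] = int(seed) + 7
    return _scenario_from_dict(cfg)
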