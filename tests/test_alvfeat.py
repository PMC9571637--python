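"""Bipolar montage, monopolar filtering, and occupied-bandwidth features."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import periodogram, welch

from ehgfilt.adafilt import FilterSpec
from ehgfilt.alvfeat import (
    AlvAnnotation,
    BipolarMap,
    default_bipolar_map,
    feature_delta,
    filter_monopolar_pair,
    to_bipolar,
    welch_features,
)
from ehgfilt.signal import Signal
from ehgfilt.synthgen import AlvAtom, RespirationSpec, make_alv_atom, make_respiration


def _band_power(sig, lo, hi):
    f, p = periodogram(sig.samples, fs=sig.fs)
    sel = (f >= lo) & (f <= hi)
    return float(np.trapezoid(p[sel], f[sel]))


@pytest.fixture(scope="module")
def contaminated_pair():
    """Monopolar pair: atoms + shared respiration picked up with different
    electrode gains (so the bipolar montage does not cancel it), with the
    true respiration as a perfect reference."""
    fs, duration = 20.0, 1200.0
    resp = make_respiration(RespirationSpec(kind="random", duration=duration, seed=21), fs)
    atom = make_alv_atom(AlvAtom(f_atom=0.30, fract_bw=0.02 / 0.30, t_center=600), fs, duration)
    rng = np.random.default_rng(22)
    a = Signal(atom.samples + resp.samples + 0.02 * rng.normal(size=len(resp)), fs)
    b = Signal(0.4 * resp.samples + 0.02 * rng.normal(size=len(resp)), fs)
    return {"a": a, "b": b, "resp": resp, "atom": atom}


class TestBipolar:
    def test_common_mode_cancels_and_identity(self):
        rng = np.random.default_rng(0)
        common = rng.normal(size=1000)
        ua = rng.normal(size=1000)
        a = Signal(ua + common, 20.0)
        b = Signal(common, 20.0)
        out = to_bipolar(a, b)
        assert np.allclose(out.samples, ua)
        zero = Signal(np.zeros(1000), 20.0)
        assert np.array_equal(to_bipolar(a, zero).samples, a.samples)

    def test_counter_phase_respiration_doubles(self):
        t = np.arange(2000) / 20.0
        r = np.sin(2 * np.pi * 0.25 * t)
        out = to_bipolar(Signal(r, 20.0), Signal(-r, 20.0))
        assert np.allclose(out.samples, 2 * r)

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError):
            to_bipolar(Signal(np.zeros(10), 20.0), Signal(np.zeros(9), 20.0))

    def test_default_map_is_valid_and_adjacent(self):
        bmap = default_bipolar_map()
        assert len(bmap.pairs) == 10
        assert bmap.monopolars(1) == (1, 5)

    def test_non_adjacent_pair_rejected(self):
        with pytest.raises(ValueError, match="adjacent"):
            BipolarMap([(1, 1, 16)])


class TestFilterMonopolarPair:
    def test_null_references_return_unfiltered_bipolar(self, contaminated_pair):
        a, b = contaminated_pair["a"], contaminated_pair["b"]
        zero = a.copy_with(np.zeros(len(a)))
        out = filter_monopolar_pair(FilterSpec("Wiener", L=2), a, b, zero, zero)
        assert np.array_equal(out.samples, to_bipolar(a, b).samples)

    def test_respiration_power_halved_atoms_kept(self, contaminated_pair):
        a, b, resp = (contaminated_pair[k] for k in ("a", "b", "resp"))
        raw_bip = to_bipolar(a, b)
        filt_bip = filter_monopolar_pair(FilterSpec("Wiener", L=2), a, b, resp, resp)
        # respiration band power drops by at least half...
        assert _band_power(filt_bip, 0.20, 0.34) <= 0.5 * _band_power(raw_bip, 0.20, 0.34)
        # ...while the atom itself survives: correlate with the known atom
        atom = contaminated_pair["atom"].samples
        sel = atom != 0
        assert np.corrcoef(filt_bip.samples[sel], atom[sel])[0, 1] > 0.8

    def test_counter_phase_enhancement_then_removal(self):
        # counter-phase respiration adds up in the bipolar montage but the
        # cancellers remove it from each monopolar channel first
        fs, duration = 20.0, 1200.0
        resp = make_respiration(RespirationSpec(kind="chirp", duration=duration, seed=3), fs)
        rng = np.random.default_rng(4)
        a = Signal(0.5 * resp.samples + 0.02 * rng.normal(size=len(resp)), fs)
        b = Signal(-0.5 * resp.samples + 0.02 * rng.normal(size=len(resp)), fs)
        raw_bip = to_bipolar(a, b)
        p_bip = _band_power(raw_bip, 0.20, 0.34)
        assert p_bip > _band_power(a, 0.20, 0.34)  # enhancement, not cancellation
        filt = filter_monopolar_pair(FilterSpec("RLS", L=2, lam=1.0), a, b, resp, resp)
        assert _band_power(filt, 0.20, 0.34) < 0.1 * p_bip

    def test_wiener_montage_linearity(self, contaminated_pair):
        # with identical references, filtering then subtracting equals
        # subtracting the per-channel estimates (linearity of the montage)
        from ehgfilt.adafilt import run_filter

        a, b, resp = (contaminated_pair[k] for k in ("a", "b", "resp"))
        spec = FilterSpec("Wiener", L=4)
        via_pair = filter_monopolar_pair(spec, a, b, resp, resp)
        e_a = run_filter(spec, a, resp).e
        e_b = run_filter(spec, b, resp).e
        assert np.allclose(via_pair.samples, e_a.samples - e_b.samples, atol=1e-12)


class TestWelchFeatures:
    def test_flat_spectrum_closed_form(self):
        # white noise: flat PSD over [0, fs/2]; 75% occupied band is
        # [0.125, 0.875] of the Nyquist span
        rng = np.random.default_rng(5)
        sig = Signal(rng.normal(size=200_000), 2.0)  # B = 1 Hz
        feats = welch_features(sig, band=None, nperseg=1024)
        assert feats.flo == pytest.approx(0.125, rel=0.05)
        assert feats.fhi == pytest.approx(0.875, rel=0.05)
        assert feats.bw == pytest.approx(0.75, rel=0.05)

    def test_pure_tone_line_spectrum(self):
        fs = 20.0
        t = np.arange(int(600 * fs)) / fs
        sig = Signal(np.sin(2 * np.pi * 0.3 * t), fs)
        feats = welch_features(sig, nperseg=2048)
        df = fs / 2048
        assert abs(feats.freq_peak - 0.3) <= df
        assert feats.bw <= 3 * df

    def test_against_bruteforce_cumulative_scan(self):
        rng = np.random.default_rng(6)
        sig = Signal(rng.normal(size=8000).cumsum() * 0.01 + rng.normal(size=8000), 20.0)
        nperseg = 512
        feats = welch_features(sig, band=(0.1, 1.0), nperseg=nperseg)
        f, psd = welch(sig.samples, fs=20.0, window="hann", nperseg=nperseg, noverlap=256)
        sel = (f >= 0.1) & (f <= 1.0)
        f, psd = f[sel], psd[sel]
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (psd[1:] + psd[:-1]) * np.diff(f))])
        flo = np.interp(0.125 * cum[-1], cum, f)
        fhi = np.interp(0.875 * cum[-1], cum, f)
        assert feats.flo == pytest.approx(flo, rel=1e-9)
        assert feats.fhi == pytest.approx(fhi, rel=1e-9)
        assert feats.power == pytest.approx(0.75 * cum[-1], rel=1e-9)

    @given(seed=st.integers(0, 500))
    def test_occupied_band_holds_75_percent(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6000)
        sig = Signal(np.convolve(x, np.ones(5) / 5)[:6000] + 0.1 * x, 20.0)
        feats = welch_features(sig, band=(0.1, 1.0), nperseg=512)
        f, psd = welch(sig.samples, fs=20.0, window="hann", nperseg=512, noverlap=256)
        sel = (f >= 0.1) & (f <= 1.0)
        total = np.trapezoid(psd[sel], f[sel])
        assert feats.power / total == pytest.approx(0.75, abs=0.01)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="short"):
            welch_features(Signal(np.ones(32), 20.0), nperseg=64)


class TestFeatureDelta:
    def test_arithmetic_and_identity(self):
        rng = np.random.default_rng(7)
        sig = Signal(rng.normal(size=4000), 20.0)
        f1 = welch_features(sig, nperseg=256)
        d0 = feature_delta(f1, f1)
        assert all(v == 0.0 for v in d0.deltas.values())
        f2 = welch_features(sig, nperseg=256)
        f2.power = f1.power * 0.8
        assert feature_delta(f1, f2)["power"] == pytest.approx(-20.0)

    def test_mismatched_welch_settings_rejected(self):
        rng = np.random.default_rng(8)
        sig = Signal(rng.normal(size=4000), 20.0)
        f1 = welch_features(sig, nperseg=256)
        f2 = welch_features(sig, nperseg=512)
        with pytest.raises(ValueError, match="Welch"):
            feature_delta(f1, f2)

    def test_power_removal_widens_band(self):
        # a quasi-tonal respiration overlapping the atom frequency: removing
        # its concentrated power makes the background tails carry a larger
        # share of the energy, so the 75% occupied band must widen
        from ehgfilt.adafilt import run_filter

        fs, dur = 20.0, 600.0
        f0 = 0.29
        atom = make_alv_atom(AlvAtom(f_atom=f0, fract_bw=0.02 / f0, t_center=300), fs, dur)
        resp = make_respiration(
            RespirationSpec(kind="chirp", duration=dur, f_lo=f0 - 0.01, f_hi=f0 + 0.01,
                            amplitude=0.7),
            fs,
        )
        noise = 0.05 * np.random.default_rng(10).normal(size=len(atom))
        raw = Signal(atom.samples + resp.samples + noise, fs)
        filt = run_filter(FilterSpec("Wiener", L=2), raw, resp).e
        seg = slice(int(200 * fs), int(400 * fs))
        raw_f = welch_features(Signal(raw.samples[seg], fs))
        flt_f = welch_features(Signal(filt.samples[seg], fs))
        delta = feature_delta(raw_f, flt_f)
        assert delta["power"] < 0
        assert delta["peak"] < 0
        assert delta["bw"] > 0
        assert delta["flo"] < 0 < delta["fhi"]

    def test_annotation_validation(self):
        with pytest.raises(ValueError):
            AlvAnnotation("r1", 1, 100.0, 90.0)
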