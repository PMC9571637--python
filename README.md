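# ehgfilt

Adaptive-filter attenuation of the maternal respiration electromyogram
(MR-EMG) in the uterine electrohysterogram (EHG).

## The problem

The EHG — the uterine muscle electromyogram recorded on the maternal
abdomen — contains Alvarez (Alv) waves: low-amplitude, localised components
with spectral peaks between 0.2 and 0.4 Hz that are candidate markers for
term/preterm labour prediction. Maternal breathing produces an
electromyographic interference in 0.20–0.34 Hz, squarely inside the Alvarez
band, so classical band filters cannot remove it without destroying the
signal of interest. Adaptive noise cancellation can: given a reference
estimate x(n) of the interference, an adaptive filter shapes it into y(n),
an estimate of the interference embedded in the recorded signal d(n), and
the cleaned output is the error

    e(n) = d(n) − y(n).

`ehgfilt` is a toolkit for choosing and applying the canceller:

- **`synthgen`** — synthetic EHG scenarios: Gaussian-envelope Alvarez atoms
  (`scipy.signal.gausspulse` parameterisation: centre frequency, −6 dB
  fractional bandwidth, −60 dB envelope truncation) over chirp, triangular
  or random frequency-modulated respiration, plus white noise; also an
  amplitude-modulated synthetic ECG for testing the respiration estimator.
- **`adafilt`** — sixteen canceller architectures: LMS, NLMS, FDAF, BLMS,
  FXLMS, SELMS, SDLMS, SSLMS, LSL, FTF, RLS, HRLS, SWRLS, HSWRLS, QRD-RLS
  and the block Wiener solution of the normal equations. The per-sample
  recursions are numba-compiled; RLS/HRLS/QRD-RLS (and SWRLS/HSWRLS) solve
  the identical least-squares problem by different numerics and agree to
  rounding.
- **`optsel`** — the study's core procedure: for every (filter, scenario)
  pair, a coarse grid over filter length L and step size μ or forgetting
  factor λ, scored by RMSE between the cleaned output and the pure
  (atoms-only) signal; then a one-pass fine grid of ±1 coarse step at 10×
  resolution; then best-filter selection by the lowest-RMSE majority
  criterion across scenarios, resolving parameter disagreements to the
  worst-case (triangular, second) scenario.
- **`edr`** — ECG-derived respiration: the reference x(n) is estimated from
  the maternal ECG picked up by the EHG electrodes themselves (QRS
  detection → per-beat QRS area → cubic interpolation → despiking →
  zero-phase 0.20–0.34 Hz band-pass → z-score → rescaling to std(EHG)/4).
- **`alvfeat`** — real-data application: bipolar montage handling (filter
  the monopolar channels, recombine the bipolar arrangement), and six
  Welch-periodogram features per annotated Alvarez wave: the 75 %-energy
  occupied band [flo, fhi], its width bw, the in-band power, the PSD peak
  and its frequency.
- **`statval`** — paired z-tests of raw vs filtered features with
  Bonferroni adjustment p_bonf = min(1, 2p), and quartile summaries of the
  percent feature changes.
- **`pipeline` / `cli`** — the two study branches as reproducible commands.

## Worked example

Optimise the two headline architectures on a compact synthetic scenario and
rank them:

```sh
$ ehgfilt optimize --filters wiener,rls --out results/demo
filter  scenario  L   mu  lam     rmse  seed
Wiener         1  2 None  NaN 0.050412   101
   RLS         1  3 None  1.0 0.050879   101
Wiener         2  2 None  NaN 0.052876   102
   RLS         2  2 None  1.0 0.053737   102
Wiener         3  2 None  NaN 0.050449   103
   RLS         3  2 None  1.0 0.050721   103
winners: [['Wiener'], ['RLS']]
```

Each row is the fine-tuned optimum for one (filter, scenario) pair: the
Wiener filter needs only its length (L = 2 taps everywhere); RLS selects a
forgetting factor λ = 1.00 (infinite memory — the reference-to-interference
mapping is stationary even though the respiration itself sweeps), and its
RMSE sits just above the Wiener's because the recursive solution pays a
convergence transient that the block solution does not. The L = 3 in the
first scenario is a noise-level wobble of an almost flat surface; the
selection rule (common value, else worst-case scenario) resolves every
winner to L = 2. RMSE values are on the scale of the simulated amplitudes
(unit atoms, unit respiration, noise σ = 0.05, hence the ≈ 0.05 noise floor
that no canceller can beat — the white noise is absent from the reference).

The real-data branch runs end-to-end on a bundled synthetic pseudo-record
(two monopolar electrodes, annotated atoms, known respiration reference):

```sh
$ ehgfilt run-real-study --demo --out results/real
feature            group  n  mean_diff         z            p       p_bonf
     bw           Wiener  5   0.000095  5.913335 3.352494e-09 6.704988e-09
    flo           Wiener  5  -0.000131 -3.374153 7.404321e-04 1.480864e-03
  power           Wiener  5  -0.003148 -1.431741 1.522180e-01 3.044360e-01
   peak           Wiener  5  -0.089995 -1.427971 1.533002e-01 3.066004e-01
  power RLS/HRLS/QRD-RLS 15  -0.001985 -2.614391 8.938663e-03 1.787733e-02
   peak RLS/HRLS/QRD-RLS 15  -0.057183 -2.577552 9.950283e-03 1.990057e-02
```

(abridged; the demo has only five annotated waves, so the z-tests warn
about the small-n normal approximation). Occupied-band power and the PSD
peak of the annotated waves drop after filtering (negative `mean_diff`),
the occupied band widens (`bw` up, `flo` down) — the qualitative signature
of respiration removal.

## Data formats

Real multichannel records are read from plain CSV (a `time_s` column plus
`ch1…ch16`); Alvarez-wave annotations from CSV
(`record_id,bipolar_id,t_start,t_end`); the bipolar arrangement table and
scenario definitions are YAML (bundled defaults in `src/ehgfilt/data/`).
Signals export to two-column `time_s,amplitude` CSV.
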