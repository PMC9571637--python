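# Third study scenario: three Alvarez atoms over a random breathing regime
# (smooth seed-reproducible frequency trajectory inside 0.20-0.34 Hz).
id: 3
fs: 20.0
duration: 3500.0
seed: 103
noise_std: 0.05
respiration:
  kind: random
  f_lo: 0.20
  f_hi: 0.34
  knot_interval: 30.0
  seed: 103
  amplitude: 1.0
atoms:
  - {bandwidth: 0.02, f_atom: 0.2500, t_center: 1000}
  - {bandwidth: 0.02, f_atom: 0.3000, t_center: 2000}
  - {bandwidth: 0.02, f_atom: 0.3500, t_center: 3000}
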