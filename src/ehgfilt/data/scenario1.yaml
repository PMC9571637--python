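# First study scenario: two Alvarez atoms over a chirp (linear-sweep) respiration.
id: 1
fs: 20.0
duration: 3500.0
seed: 101
noise_std: 0.05
respiration:
  kind: chirp
  f_lo: 0.20
  f_hi: 0.34
  amplitude: 1.0
atoms:
  - {bandwidth: 0.02, f_atom: 0.2500, t_center: 1000}
  - {bandwidth: 0.02, f_atom: 0.3500, t_center: 3000}
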