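# Second study scenario: eight Alvarez atoms over a triangular-FM respiration
# (smooth-to-fast in 250 s per cycle, eight cycles). The abrupt modulation makes
# this the worst-case scenario for the adaptive filters.
id: 2
fs: 20.0
duration: 3500.0
seed: 102
noise_std: 0.05
respiration:
  kind: triangular
  f_lo: 0.20
  f_hi: 0.34
  cycle_period: 250.0
  n_cycles: 8
  amplitude: 1.0
atoms:
  - {bandwidth: 0.02, f_atom: 0.2084, t_center: 500}
  - {bandwidth: 0.02, f_atom: 0.3415, t_center: 1250}
  - {bandwidth: 0.02, f_atom: 0.2622, t_center: 1604}
  - {bandwidth: 0.02, f_atom: 0.2622, t_center: 1896}
  - {bandwidth: 0.02, f_atom: 0.3043, t_center: 2173}
  - {bandwidth: 0.02, f_atom: 0.3043, t_center: 2327}
  - {bandwidth: 0.02, f_atom: 0.3415, t_center: 2750}
  - {bandwidth: 0.02, f_atom: 0.2084, t_center: 3000}
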