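# Default bipolar arrangements over the 4x4 abdominal electrode grid
# (channels 1-16, row-major: 1-4 top row ... 13-16 bottom row).
# Ten vertically adjacent pairs; this is an editable default, not a fixed
# truth -- the published electrode diagram does not enumerate its arrows.
pairs:
  - {id: 1, a: 1, b: 5}
  - {id: 2, a: 5, b: 9}
  - {id: 3, a: 9, b: 13}
  - {id: 4, a: 2, b: 6}
  - {id: 5, a: 6, b: 10}
  - {id: 6, a: 10, b: 14}
  - {id: 7, a: 3, b: 7}
  - {id: 8, a: 7, b: 11}
  - {id: 9, a: 11, b: 15}
  - {id: 10, a: 4, b: 8}
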