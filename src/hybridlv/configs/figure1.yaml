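# Classical predator-prey orbit: closed curve around the equilibrium (3, 2).
seed: 0
mu:
  source: constant
  value: 1.0
macro:
  a: 2.0
  b: 1.0
  c: 1.0
  d: 3.0
  x0: 4.0
  y0: 1.0
  dt: 1.0e-3
  t_end: 40.0
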