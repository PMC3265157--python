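# Hybrid orbit with closed-form learning coefficient, immune-dominant start:
# with x0 << y0 the asymptotic closed orbit is reached sooner than in figure2a.
seed: 0
mu:
  source: closed_form
  eta: 0.25
macro:
  a: 2.0
  b: 1.0
  c: 1.0
  d: 3.0
  x0: 0.1
  y0: 9.0
  dt: 1.0e-3
  t_end: 40.0
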