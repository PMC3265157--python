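# Fully coupled run: the learning coefficient is computed from an actual
# delta-mode kinetic simulation instead of the closed form.
seed: 0
grid:
  lower: -6.0
  upper: 6.0
  n_nodes: 241
kinetic:
  mode: delta_reduced
  rates: 0.25
  dt: 0.01
  t_end: 40.0
mu:
  source: kinetic
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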