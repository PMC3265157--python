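# hybridlv

A hybrid two-scale simulator of tumour–immune competition.

Two cell populations compete: tumour cells proliferate without control and
*hide* by reshaping their activity profile, while immune cells must *learn*
that profile before their attack becomes effective.  `hybridlv` couples the
two natural descriptions of this contest:

* a **kinetic layer**, in which each population `i` carries a probability
  density `f_i(t, u)` over a scalar biological activity `u`, evolving under
  binary interactions with encounter rates `η_ij` and transition densities
  `φ_ij(u*, u^*, u)`:

  ```
  ∂f_i/∂t (u) = Σ_j η_ij ∬ φ_ij(u*, u^*, u) f_i(u*) f_j(u^*) du* du^*
                − f_i(u) Σ_j η_ij ∫ f_j(u^*) du^*
  ```

  with general tabulated, separable (`φ_ij = ψ_i ξ_j`, `i ≠ j`) and
  Dirac-delta kernel representations — the delta case collapses to the
  local system `∂f_1/∂t = η_12 f_1 f_2 − (η_11 + η_12) f_1` (and
  symmetrically for `f_2`);

* a **hiding-learning functional** `μ(t) = 1 − ∫ (f_1 − f_2)² du ∈ [0, 1]`
  measuring how well the immune population has reproduced the tumour's
  activity distribution (`μ = 1` ⇔ identical distributions).  For equal
  rates `η` and the Gaussian initial difference `f(0, u) = e^{−u²}/√π` it
  has the closed form `μ(t) = 1 − e^{−4ηt}/√(2π)`;

* a **macroscopic layer**: a Lotka–Volterra system for the population
  sizes `x` (tumour, prey-like) and `y` (immune, predator-like) whose
  predation coefficient is scaled by the learning level:

  ```
  dx/dt = a x − μ(t) b x y,     dy/dt = c x y − d y .
  ```

  With `μ ≡ 1` this is the classical conservative predator–prey system
  with equilibrium `(d/c, a/b)`; with `μ(t) < 1` the immune attack is
  initially blunted and the instantaneous equilibrium
  `(d/c, a/(b μ(t)))` descends over time to the classical one.

## Worked example

Run the packaged hybrid-orbit configuration (`a = 2`, `b = c = 1`,
`d = 3`, closed-form `μ` with `η = 1/4`, start `(x₀, y₀) = (4, 1)`):

```bash
$ hybridlv run figure2a --out out/figure2a
run complete: t = 40, x = 2.35788, y = 4.93915, mu = 1; outputs in out/figure2a/
```

By `t = 40` the learning coefficient has saturated (`μ = 1` to machine
precision), so the trajectory has settled onto a closed classical orbit
around `(3, 2)`; the state `(2.36, 4.94)` is a point on that orbit.  The
output directory holds `macro.csv` (columns `t, x, y, mu`),
`mu_trace.csv`, and `run.json` (config echo plus any warnings, e.g. mass
drift of a kinetic run).  `hybridlv selfcheck` runs the fast invariant
suite (quadrature order, closed-form μ identity, RK4 decay oracle,
first-integral drift, kernel-expansion equivalence);
`hybridlv fixtures` emits seeded random densities and a separable-kernel
descriptor for testing.

A fully coupled run, where `μ` is computed from an actual delta-mode
kinetic simulation instead of the closed form, is packaged as
`hybridlv run hybrid_kinetic`.

`python scripts/reproduce_figures.py --out results/figures [--plot]`
regenerates all three reference orbits (classical; hybrid tumour-dominant
start `(4, 1)`; hybrid immune-dominant start `(0.1, 9)`) and reports how
much later the tumour-dominant start reaches the asymptotic orbit.

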