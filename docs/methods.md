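# Methods

## Model

Two interacting cell populations are described at two scales.  At the
microscopic scale each population `i ∈ {1, 2}` (1 = tumour, 2 = immune)
carries a distribution `f_i(t, u)` over a scalar *activity* `u` — the
biological function a cell expresses.  Binary interactions are
characterised by encounter rates `η_ij ≥ 0` and transition densities
`φ_ij(u*, u^*, u)`: the probability density that a candidate particle of
population `i` with activity `u*`, meeting a field particle of population
`j` with activity `u^*`, ends at activity `u`.  Conservation of candidates
requires `∫ φ_ij du = 1` for every `(u*, u^*)`.  The resulting evolution
is the gain/loss integro-differential system quoted in the README.

At the macroscopic scale the population sizes follow a predator–prey
system in which the predation coefficient `b` is scaled by the
hiding-learning functional `μ[f](t) = 1 − ∫ (f_1 − f_2)² du`.  Only the
tumour (prey) equation is modified — this is the literal statement of the
model; a symmetric modification of the immune equation would be a
plausible extension but is not what the model says.  The coupling is
one-way: the kinetic layer drives `μ`, and population sizes do not feed
back into the kinetic equations (kernels and rates are static).

## Kernel representations

* **General**: a dense table per ordered pair `(i, j)` over
  (candidate, field, outcome) grid triples, `O(n³)` memory per block.
  Blocks are stored in a dictionary; an absent block is identically zero.
* **Separable**: `φ_ij = ψ_i(u*, u) ξ_j(u^*, u)` for `i ≠ j`; the
  diagonal vanishes by construction (the factor `1 − δ_ij`), so diagonal
  blocks are never stored and are exempted from the normalisation check.
  The unit-outcome-mass constraint applies to the *product* only — the
  individual factors are not densities, and any scaling convention is
  absorbed between them.
* **Dirac delta** (`ψ_i = δ(u − u*)`, `ξ_j = δ(u − u^*)`): kept symbolic.
  A gridded delta would introduce resolution-dependent error that the
  closed-form results for this case do not have, so the marker simply
  routes the solver to the analytically reduced local equations.

The loss term of the separable system exists in two variants: the *full*
form uses the actual field masses `∫ f_j du`, while the *reduced* form
substitutes their nominal value 1, giving the constant coefficient
`η_i1 + η_i2`.  The reduced dynamics (and the delta dynamics derived from
it) do **not** preserve unit mass: the gain `η_12 ∫ f_1 f_2 du` generally
differs from the loss.  This is a property of the model, not a numerical
artifact; the integrator therefore records the mass drift in the run
metadata and emits a `MassDriftWarning` when it exceeds 1e-6 rather than
renormalising silently.

## Activity grid and quadrature

The activity domain is truncated to `[−6, 6]` and discretised uniformly
with an odd number of nodes (default 241, spacing 0.05) carrying
composite-Simpson weights.  Rationale for the truncation: the canonical
Gaussian difference profile is `< 3e-16` at `|u| = 6`, below
double-precision quadrature noise.  Simpson was chosen because its
fourth-order accuracy is directly testable (exactness on cubics; 16×
error decay per halving on a generic smooth integrand).  Note that for
Gaussian-type integrands whose derivatives vanish at the truncated
endpoints the composite rule inherits the trapezoidal rule's
super-algebraic convergence, so those integrals are exact to roundoff
already at moderate resolution — convergence-order tests must use an
integrand with non-vanishing endpoint derivatives.

The double collision integral of the general mode is evaluated with the
tensor product of the Simpson weights (einsum over precomputed weighted
densities), `O(n³)` per evaluation and pair.  This is routine at `n = 61`
(the default working resolution for dense kernels) and still desk-scale at
`n = 241` for cross-pair-only kernels.

Densities are validated at construction: nonnegativity always (tolerance
1e-9 for integrator output), unit mass within relative 1e-6 when a state
is declared normalised, with an explicit `renormalize()` rather than
silent rescaling.  The pointwise bound `f ≤ 1` is reported as a warning
only: a narrow normalised density legitimately exceeds 1, the bound
conflates density with probability.

## The learning functional

`μ = 1 − ∫ (f_1 − f_2)² du` is clamped to 0 (with a `MuClampWarning`)
when the squared distance exceeds 1: the admissible-range condition is an
assumption on the inputs, not a guarantee of the functional form, and a
running simulation should degrade gracefully while surfacing the
violation.  The abstract boundary condition "μ = 0 when one distribution
vanishes" is *not* satisfied by this quadratic form (with `f_1 = 0` it
returns `1 − ∫ f_2²`) and is deliberately not asserted anywhere.

For equal rates `η` the delta-mode difference obeys `∂f/∂t = −2ηf`
exactly — the nonlinear terms cancel pointwise — so from the Gaussian
start `f(0, u) = e^{−u²}/√π` one gets `f(t, u) = e^{−(u² + 2ηt)}/√π` and
`μ(t) = 1 − e^{−4ηt}/√(2π)`.  This chain is the package's central oracle:
it is checked by quadrature (identity of the Gaussian integral), by the
RK4 integrator (sup-norm error and order), end-to-end along a numerical
trajectory, and by recovering `η` from a log-linear fit of the squared L2
distance (decay rate `4η`).

A note on the initial split: the model pins only the *difference* of the
two initial densities, never the individual ones.  Since the Gaussian
profile integrates to 1, the two individual densities cannot both be
probability densities.  The default configuration therefore sets
`f_2` to a truncated normalised Gaussian and `f_1 = f_2 + difference`;
the equal-rate difference dynamics is provably insensitive to this split,
which the test suite verifies against a random alternative split.

## Time integration

Both layers use classical fixed-step fourth-order Runge–Kutta: the order
is independently verifiable against the analytic decay (kinetic) and the
first integral `H = c x − d ln x + b y − a ln y` (macro).  Defaults:
kinetic `dt = 0.01`; macro `dt = 1e-3`, horizon `t_end = 40` (several
orbit periods at the reference parameters, seconds of runtime).  A step
producing a non-finite state aborts with the failure time.  `t_end` must
be a whole multiple of `dt` (within `dt/2`); no step-size adaptation.

For a kinetic-sourced `μ` the macro solver interpolates the recorded
trace linearly at each internal RK4 stage time.  Linear interpolation is
formally below RK4's order; in practice, choosing the kinetic step equal
to *half* the macro step places every stage time exactly on a trace node,
making the coupling error collapse to the accuracy of the trace values
themselves (observed ~1e-12 agreement with the closed-form source versus
~1e-4 over long horizons when the steps are equal and stages fall between
nodes).

"Orbits are closed curves" is verified through conservation of `H`
(stationary exactly at `(d/c, a/b)`), not literal circularity —
Lotka–Volterra orbits are closed but circular only near equilibrium.  The
time-dependent hybrid "equilibrium" `(d/c, a/(b μ(t)))` is the
instantaneous nullcline intersection of a nonautonomous system; the
package computes it as defined and asserts only its monotone descent and
its classical limit.

## Synthetic inputs

The fixture generator produces (a) random densities — a positive baseline
plus 2–4 Gaussian bumps with seeded random centres, widths and
amplitudes, quadrature-normalised — and (b) separable kernels in which
`ψ_i(u*, ·)` is an even Gaussian bump about the grid midpoint with a
candidate-dependent width (row-normalised to unit outcome mass) and
`ξ_j(u^*, u) = 1 + ε tanh(u^*) h(u)` with `h` odd about the midpoint.
Because each `ψ` row is even and `h` is odd, the product integral is 1
for *every* star pair up to the numerically negligible odd moment
(~1e-15), so the constraint holds by construction rather than by
iterative rescaling.  These fixtures emulate smooth, single-scale
transition behaviour; they do not emulate multimodal or heavy-tailed
activity redistribution, kernels varying with time or population size, or
measurement noise — passing tests show correctness of the numerics under
the stated model, not realism of any particular biological kernel.

## Reference computations and problem sizes

The acceptance script and tests use: the reference macro parameter set
`a = 2, b = c = 1, d = 3` with starts `(4, 1)` and `(0.1, 9)`;
`η = 1/4`; grid 241 nodes (61 for dense-kernel runs, where `O(n³)` tables
dominate memory; 41 for ten-seed kernel-equivalence sweeps); kinetic
horizons `t ≤ 5`, macro horizons `t ≤ 40`.  These sizes keep every
reference computation in the seconds range on a single core while leaving
all stated tolerances met with orders of magnitude to spare.

## Known limitations

* Exactly two populations and a one-dimensional activity variable.
* Fixed-step integration only; stiff parameter regimes (very large rates)
  require manually reducing `dt`.
* The general-kernel memory cost `O(n³)` per stored block restricts dense
  tabulated kernels to moderate grids.
* Kernels are static: no dependence on time or population sizes, and no
  estimation of kernels from data.
* The reduced/delta kinetic modes do not conserve mass (see above); long
  delta-mode runs drive both masses toward zero while the difference —
  the quantity the hybrid coupling consumes — remains exact.
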