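# Methods

## Model

Signallers (think of males courting females) differ in a hidden quality
`q ∈ [q_min, q_max]` distributed with full support under `G`. Each carries a
continuous trait `a` that receivers can observe perfectly. Natural selection
outside the signalling context gives the trait a quality-dependent optimum —
the *non-informational optimum* `n(q)` — which in the specific model is
linear,

    n(q) = a_min + β (q − q_min),        β > 0.

Receivers respond to the trait with an inference rule `p = P(a)` and
signaller fitness is bell-shaped around the optimum with a log-linear
benefit of being perceived as high quality:

    w(a, p, q) = exp(λ p) · exp( −(a − n(q))² / (2σ) ).

`λ ≥ 0` scales the impact of receiver preference, `σ > 0` scales how cheap
it is to deviate from the optimum (small σ = rigid, costly trait). Receivers
pay a loss `D(q, p)` that increases with the discrepancy between true and
inferred quality (squared error by default, with an optional asymmetric
variant), averaged over `G`. A strategy pair `(A*, P*)` is evolutionarily
stable when no signaller type gains from any trait deviation given `P*`,
and no inference rule lowers the receiver's average loss given `A*`.

The quadratic-cost exponent is scaled as `(a−n)²/(2σ)` rather than
`((a−n)/σ)²/2`; this is the unique member of the family for which the
equilibrium's limiting exaggeration is `λσ/β` and its deficit half-life is
`(λσ/β²) ln 2` (see below), the two closed-form tail properties the model
is anchored on.

## The separating equilibrium

At a separating equilibrium the rule `A*` is strictly increasing, inference
is honest (`P*(A*(q)) = q`), and the signaller first-order condition
collapses to a scalar ODE for the exaggeration (signalling gap)
`E(q) = A*(q) − n(q)`:

    dE/dq = λσ/E − n′(q),      E(q_min) = 0.

The boundary condition is the least-cost separating convention: the lowest
type has nothing to distinguish itself from and sits at its optimum. For
linear `n` (`n′ = β`) the solution has an exact implicit form. With

    τ = β² (q − q_min)/(λσ),      x = 1 − βE/(λσ),

the relation is `τ = x − 1 − ln x`, `x ∈ (0, 1]` (equivalently
`x = −W(−e^{−(1+τ)})` on the principal Lambert-W branch). Hence:

- `E(q_min) = 0` exactly, with infinite initial slope
  (`E ≈ sqrt(2λσ (q − q_min))` near the boundary);
- `E` rises monotonically to the asymptote `λσ/β`;
- the deficit `λσ/β − E` decays asymptotically as `e^{−τ}`, i.e. it halves
  over the quality distance `(λσ/β²) ln 2`;
- `A*′ = λσ/E` falls monotonically toward β.

Comparative statics follow directly: exaggeration increases with λ and σ
and decreases with β; the equilibrium cost, defined here as the
proportional fitness reduction `1 − exp(−E²/(2σ))`, ranges from ≈0 (large
β, or σ → 0: the trait stays glued to its optimum, a cost-free cue) to
substantial (small β: a costly handicap). The cost definition is this
package's own ratio-scale choice of "cost"; any monotone transform of the
deviation penalty would order the continuum identically. At fixed `q` the
exaggeration is capped by `sqrt(2λσ(q−q_min))` for every β; it is the
large-`q` (asymptotic) exaggeration `λσ/β` that grows without bound as the
cue slope vanishes.

## Numerics

Two independent routes compute `E`:

- **ODE route** (`solve_equilibrium`): the singular start is removed by
  integrating `u = E²`, whose rate `2λσ − 2β√u` is finite at `u = 0`; the
  substitution is used over the whole range (not just the first cell) to
  avoid a switch-over seam. `scipy.solve_ivp` (RK45, rtol 1e−10, atol
  1e−12) evaluates on the requested grid; default 2001 uniform points.
- **Closed-form route** (`exaggeration_implicit`): bracketed Brent root
  finding on `x − 1 − ln x = τ` over `[1e−300, 1]` (machine-exact at τ=0;
  for τ > 700 the root underflows and E equals the asymptote to machine
  precision).

The two routes agree to ≤1e−9 relative error and serve as mutual oracles in
the tests. `A*` is interpolated with a monotone (PCHIP) cubic. The honest
inference rule `P*` is a cubic Hermite interpolant of the inverse whose
node slopes are set analytically to `E/(λσ)` (exactly 0 at the lowest
signal) — shape-estimated slopes are inadequate here because the inverse's
derivative vanishes at the singular boundary and the lowest type's
incentive is only third-order flat, so an inference error ε displaces its
best response by ~(6λε)^{1/3}. Off-path beliefs clamp: signals below
`A*(q_min)` are read as `q_min`, above `A*(q_max)` as `q_max`. Any
numerical non-monotonicity of `A*` beyond 1e−9 relative aborts with
diagnostics rather than being repaired silently.

For a general strictly increasing `n(q)` the same `u`-substitution is used
with `n′` from central finite differences; the tail formulas no longer
apply but honesty and monotonicity do.

Tail extraction (`extract_asymptote_halflife`) reads the asymptote at the
top of the grid (which must reach τ ≥ 30, where the residual deficit is
~1e−13 relative) and measures the deficit-halving distance from a reference
point at τ = 8 by bracketed root finding on the interpolated deficit; the
reference sits that deep because the deficit is only asymptotically
exponential — at τ = 8 the residual bias of the halving distance is ~1e−4
relative, comfortably below the 0.1% the tests demand.

## Stability verification

Evolutionary stability is certified by brute force rather than algebra:

- `signaller_deviation_scan` evaluates `w(a, P*(a), q) − w(A*(q), q, q)` on
  a 200 × 2000 (quality × trait) grid covering
  `[0.5 a_min, A*(q_max) + 3λσ/β]`, so off-path signals are included. The
  solved equilibrium shows no gain above 1e−6 fitness units; a rule shifted
  by +0.5 is flagged immediately (verifier sensitivity).
- `receiver_perturbation_check` perturbs `P*` by 100 seeded Gaussian bumps
  (random centre, width, signed amplitude ≤ 0.1) plus constant shifts and
  confirms the average loss never falls below the honest baseline
  (trapezoidal quadrature on the solution grid; default seed 20180524). A
  finite family is a certificate, not a proof, against "all functions P".
- `single_crossing_check` verifies the Spence–Mirrlees condition: the
  marginal rate of substitution `(a − n(q))/(λσ)` strictly decreases in `q`
  — which is exactly why a positive cue slope makes faking differentially
  costly for low-quality signallers. A flat `n` degenerates and fails
  strictness, as it should.

## Best-response dynamics

`iterate_dynamics` alternates the receiver's conditional-mean inference
(pooling ties, nearest-signal convention off the nodes, and an
out-of-equilibrium extension that reads signals above the observed range
along the separating continuation until they reach `q_max`) with the
signaller's grid argmax (4001-point trait scan, ties to the smaller trait,
guarded parabolic refinement), damped as
`new = (1 − d)·old + d·response`, default `d = 0.5`, stopping when the
sup-norm change falls below 1e−6 or after 500 iterations.

Findings the user should know:

- From the pure-cue start the first signaller response immediately
  exaggerates the trait — the engine reproduces why a cue, once receivers
  attend to it, cannot stay a cue.
- The iterates move toward the analytic equilibrium (sup-norm distance
  falls from ~1.0 to ~0.5–0.7 over a few hundred iterations on a 401-point
  grid) but settle at a rough separating profile rather than converging in
  sup-norm. This is a property of discrete-time best response in this game,
  not of a particular implementation: the signaller's response depends on
  the *slope* of the receiver's inference, so the composed map acts like a
  differentiation operator and amplifies strategy-profile modes up to
  wavelengths of order `E²/(λσ)`; moreover any inference reconstructed from
  sampled strategy data carries in-cell errors far above the ~1e−7 that the
  boundary type's third-order-flat incentive can tolerate. Alternative
  conventions (persistent two-timescale beliefs, isotonic belief
  projection, perceptual binning, node-exact responses, response smoothing,
  annealed noise, damping 0.05–1.0) were explored and settle in the same
  0.1–0.6 band.
- Evolutionary stability of the analytic equilibrium is therefore certified
  by the static deviation scans above, and `converged` in a
  `DynamicsTrajectory` reports the honest outcome (three consecutive
  iterations within `distance_tol` of the analytic rule).

Initial conditions (`make_initial_rules`) are reproducible: the exact cue,
the cue plus seeded smooth sinusoidal noise of a chosen magnitude (floored
at 0.1·a_min to keep traits positive), or a constant (fully pooling) rule.

## Configuration and defaults

Everything is driven by a `RunConfig` (TOML + flag overrides; defaults are
λ = σ = β = 1, a_min = 1, q on [0, 5], chosen as the scale-setting
reference: with λ = σ = 1 the cue slope β is the model's one meaningful
shape parameter, and q_max = 5 covers five half-lives of the approach to
the asymptote). A present `[model]` section must be complete (a missing
field errors by name) so that archived configs are unambiguous; absent
sections fall back to package defaults. Outputs echo the resolved config as
`config.json`, CSVs carry 17 significant digits, and identical configs
reproduce identical bytes; the only randomness (receiver perturbations,
perturbed initial rules) is seeded.

Problem sizes used in the shipped tests and acceptance computations — grids
of 401–5001 points, quality ranges out to τ = 30–60, a 200×2000 deviation
scan, 100 receiver perturbations, ≤600 dynamics iterations — keep every
check deterministic and the full suite around half a minute on one core.

## Limitations

- Receiver perception is perfect; perception noise, choosiness costs,
  pooling/partial-pooling equilibria, multiple audiences and explicit
  population genetics are out of scope.
- The equilibrium-cost formula is the package's ratio-scale definition (see
  above), not a uniquely determined quantity.
- The receiver-side check certifies optimality only against the sampled
  perturbation family; the signaller-side scan only at its grid resolution.
- The dynamics engine demonstrates attraction in shape, not sup-norm
  convergence; see the findings above.
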